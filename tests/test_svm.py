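"""Linear soft-margin SVM, stratified splitting, and C tuning."""

import numpy as np
import pytest

from buscad import svm


def lattice_min_objective(X, y, C, center=(0.0, 0.0, 0.0), span=4.0, steps=81,
                          refinements=3):
    """Brute-force oracle: minimize 1/2||w||² + C·Σ hinge on a (w, b) lattice,
    refined around the running argmin.  Hinge form is the slack optimum."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[1] == 1:
        X = np.column_stack([X[:, 0], np.zeros(len(X))])
    best = None
    c = np.array(center, float)
    s = span
    for _ in range(refinements):
        w1 = np.linspace(c[0] - s, c[0] + s, steps)
        w2 = np.linspace(c[1] - s, c[1] + s, steps)
        b = np.linspace(c[2] - s, c[2] + s, steps)
        W1, W2, B = np.meshgrid(w1, w2, b, indexing="ij")
        margins = (W1[..., None] * X[:, 0] + W2[..., None] * X[:, 1]
                   + B[..., None]) * y
        obj = 0.5 * (W1**2 + W2**2) + C * np.maximum(0.0, 1.0 - margins).sum(axis=-1)
        idx = np.unravel_index(obj.argmin(), obj.shape)
        best = float(obj[idx])
        c = np.array([W1[idx], W2[idx], B[idx]])
        s = 2 * s / (steps - 1) * 2  # shrink around the argmin
    return best


def separated_table(n_per_class=20, seed=0, gap=4.0):
    rng = np.random.default_rng(seed)
    Xb = rng.normal(0.0, 0.5, size=(n_per_class, 4))
    Xm = rng.normal(gap, 0.5, size=(n_per_class, 4))
    X = np.vstack([Xb, Xm])
    y = np.array([svm.BENIGN] * n_per_class + [svm.MALIGNANT] * n_per_class)
    return svm.FeatureTable(X, y)


class TestLargestRemainder:
    @pytest.mark.parametrize("counts,frac,expected", [
        ((437, 210), 0.30, (306, 147)),       # tumor-bearing 70/30
        ((133, 437, 210), 0.20, (106, 350, 168)),  # full cohort 80/20
        ((10, 10), 0.50, (5, 5)),
    ])
    def test_largest_remainder_split_arithmetic(self, counts, frac, expected):
        split = svm.stratified_holdout(
            np.repeat(np.arange(len(counts)), counts), test_fraction=frac, seed=0
        )
        assert tuple(split.per_class_train[i] for i in range(len(counts))) == expected
        total = sum(counts)
        assert len(split.train_idx) == round(total * (1 - frac))
        assert len(split.train_idx) + len(split.test_idx) == total

    def test_disjoint_and_exhaustive(self):
        labels = np.repeat([0, 1], [13, 7])
        split = svm.stratified_holdout(labels, 0.3, seed=3)
        both = np.concatenate([split.train_idx, split.test_idx])
        assert sorted(both.tolist()) == list(range(20))

    def test_split_is_pure_function_of_inputs(self):
        labels = np.repeat([0, 1], [30, 20])
        a = svm.stratified_holdout(labels, 0.25, seed=11)
        b = svm.stratified_holdout(labels, 0.25, seed=11)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        c = svm.stratified_holdout(labels, 0.25, seed=12)
        assert not np.array_equal(a.train_idx, c.train_idx)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            svm.stratified_holdout(np.array([], int), 0.3, seed=0)


class TestTrainSvm:
    def test_1d_separable_closed_form(self):
        """x = ±1 with matching labels: max-margin solution w=1, b=0."""
        table = svm.FeatureTable(np.array([[-1.0], [1.0]]),
                                 np.array([svm.BENIGN, svm.MALIGNANT]))
        model = svm.train_svm(table, C=1e6)
        assert model.w[0] == pytest.approx(1.0, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)

    def test_separable_has_zero_slack_and_full_accuracy(self):
        table = separated_table()
        model = svm.train_svm(table, C=1e4)
        assert model.xi.max() < 1e-3  # zero up to SMO tolerance
        d = svm.decision_values(model, table.X)
        assert ((d > 0) == (table.y == svm.MALIGNANT)).all()

    def test_six_point_instance_matches_lattice_oracle(self):
        """2-D instance with one margin violator: SMO objective equals the
        brute-force lattice minimum within 1e-2."""
        X = np.array([[-2.0, 0.0], [-1.5, 1.0], [-1.0, -1.0],
                      [2.0, 0.5], [1.5, -0.5], [-0.5, 0.3]])  # last one violates
        y = np.array([-1, -1, -1, 1, 1, 1])
        C = 1.0
        model = svm.train_svm(svm.FeatureTable(X, y), C, standardize=False)
        oracle = lattice_min_objective(X, y, C)
        assert model.objective() == pytest.approx(oracle, abs=1e-2)

    def test_random_small_instances_match_lattice_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            X = rng.normal(0, 1.2, size=(n, 2))
            y = np.where(rng.random(n) < 0.5, -1, 1)
            if len(np.unique(y)) < 2:
                y[0] = -y[0]
            C = float(rng.choice([0.5, 1.0, 2.0]))
            model = svm.train_svm(svm.FeatureTable(X, y), C, standardize=False)
            oracle = lattice_min_objective(X, y, C)
            assert model.objective() == pytest.approx(oracle, abs=2e-2)

    def test_slack_nonnegative_and_margin_constraints(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(30, 4))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=30) > 0, 1, -1)
        model = svm.train_svm(svm.FeatureTable(X, y), C=1.0)
        assert (model.xi >= 0).all()
        margins = model.standardizer.transform(X) @ model.w + model.b
        assert (y * margins >= 1 - model.xi - 1e-9).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            svm.train_svm(svm.FeatureTable(np.zeros((3, 4)),
                                           np.array([1, 1, 1])), C=1.0)


class TestPredict:
    def test_separable_training_labels_reproduced(self):
        table = separated_table(seed=5)
        model = svm.train_svm(table, C=10.0)
        for x, yy in zip(table.X, table.y):
            name, _ = svm.predict(model, x)
            assert name == ("malignant" if yy == svm.MALIGNANT else "benign")

    def test_point_on_hyperplane_is_benign(self):
        model = svm.SvmModel(w=np.array([1.0, 0, 0, 0]), b=0.0, C=1.0,
                             standardizer=svm.Standardizer.identity(4),
                             xi=np.zeros(1))
        name, d = svm.predict(model, np.zeros(4))
        assert d == 0.0 and name == "benign"


class TestStandardization:
    def test_parameters_depend_only_on_training_rows(self):
        table = separated_table(seed=2)
        split = svm.stratified_holdout(table.y, 0.3, seed=0)
        train_tab = table.subset(split.train_idx)
        model = svm.train_svm(train_tab, C=1.0)
        np.testing.assert_allclose(model.standardizer.center,
                                   train_tab.X.mean(axis=0))
        np.testing.assert_allclose(model.standardizer.scale,
                                   train_tab.X.std(axis=0))
        # permuting/removing test rows cannot change the standardizer
        model2 = svm.train_svm(train_tab, C=1.0)
        np.testing.assert_array_equal(model.standardizer.center,
                                      model2.standardizer.center)

    def test_standardize_toggle(self):
        table = separated_table(seed=4)
        off = svm.train_svm(table, C=1.0, standardize=False)
        assert (off.standardizer.center == 0).all()
        assert (off.standardizer.scale == 1).all()


class TestTuneC:
    def test_tie_breaks_to_smallest_C(self):
        table = separated_table(n_per_class=25, seed=1, gap=8.0)
        best, scores = svm.tune_C(table, k=5, seed=0)
        assert all(s == 1.0 for s in scores.values())
        assert best == 0.1

    def test_seeded_fold_determinism(self):
        table = separated_table(n_per_class=25, seed=3, gap=1.0)
        a = svm.tune_C(table, k=5, seed=42)
        b = svm.tune_C(table, k=5, seed=42)
        assert a == b

    def test_grid_order_invariance(self):
        table = separated_table(n_per_class=15, seed=6, gap=1.5)
        best1, _ = svm.tune_C(table, grid=(0.1, 1, 10, 100), k=3, seed=1)
        best2, _ = svm.tune_C(table, grid=(100, 10, 1, 0.1), k=3, seed=1)
        assert best1 == best2

    def test_fold_sizes_differ_by_at_most_one(self):
        labels = np.repeat([svm.BENIGN, svm.MALIGNANT], [437, 210])
        folds = svm.stratified_folds(labels, k=5, seed=0)
        for cls in (svm.BENIGN, svm.MALIGNANT):
            sizes = [int((labels[f] == cls).sum()) for f in folds]
            assert max(sizes) - min(sizes) <= 1
        assert sum(len(f) for f in folds) == 647
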