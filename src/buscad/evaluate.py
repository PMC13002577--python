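"""Segmentation and classification evaluation: IoU/Dice, confusion matrices,
accuracy with a Wald binomial confidence interval, stratified k-fold
cross-validation, and the end-to-end pipeline report.

Conventions
-----------
* Mask IoU is reported in percent: 100·|P∩G| / |P∪G|.
* Dice relates to IoU (as fractions) by DSC = 2·IoU / (1 + IoU); the identity
  holds exactly per image, since both derive from the same |P∩G|, |P∪G|.
* An empty predicted mask against an empty ground truth (a correctly gated
  normal case) has undefined IoU by the formula; it is scored 100 with a
  flag, and mean IoU is reported both including and excluding such cases.
* The 95% CI uses the normal approximation p̂ ± z·√(p̂(1−p̂)/n) with
  z = 1.959964, clipped to [0, 100].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import svm as _svm
from .geometry import extract_features
from .unet import gate_normal, predict_mask

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "mask_iou",
    "dice_from_iou",
    "dice",
    "accuracy",
    "misclassification_rate",
    "wald_ci",
    "stratified_kfold_cv",
    "evaluate_pipeline",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts n[true][pred] over a fixed label set."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k) or (counts < 0).any():
            raise ValueError("counts must be a non-negative k×k matrix")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_pairs(cls, true, pred, labels) -> "ConfusionMatrix":
        labels = tuple(labels)
        index = {l: i for i, l in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(true, pred, strict=True):
            counts[index[t], index[p]] += 1
        return cls(labels=labels, counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "counts": self.counts.tolist()}


def mask_iou(P: np.ndarray, G: np.ndarray) -> tuple[float, bool]:
    """Intersection over union of two binary masks, in percent.

    Returns ``(iou_percent, empty_pair_flag)``; two empty masks agree
    perfectly, scored 100 with the flag raised.
    """
    P = np.asarray(P).astype(bool)
    G = np.asarray(G).astype(bool)
    if P.shape != G.shape:
        raise ValueError(f"mask shapes differ: {P.shape} vs {G.shape}")
    union = np.count_nonzero(P | G)
    if union == 0:
        return 100.0, True
    inter = np.count_nonzero(P & G)
    return 100.0 * inter / union, False


def dice_from_iou(iou: float) -> float:
    """Dice similarity from IoU, both as fractions: 2·IoU / (1 + IoU)."""
    if not (0.0 <= iou <= 1.0):
        raise ValueError(f"IoU fraction out of range: {iou}")
    return 2.0 * iou / (1.0 + iou)


def dice(P: np.ndarray, G: np.ndarray) -> tuple[float, bool]:
    """Dice coefficient 2|P∩G|/(|P|+|G|) as a fraction, empty/empty → 1."""
    P = np.asarray(P).astype(bool)
    G = np.asarray(G).astype(bool)
    if P.shape != G.shape:
        raise ValueError(f"mask shapes differ: {P.shape} vs {G.shape}")
    denom = np.count_nonzero(P) + np.count_nonzero(G)
    if denom == 0:
        return 1.0, True
    return 2.0 * np.count_nonzero(P & G) / denom, False


def accuracy(matrix: ConfusionMatrix) -> float:
    """100 · correct / total."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * matrix.correct / matrix.total


def misclassification_rate(matrix: ConfusionMatrix) -> float:
    """100 · errors / total."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (matrix.total - matrix.correct) / matrix.total


def wald_ci(correct: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Normal-approximation binomial CI for an accuracy, in percent.

    p̂ ± z·√(p̂(1−p̂)/n), clipped to [0, 100].  At 95%, z = 1.959964.
    """
    if n <= 0 or not (0 <= correct <= n):
        raise ValueError("need 0 <= correct <= n with n > 0")
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    p = correct / n
    half = z * np.sqrt(p * (1.0 - p) / n)
    return (
        float(np.clip(100.0 * (p - half), 0.0, 100.0)),
        float(np.clip(100.0 * (p + half), 0.0, 100.0)),
    )


def stratified_kfold_cv(table: "_svm.FeatureTable", k: int = 5, seed: int = 0,
                        C_protocol: str = "tune", C: float = 1.0,
                        grid=_svm.DEFAULT_GRID):
    """Stratified k-fold cross-validated accuracy of the stage-2 classifier.

    Each fold is scored by a model trained on the remaining folds; with
    ``C_protocol="tune"`` the penalty is re-tuned inside each training
    portion (nested grid search, the full training protocol), with
    ``"fixed"`` the supplied C is used throughout.  Returns a dict with
    per-fold accuracies (percent), their mean and standard deviation, and
    the fold sizes.
    """
    folds = _svm.stratified_folds(table.y, k=k, seed=seed)
    all_idx = np.arange(table.n)
    accs, sizes = [], []
    for f in range(k):
        test_idx = folds[f]
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_tab = table.subset(train_idx)
        if C_protocol == "tune":
            C_f, _ = _svm.tune_C(train_tab, grid=grid, k=k, seed=seed)
        elif C_protocol == "fixed":
            C_f = C
        else:
            raise ValueError("C_protocol must be 'tune' or 'fixed'")
        model = _svm.train_svm(train_tab, C_f)
        d = _svm.decision_values(model, table.X[test_idx])
        pred = np.where(d > 0, _svm.MALIGNANT, _svm.BENIGN)
        accs.append(100.0 * float((pred == table.y[test_idx]).mean()))
        sizes.append(int(len(test_idx)))
    accs = np.array(accs)
    return {
        "per_fold_accuracy": [round(a, 10) for a in accs.tolist()],
        "fold_sizes": sizes,
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)),
    }


@dataclass
class EvalReport:
    """End-to-end evaluation artefact; serializable to JSON and text."""

    per_image: list
    mean_iou: float
    mean_iou_excluding_empty: float | None
    gate_matrix: ConfusionMatrix
    stage2_matrix: ConfusionMatrix | None
    stage2_accuracy: float | None
    stage2_ci95: tuple[float, float] | None
    config: dict
    seed: int

    def to_json(self) -> str:
        payload = {
            "per_image": self.per_image,
            "mean_iou": self.mean_iou,
            "mean_iou_excluding_empty": self.mean_iou_excluding_empty,
            "gate_matrix": self.gate_matrix.to_dict(),
            "stage2_matrix": self.stage2_matrix.to_dict() if self.stage2_matrix else None,
            "stage2_accuracy": self.stage2_accuracy,
            "stage2_ci95": list(self.stage2_ci95) if self.stage2_ci95 else None,
            "config": self.config,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            "Two-stage evaluation report",
            f"  images evaluated : {len(self.per_image)}",
            f"  mean Mask IoU    : {self.mean_iou:.1f}%",
        ]
        if self.mean_iou_excluding_empty is not None:
            lines.append(
                f"  mean Mask IoU (tumor-bearing only): {self.mean_iou_excluding_empty:.1f}%"
            )
        lines.append(f"  gate audit (true × routed): {self.gate_matrix.counts.tolist()}")
        if self.stage2_matrix is not None:
            lines += [
                f"  stage-2 confusion (true × pred): {self.stage2_matrix.counts.tolist()}",
                f"  stage-2 accuracy : {self.stage2_accuracy:.2f}%",
                f"  stage-2 95% CI   : {self.stage2_ci95[0]:.2f}%–{self.stage2_ci95[1]:.2f}%",
            ]
        return "\n".join(lines)


def evaluate_pipeline(seg_model, svm_model, samples, seed: int = 0,
                      min_area: int = 0, config: dict | None = None,
                      predicted_masks=None) -> EvalReport:
    """Run the full two-stage evaluation over labeled samples.

    For each sample the segmenter predicts a mask (or ``predicted_masks[i]``
    is used when supplied, e.g. to audit with oracle masks); the empty-mask
    gate routes the case to *normal* or to morphometry + SVM.  Segmentation
    is scored by per-image Mask IoU (empty/empty flagged and reported both
    included and excluded); the gate audit is a normal-vs-tumor confusion
    matrix over all samples; the stage-2 confusion matrix, accuracy and Wald
    CI cover tumor-bearing ground-truth samples that passed the gate.
    """
    samples = list(samples)
    per_image = []
    gate_true, gate_routed = [], []
    s2_true, s2_pred = [], []
    ious, empties = [], []
    for i, s in enumerate(samples):
        pred = predicted_masks[i] if predicted_masks is not None else predict_mask(seg_model, s.image)
        iou, empty_pair = mask_iou(pred, s.mask)
        dsc, _ = dice(pred, s.mask)
        ious.append(iou)
        empties.append(empty_pair)
        is_normal = gate_normal(pred, min_area=min_area)
        routed = "normal" if is_normal else "tumor"
        truth = "normal" if s.class_label == "normal" else "tumor"
        gate_true.append(truth)
        gate_routed.append(routed)
        verdict = "normal"
        decision = None
        if not is_normal:
            feats = extract_features(pred)
            verdict, decision = _svm.predict(svm_model, feats)
        if s.class_label in ("benign", "malignant") and not is_normal:
            s2_true.append(s.class_label)
            s2_pred.append(verdict)
        per_image.append({
            "sample_id": s.sample_id or str(i),
            "class": s.class_label,
            "iou": iou,
            "dice": dsc,
            "empty_pair": bool(empty_pair),
            "routed": routed,
            "verdict": verdict,
            "decision_value": decision,
        })

    gate_matrix = ConfusionMatrix.from_pairs(gate_true, gate_routed, ("normal", "tumor"))
    ious_arr = np.array(ious)
    empt = np.array(empties)
    mean_iou = float(ious_arr.mean()) if len(ious_arr) else float("nan")
    mean_iou_ex = float(ious_arr[~empt].mean()) if (~empt).any() else None

    stage2_matrix = stage2_acc = ci = None
    if s2_true:
        stage2_matrix = ConfusionMatrix.from_pairs(s2_true, s2_pred, ("benign", "malignant"))
        stage2_acc = accuracy(stage2_matrix)
        ci = wald_ci(stage2_matrix.correct, stage2_matrix.total)

    return EvalReport(
        per_image=per_image,
        mean_iou=mean_iou,
        mean_iou_excluding_empty=mean_iou_ex,
        gate_matrix=gate_matrix,
        stage2_matrix=stage2_matrix,
        stage2_accuracy=stage2_acc,
        stage2_ci95=ci,
        config=config or {},
        seed=seed,
    )
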