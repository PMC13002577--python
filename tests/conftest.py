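"""Shared fixtures: in-memory phantom cohorts and independent geometry oracles.

The oracles here deliberately re-implement the measured quantities from
first principles (gift-wrapped hulls, a from-scratch boundary walk, direct
moment sums) so they share no code with the package's geometry module.
"""

import numpy as np
import pytest

from buscad import phantom


# ------------------------------------------------------------ phantom data --


def make_pairs(n_per_class: int, seed: int, size: int = 64, easy: bool = True):
    """(image, mask, class) triples, classes interleaved, without file I/O."""
    spec = (phantom.easy_spec(seed=seed, image_size=(size, size)) if easy
            else phantom.PhantomSpec(seed=seed, image_size=(size, size)))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_per_class):
        for cls in ("normal", "benign", "malignant"):
            if cls == "normal":
                mask = np.zeros((size, size), bool)
            else:
                mask = phantom.rasterize(phantom.sample_outline(cls, spec, rng), size, size).mask
            out.append((phantom.render(mask, spec, rng), mask, cls))
    return out


@pytest.fixture(scope="session")
def tumor_masks_256():
    """50 benign + 50 malignant ground-truth masks at the native 256×256."""
    spec = phantom.PhantomSpec(seed=42)
    rng = np.random.default_rng(42)
    masks = {"benign": [], "malignant": []}
    for cls in masks:
        for _ in range(50):
            masks[cls].append(
                phantom.rasterize(phantom.sample_outline(cls, spec, rng), 256, 256).mask
            )
    return masks


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """A small phantom dataset written to disk in the dataset dialect."""
    root = tmp_path_factory.mktemp("phantom") / "data"
    spec = phantom.PhantomSpec(
        n_normal=5, n_benign=7, n_malignant=3, image_size=(64, 64), seed=9,
        p_multimask=0.4,
    )
    manifest = phantom.generate_dataset(spec, str(root))
    return root, spec, manifest


# ---------------------------------------------------------------- oracles --


def random_small_mask(rng: np.random.Generator) -> np.ndarray:
    """A random non-empty mask of size up to 12×12 (any foreground pattern)."""
    h = int(rng.integers(1, 13))
    w = int(rng.integers(1, 13))
    p = float(rng.uniform(0.2, 0.8))
    mask = rng.random((h, w)) < p
    if not mask.any():
        mask[int(rng.integers(h)), int(rng.integers(w))] = True
    return mask


def giftwrap_hull(points: np.ndarray) -> np.ndarray:
    """Jarvis-march convex hull of integer points, counter-clockwise."""
    pts = [tuple(p) for p in np.unique(points, axis=0)]
    if len(pts) <= 2:
        return np.array(pts)
    start = min(pts)
    hull = [start]
    cur = start
    while True:
        cand = pts[0] if pts[0] != cur else pts[1]
        for p in pts:
            if p == cur:
                continue
            cross = ((cand[0] - cur[0]) * (p[1] - cur[1])
                     - (cand[1] - cur[1]) * (p[0] - cur[0]))
            if cross > 0 or (cross == 0 and
                             (abs(p[0] - cur[0]) + abs(p[1] - cur[1])
                              > abs(cand[0] - cur[0]) + abs(cand[1] - cur[1]))):
                cand = p
        cur = cand
        if cur == start:
            break
        hull.append(cur)
    return np.array(hull)


def oracle_convex_area(region: np.ndarray) -> int:
    """Count pixel centers inside (or on) the hull of foreground centers."""
    coords = np.argwhere(region)
    hull = giftwrap_hull(coords)
    if len(hull) <= 2:
        return len(coords)
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    count = 0
    for r in range(rmin, rmax + 1):
        for c in range(cmin, cmax + 1):
            crosses = [
                (hull[(k + 1) % len(hull)][0] - hull[k][0]) * (c - hull[k][1])
                - (hull[(k + 1) % len(hull)][1] - hull[k][1]) * (r - hull[k][0])
                for k in range(len(hull))
            ]
            # inside/on-hull iff all edge crosses share a sign (either
            # orientation of the hull polygon is accepted)
            if all(x >= -1e-9 for x in crosses) or all(x <= 1e-9 for x in crosses):
                count += 1
    return count


def oracle_boundary_walk(region: np.ndarray) -> float:
    """Raw chain length of the outer boundary, written from scratch.

    Moore-neighbour walk in the *counter-clockwise* orientation (production
    traces clockwise; the closed walk is the same cycle reversed, so its
    length must agree).  Step weights 1 (orthogonal) and sqrt(2) (diagonal).
    """
    H, W = region.shape
    fg = np.argwhere(region)
    fg = fg[np.lexsort((fg[:, 1], fg[:, 0]))]
    start = (int(fg[0][0]), int(fg[0][1]))
    # counter-clockwise ring (in image coordinates: row down, col right)
    ring = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]

    def filled(p):
        return 0 <= p[0] < H and 0 <= p[1] < W and bool(region[p[0], p[1]])

    def scan(cur, back):
        """First foreground neighbour counter-clockwise after ``back``."""
        b = (back[0] - cur[0], back[1] - cur[1])
        i0 = ring.index(b)
        for k in range(1, 9):
            i = (i0 + k) % 8
            q = (cur[0] + ring[i][0], cur[1] + ring[i][1])
            if filled(q):
                prev = (cur[0] + ring[(i - 1) % 8][0], cur[1] + ring[(i - 1) % 8][1])
                return q, prev
        return None, None

    cur, back = start, (start[0], start[1] - 1)  # west neighbour is background
    first_move = None
    walk = [start]
    for _ in range(8 * region.size + 8):
        nxt, new_back = scan(cur, back)
        if nxt is None:
            return 0.0  # isolated pixel
        if first_move is None:
            first_move = nxt
        elif cur == start and nxt == first_move:
            break
        walk.append(nxt)
        # backtrack must be expressed relative to the new pixel
        back, cur = new_back, nxt
    else:
        raise RuntimeError("oracle walk failed to close")
    if len(walk) > 1 and walk[-1] == walk[0]:
        walk = walk[:-1]
    length = 0.0
    closed = walk + [walk[0]]
    for a, b in zip(closed[:-1], closed[1:]):
        dr, dc = abs(a[0] - b[0]), abs(a[1] - b[1])
        length += np.sqrt(2.0) if dr and dc else 1.0
    return length
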