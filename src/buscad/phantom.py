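"""Seeded speckle-phantom generator for breast-ultrasound-like images.

Real B-mode breast scans show a bright speckled tissue background with
hypoechoic (darker) lesions; benign lesions have smooth, near-elliptical,
well-circumscribed outlines while malignant ones are spiculated and
irregular.  This module fabricates desk-scale datasets with exactly those
contrasts so that every downstream stage (loading, segmentation, morphometry,
classification) is testable without any clinical download.

The lesion boundary model is a truncated Fourier perturbation of an ellipse:

    r(θ) = r0 · s(θ) · (1 + Σ_k a_k cos(kθ + φ_k)) [+ spicule bumps]

where s(θ) is the polar radius of a unit-area-preserving ellipse (the
elongation term), the low-order harmonics give gentle lobulation, and, for
malignant lesions only, narrow additive Gaussian bumps in angle create
spicules.  This parameterization gives direct, independent control over the
four shape descriptors used by the classifier.

Speckle is multiplicative gamma noise (unit mean) on a smooth background,
lightly blurred so it has grain; no attempt is made at physical acoustics
(point-spread functions, attenuation, posterior shadowing).  The images only
need enough texture to make segmentation nontrivial — all shape features
depend on masks alone.

Files are written in the public breast-ultrasound dataset dialect:
``<class>/<class> (k).png`` with masks ``<class> (k)_mask.png`` (and
``_mask_1.png`` when a lesion is split across two mask files whose logical
OR restores the full lesion).  Normal cases get all-zero masks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "LesionOutline",
    "PhantomSpec",
    "RasterResult",
    "sample_outline",
    "rasterize",
    "render",
    "generate_dataset",
    "easy_spec",
    "CLASSES",
]

CLASSES = ("normal", "benign", "malignant")


@dataclass(frozen=True)
class LesionOutline:
    """Polar lesion boundary sampled at uniformly spaced angles.

    ``radii[k]`` is r(θ_k) at θ_k = 2πk/n for k = 0..n−1; evaluation at
    arbitrary θ wraps around periodically.
    """

    center: tuple[float, float]  # (row, col), pixels
    base_radius: float
    radii: np.ndarray

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        if radii.ndim != 1 or len(radii) < 8:
            raise ValueError("radii must be a 1-D sample of at least 8 angles")
        if not np.all(radii > 0):
            raise ValueError("all boundary radii must be positive")
        object.__setattr__(self, "radii", radii)

    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of r(θ)."""
        n = len(self.radii)
        t = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi) * n / (2.0 * np.pi)
        i0 = np.floor(t).astype(int) % n
        frac = t - np.floor(t)
        return self.radii[i0] * (1.0 - frac) + self.radii[(i0 + 1) % n] * frac


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the synthetic cohort.

    Defaults describe the stock phantom: 256×256 frames (the segmentation
    network's native input), moderately hypoechoic lesions on gamma speckle,
    smooth low-harmonic benign outlines vs. strongly perturbed, spiculated
    malignant ones, and malignant lesions drawn more elongated than benign
    (the radiological convention that malignancy raises eccentricity).
    """

    n_normal: int = 0
    n_benign: int = 0
    n_malignant: int = 0
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0

    # boundary morphology
    benign_amplitude: float = 0.055       # total low-harmonic amplitude budget
    benign_harmonics: int = 3             # harmonics k = 2..4
    malignant_amplitude: float = 0.20     # high-harmonic amplitude budget
    malignant_harmonics: int = 8          # harmonics k = 2..9
    n_spicules: int = 8
    spicule_amplitude: float = 0.32       # additive bump height, units of r0
    spicule_width: float = 0.07           # angular std of a bump, radians
    benign_elongation: tuple[float, float] = (1.05, 1.5)
    malignant_elongation: tuple[float, float] = (1.5, 2.2)
    radius_frac: tuple[float, float] = (0.10, 0.16)  # r0 / min(H, W)

    # speckle rendering
    background_mean: float = 0.55
    lesion_contrast: float = 0.55         # fractional darkening inside lesion
    noise_scale: float = 0.30             # std of unit-mean multiplicative speckle
    edge_blur: float = 2.0                # Gaussian blur of lesion support, px

    p_multimask: float = 0.15             # chance a lesion is written as 2 files
    n_theta: int = 720                    # angular samples per outline

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_benign, self.n_malignant) < 0:
            raise ValueError("class counts must be non-negative")
        if min(self.image_size) <= 0:
            raise ValueError("image size must be positive")
        if self.benign_amplitude < 0 or self.malignant_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.malignant_amplitude <= self.benign_amplitude:
            raise ValueError("malignant boundary amplitude must exceed benign")
        if not (0.0 < self.lesion_contrast < 1.0):
            raise ValueError("lesion contrast must lie in (0, 1)")
        if not (0.0 <= self.p_multimask <= 1.0):
            raise ValueError("p_multimask must be a probability")


@dataclass(frozen=True)
class RasterResult:
    mask: np.ndarray
    clipped: bool


def easy_spec(n_per_class: int = 20, seed: int = 0, image_size: tuple[int, int] = (64, 64)) -> PhantomSpec:
    """High-contrast, low-noise preset used for desk-scale segmentation runs."""
    return PhantomSpec(
        n_normal=n_per_class,
        n_benign=n_per_class,
        n_malignant=n_per_class,
        image_size=image_size,
        seed=seed,
        lesion_contrast=0.8,
        noise_scale=0.15,
        edge_blur=1.0,
    )


def _ellipse_shape(theta: np.ndarray, elong: float, phase: float) -> np.ndarray:
    """Polar radius of an area-preserving ellipse with axis ratio ``elong``.

    Semi-axes sqrt(e) and 1/sqrt(e) so the enclosed area stays π·r0².
    """
    a = np.sqrt(elong)
    b = 1.0 / a
    t = theta - phase
    return (a * b) / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)


def sample_outline(class_kind: str, spec: PhantomSpec, rng: np.random.Generator) -> LesionOutline:
    """Draw one lesion outline with class-dependent morphology.

    Benign: few low-order, low-amplitude harmonics on a mildly elongated
    ellipse.  Malignant: more and higher-order harmonics with a larger
    amplitude budget, stronger elongation, plus additive angular spicule
    bumps.  Radii are floored at 1 px to keep the invariant r(θ) > 0.
    """
    if class_kind == "normal":
        raise ValueError("normal cases carry no lesion outline")
    if class_kind not in ("benign", "malignant"):
        raise ValueError(f"unknown class {class_kind!r}")

    H, W = spec.image_size
    r0 = float(rng.uniform(*spec.radius_frac)) * min(H, W)

    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_theta, endpoint=False)
    if class_kind == "benign":
        n_h, total_amp = spec.benign_harmonics, spec.benign_amplitude
        elong = float(rng.uniform(*spec.benign_elongation))
        spicule_reach = 0.0
    else:
        n_h, total_amp = spec.malignant_harmonics, spec.malignant_amplitude
        elong = float(rng.uniform(*spec.malignant_elongation))
        spicule_reach = spec.spicule_amplitude * r0
    phase = float(rng.uniform(0.0, np.pi))

    # keep the whole outline inside the frame: bound the maximal radius and
    # restrict the center accordingly (falls back to the frame center when
    # the lesion is too large to move)
    reach = r0 * np.sqrt(elong) * (1.0 + total_amp) + spicule_reach + 2.0
    center = (
        float(rng.uniform(reach, H - 1 - reach)) if 2 * reach < H - 1 else H / 2.0,
        float(rng.uniform(reach, W - 1 - reach)) if 2 * reach < W - 1 else W / 2.0,
    )

    shape = _ellipse_shape(theta, elong, phase)
    perturb = np.zeros_like(theta)
    if n_h > 0 and total_amp > 0:
        amps = rng.dirichlet(np.ones(n_h)) * total_amp
        phis = rng.uniform(0.0, 2.0 * np.pi, size=n_h)
        for k in range(n_h):
            perturb += amps[k] * np.cos((k + 2) * theta + phis[k])
    r = r0 * shape * (1.0 + perturb)

    if class_kind == "malignant" and spec.n_spicules > 0 and spec.spicule_amplitude > 0:
        centers = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_spicules)
        heights = rng.uniform(0.4, 1.0, size=spec.n_spicules) * spec.spicule_amplitude * r0
        widths = rng.uniform(0.6, 1.4, size=spec.n_spicules) * spec.spicule_width
        for c, h, w in zip(centers, heights, widths):
            d = np.angle(np.exp(1j * (theta - c)))  # wrapped angular distance
            r += h * np.exp(-0.5 * (d / w) ** 2)

    r = np.maximum(r, 1.0)
    return LesionOutline(center=center, base_radius=r0, radii=r)


def rasterize(outline: LesionOutline, H: int, W: int) -> RasterResult:
    """Fill the outline: pixel (i, j) is foreground iff its center's polar
    radius about the lesion center is ≤ the interpolated boundary radius.

    ``clipped`` flags outlines extending beyond the frame (the part outside
    is cut; an outline entirely outside yields an empty mask).
    """
    if H <= 0 or W <= 0:
        raise ValueError("mask dimensions must be positive")
    cy, cx = outline.center
    rmax = float(outline.radii.max())
    r0, r1 = int(np.floor(cy - rmax)), int(np.ceil(cy + rmax))
    c0, c1 = int(np.floor(cx - rmax)), int(np.ceil(cx + rmax))
    clipped = r0 < 0 or c0 < 0 or r1 >= H or c1 >= W

    rr0, rr1 = max(r0, 0), min(r1, H - 1)
    cc0, cc1 = max(c0, 0), min(c1, W - 1)
    mask = np.zeros((H, W), dtype=bool)
    if rr0 > rr1 or cc0 > cc1:
        return RasterResult(mask=mask, clipped=True)

    yy, xx = np.mgrid[rr0 : rr1 + 1, cc0 : cc1 + 1]
    dy = yy - cy
    dx = xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dx, -dy)  # orientation convention is internal only
    inside = dist <= outline.radius_at(theta)
    mask[rr0 : rr1 + 1, cc0 : cc1 + 1] = inside
    if clipped and not mask.any():
        return RasterResult(mask=mask, clipped=True)
    return RasterResult(mask=mask, clipped=clipped)


def render(mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Render a speckled grayscale image in [0, 1] for a given lesion mask.

    Expected intensity is ``background_mean`` outside the lesion and
    ``background_mean * (1 − lesion_contrast)`` inside, with the lesion
    support edge-blurred; multiplicative unit-mean gamma speckle (lightly
    smoothed to give it grain) is applied on top, then values are clipped.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != tuple(spec.image_size):
        raise ValueError(f"mask shape {mask.shape} != spec image size {spec.image_size}")
    support = mask.astype(float)
    if spec.edge_blur > 0:
        support = ndimage.gaussian_filter(support, sigma=spec.edge_blur)
    base = spec.background_mean * (1.0 - spec.lesion_contrast * support)
    if spec.noise_scale > 0:
        shape_k = 1.0 / spec.noise_scale**2
        speckle = rng.gamma(shape=shape_k, scale=1.0 / shape_k, size=mask.shape)
        speckle = ndimage.gaussian_filter(speckle, sigma=0.6)
    else:
        speckle = 1.0
    img = np.clip(base * speckle, 0.0, 1.0)
    return img.astype(np.float64)


def _split_mask(mask: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split a lesion mask into two overlapping halves whose OR is the mask."""
    coords = np.argwhere(mask)
    axis = int(rng.integers(0, 2))  # 0: split by row, 1: by column
    cut = int(np.median(coords[:, axis]))
    lo = np.zeros_like(mask)
    hi = np.zeros_like(mask)
    idx = np.indices(mask.shape)[axis]
    lo[(idx <= cut) & mask] = True
    hi[(idx >= cut) & mask] = True  # one-line overlap keeps both non-empty
    if not lo.any() or not hi.any():
        return mask.copy(), mask.copy()
    return lo, hi


def _save_png(path: str, arr: np.ndarray, is_mask: bool) -> None:
    if is_mask:
        data = np.where(np.asarray(arr, dtype=bool), 255, 0).astype(np.uint8)
    else:
        data = np.clip(np.round(np.asarray(arr) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def iter_samples(spec: PhantomSpec):
    """Yield the cohort deterministically: (class, stem, image, mask, mask_parts).

    ``mask_parts`` is the list of mask arrays that will be written as files;
    their logical OR always equals ``mask`` (a lesion is occasionally split
    into two overlapping parts, per ``p_multimask``).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    for cls, count in (
        ("normal", spec.n_normal),
        ("benign", spec.n_benign),
        ("malignant", spec.n_malignant),
    ):
        for k in range(1, count + 1):
            stem = f"{cls} ({k})"
            if cls == "normal":
                mask = np.zeros((H, W), dtype=bool)
            else:
                mask = rasterize(sample_outline(cls, spec, rng), H, W).mask
            image = render(mask, spec, rng)
            split = (
                cls != "normal"
                and mask.any()
                and float(rng.uniform()) < spec.p_multimask
            )
            parts = list(_split_mask(mask, rng)) if split else [mask]
            yield cls, stem, image, mask, parts


def generate_dataset(spec: PhantomSpec, out_dir: str) -> pd.DataFrame:
    """Write a phantom dataset in the public-dataset dialect; return its manifest.

    The manifest (also written to ``manifest.csv``) has one row per image:
    path (relative to ``out_dir``), class, n_masks, seed.  The whole dataset
    is a pure function of ``spec`` (which includes the seed).
    """
    rows = []
    for cls, stem, image, mask, parts in iter_samples(spec):
        cls_dir = os.path.join(out_dir, cls)
        os.makedirs(cls_dir, exist_ok=True)
        img_rel = os.path.join(cls, f"{stem}.png")
        _save_png(os.path.join(out_dir, img_rel), image, is_mask=False)
        for i, part in enumerate(parts):
            suffix = "_mask" if i == 0 else f"_mask_{i}"
            _save_png(os.path.join(cls_dir, f"{stem}{suffix}.png"), part, is_mask=True)
        rows.append({"path": img_rel, "class": cls, "n_masks": len(parts),
                     "seed": spec.seed})
    manifest = pd.DataFrame(rows, columns=["path", "class", "n_masks", "seed"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
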