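"""Reading the breast-ultrasound dataset dialect.

The public dataset ships class folders ``normal``/``benign``/``malignant``
containing grayscale PNGs named ``benign (7).png`` with one or more mask
files ``benign (7)_mask.png``, ``benign (7)_mask_1.png``, ...  A sample's
ground truth is the logical OR of all its mask files; normal samples carry
an all-zero mask.  This module scans that layout, loads and OR-merges the
masks, and resizes image/mask pairs to the segmentation network's input
geometry (images with a smooth interpolant, masks with nearest-neighbour
plus re-binarization so they stay strictly boolean).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "SampleRecord",
    "LabeledSample",
    "scan_dataset",
    "load_and_merge",
    "resize_pair",
    "load_image",
    "load_mask",
]

_CLASSES = ("normal", "benign", "malignant")
_MASK_RE = re.compile(r"^(?P<stem>.*)_mask(?:_\d+)?$")


@dataclass(frozen=True)
class SampleRecord:
    """One image plus the ordered list of its mask files."""

    image_path: str
    mask_paths: tuple[str, ...]
    class_label: str

    def __post_init__(self) -> None:
        if len(self.mask_paths) < 1:
            raise ValueError(f"sample {self.image_path} has no mask files")
        if self.class_label not in _CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")


@dataclass(frozen=True)
class LabeledSample:
    """In-memory pair: image in [0,1] and a boolean mask of equal shape."""

    image: np.ndarray
    mask: np.ndarray
    class_label: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if self.mask.dtype != bool:
            raise ValueError("mask must be strictly boolean")


def load_image(path: str) -> np.ndarray:
    """Load a grayscale image scaled to [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def load_mask(path: str) -> np.ndarray:
    """Load a mask file, binarized by value > 0 (files may store 1 or 255)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def scan_dataset(root_dir: str) -> list[SampleRecord]:
    """Scan a dataset root into sample records, lexicographic by image path.

    Every non-mask PNG is an image and must have at least one companion file
    sharing its stem with a ``_mask``/``_mask_<n>`` suffix; an image without
    one is reported as an orphan.  Class comes from the folder name and is
    cross-checked against the filename prefix.
    """
    if not os.path.isdir(root_dir):
        raise FileNotFoundError(f"dataset root {root_dir!r} does not exist")
    class_dirs = sorted(
        d for d in os.listdir(root_dir) if os.path.isdir(os.path.join(root_dir, d))
    )
    unknown = [d for d in class_dirs if d not in _CLASSES]
    if unknown:
        raise ValueError(f"unknown class folder(s) {unknown} under {root_dir!r}")
    if not class_dirs:
        raise ValueError(f"no class folders found under {root_dir!r}")

    records: list[SampleRecord] = []
    for cls in class_dirs:
        cdir = os.path.join(root_dir, cls)
        files = sorted(f for f in os.listdir(cdir) if f.lower().endswith(".png"))
        stems = {}
        masks: dict[str, list[str]] = {}
        for f in files:
            stem = os.path.splitext(f)[0]
            m = _MASK_RE.match(stem)
            if m:
                masks.setdefault(m.group("stem"), []).append(os.path.join(cdir, f))
            else:
                stems[stem] = os.path.join(cdir, f)
        for stem in sorted(stems):
            if stem not in masks:
                raise ValueError(f"image {stems[stem]!r} has no mask files (orphan)")
            if not stem.startswith(cls):
                raise ValueError(
                    f"filename {stem!r} inconsistent with class folder {cls!r}"
                )
            records.append(
                SampleRecord(
                    image_path=stems[stem],
                    mask_paths=tuple(sorted(masks[stem])),
                    class_label=cls,
                )
            )
    records.sort(key=lambda r: r.image_path)
    return records


def load_and_merge(record: SampleRecord) -> LabeledSample:
    """Load a record, OR-merging all its mask files into one boolean mask."""
    image = load_image(record.image_path)
    merged = np.zeros(image.shape, dtype=bool)
    for mp in record.mask_paths:
        m = load_mask(mp)
        if m.shape != image.shape:
            raise ValueError(
                f"mask {mp!r} shape {m.shape} != image shape {image.shape}"
            )
        merged |= m
    stem = os.path.splitext(os.path.basename(record.image_path))[0]
    return LabeledSample(
        image=image, mask=merged, class_label=record.class_label, sample_id=stem
    )


def resize_pair(sample: LabeledSample, target: tuple[int, int]) -> LabeledSample:
    """Resize an image/mask pair; bilinear for the image, nearest + re-binarize
    for the mask (no gray halos may become spurious foreground)."""
    H, W = target
    if H <= 0 or W <= 0:
        raise ValueError("target size must be positive")
    if sample.image.shape == (H, W):
        return sample
    image = _sk_resize(
        sample.image, (H, W), order=1, mode="edge", anti_aliasing=True,
        preserve_range=True,
    )
    mask = _sk_resize(
        sample.mask.astype(np.uint8), (H, W), order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ) > 0
    return replace(sample, image=np.clip(image, 0.0, 1.0), mask=mask)
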