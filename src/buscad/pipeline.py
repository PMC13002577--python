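"""End-to-end two-stage decision path for a single image.

Stage 1 predicts a binary lesion mask; an entirely empty mask classifies the
case as *normal* and stops.  Otherwise the mask's shape features are
extracted and the linear SVM issues a benign/malignant verdict.  Every
intermediate artefact (mask, features, decision value) is kept on the
returned record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import svm as _svm
from .geometry import ShapeFeatures, extract_features
from .unet import SegModel, gate_normal, predict_mask

__all__ = ["Diagnosis", "run_two_stage"]


@dataclass(frozen=True)
class Diagnosis:
    """Per-image outcome of the two-stage pipeline.

    ``verdict == "normal"`` iff the empty-mask gate fired, in which case no
    features or decision value exist.
    """

    sample_id: str
    verdict: str  # normal | benign | malignant
    mask: np.ndarray
    features: ShapeFeatures | None
    decision_value: float | None

    def __post_init__(self) -> None:
        if self.verdict not in ("normal", "benign", "malignant"):
            raise ValueError(f"invalid verdict {self.verdict!r}")
        gate_fired = self.verdict == "normal"
        if gate_fired != (self.features is None) or gate_fired != (self.decision_value is None):
            raise ValueError("features/decision must be absent iff verdict is normal")


def run_two_stage(seg_model: SegModel, svm_model: "_svm.SvmModel", image: np.ndarray,
                  sample_id: str = "", min_area: int = 0,
                  oracle_mask: np.ndarray | None = None) -> Diagnosis:
    """Diagnose one grayscale image.

    ``oracle_mask`` bypasses the segmenter (ground-truth injection for stage
    isolation); the gate and classifier still run unchanged.
    """
    mask = oracle_mask if oracle_mask is not None else predict_mask(seg_model, image)
    if gate_normal(mask, min_area=min_area):
        return Diagnosis(sample_id=sample_id, verdict="normal", mask=mask,
                         features=None, decision_value=None)
    feats = extract_features(mask)
    verdict, decision = _svm.predict(svm_model, feats)
    return Diagnosis(sample_id=sample_id, verdict=verdict, mask=mask,
                     features=feats, decision_value=decision)
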