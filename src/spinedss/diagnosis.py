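"""Herniation diagnosis from the posterior-half disc ROI.

The ROI is an oriented rectangle whose long side is the segment between
two adjacent vertebra centers and whose short side is a fixed 44-pixel
strip extending from that line in the dorsal direction — herniated
material protrudes posteriorly, so the strip covers the posterior disc
margin and anything extruded beyond it. The reference classifier feeds the
shared 572-dimensional HPI+LBP+PHOG descriptor into a logistic
(perceptron) head; any model honoring the same interface (e.g. a CNN) can
replace it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from ._geometry import perp, rect_corners, sample_oriented_rect, unit
from .exceptions import NotTrainedError, TrainingError, ValidationError
from .pfirrmann import build_feature_vector

__all__ = [
    "RoiConfig",
    "DiscROI",
    "DiagnosisModel",
    "crop_disc_roi",
    "train_diagnosis_model",
    "classify_herniation",
    "HERNIATED",
    "NORMAL",
]

HERNIATED = "herniated"
NORMAL = "normal"


@dataclass(frozen=True)
class RoiConfig:
    """Posterior-strip geometry: 44 px short side by default."""

    strip_width_px: int = 44
    output_size: tuple = (64, 44)  # (rows along the segment, cols dorsally)
    dorsal_direction: tuple = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.strip_width_px <= 0:
            raise ValidationError("strip_width_px must be positive")
        d = np.asarray(self.dorsal_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise ValidationError("dorsal_direction must have unit norm")


@dataclass(frozen=True)
class DiscROI:
    patch: np.ndarray
    source_rect: np.ndarray  # 4 corner points in source coordinates
    level_index: int = 0


def crop_disc_roi(
    image: np.ndarray, p_upper, p_lower, cfg: RoiConfig | None = None, level_index: int = 0
) -> DiscROI:
    """Crop the posterior disc strip between two adjacent vertebra centers.

    The rectangle's long side is the full segment ``p_upper -> p_lower``;
    the short side extends ``strip_width_px`` from that line toward the
    dorsal direction (its component perpendicular to the segment). Pixels
    outside the image are zero-padded; resampling is bilinear.
    """
    cfg = cfg or RoiConfig()
    p0 = np.asarray(p_upper, dtype=float)
    p1 = np.asarray(p_lower, dtype=float)
    if np.allclose(p0, p1):
        raise ValidationError("ROI endpoints must be distinct")
    u = unit(p1 - p0)
    dorsal = np.asarray(cfg.dorsal_direction, dtype=float)
    v_raw = dorsal - np.dot(dorsal, u) * u  # dorsal component normal to the segment
    if np.linalg.norm(v_raw) < 1e-9:
        raise ValidationError("dorsal direction is parallel to the segment")
    v = unit(v_raw)
    length = float(np.linalg.norm(p1 - p0))
    patch = sample_oriented_rect(
        np.asarray(image, dtype=float),
        p0,
        u,
        v,
        length,
        float(cfg.strip_width_px),
        tuple(cfg.output_size),
    )
    corners = rect_corners(p0, u, v, length, float(cfg.strip_width_px))
    return DiscROI(patch=patch, source_rect=corners, level_index=level_index)


@dataclass
class DiagnosisModel:
    """Reference binary classifier: shared feature stack + logistic head."""

    scaler: StandardScaler | None = None
    head: LogisticRegression | None = None
    seed: int = 0

    @property
    def trained(self) -> bool:
        return self.scaler is not None and self.head is not None


def _features(rois) -> np.ndarray:
    return np.asarray(
        [build_feature_vector(r.patch if isinstance(r, DiscROI) else r).values for r in rois]
    )


def train_diagnosis_model(rois, labels, seed: int = 0) -> DiagnosisModel:
    """Train the reference herniation classifier on labelled ROIs.

    ``labels`` are booleans (True = herniated) or the strings
    ``"herniated"`` / ``"normal"``. Both classes must be present.
    """
    y = np.asarray(
        [
            bool(lab) if not isinstance(lab, str) else lab == HERNIATED
            for lab in labels
        ]
    )
    if len(set(y.tolist())) < 2:
        raise TrainingError("both herniated and normal examples are required")
    x = _features(rois)
    if x.shape[0] != y.shape[0]:
        raise ValidationError("one label per ROI required")
    scaler = StandardScaler().fit(x)
    head = LogisticRegression(max_iter=2000, random_state=seed)
    head.fit(scaler.transform(x), y.astype(int))
    return DiagnosisModel(scaler=scaler, head=head, seed=seed)


def classify_herniation(roi, model: DiagnosisModel) -> tuple[str, float]:
    """Label an ROI herniated/normal; the score is P(herniated).

    Degenerate-input rule: a constant patch (e.g. an all-zero crop that
    fell outside the image) carries no disc structure and is labelled
    normal with score 0 rather than extrapolating the model beyond its
    feature distribution.
    """
    if not isinstance(model, DiagnosisModel) or not model.trained:
        raise NotTrainedError("diagnosis model has not been trained")
    patch = roi.patch if isinstance(roi, DiscROI) else np.asarray(roi)
    if float(np.ptp(patch)) == 0.0:
        return NORMAL, 0.0
    x = _features([roi])
    score = float(model.head.predict_proba(model.scaler.transform(x))[0, 1])
    return (HERNIATED if score >= 0.5 else NORMAL), score
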