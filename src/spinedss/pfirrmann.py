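"""Pfirrmann grading from hand-crafted texture features and an MLP.

A disc crop is described by three normalized descriptors concatenated into
a single 572-dimensional vector:

* HPI (64 bins): histogram of pixel intensity over [0, 255] — degeneration
  means T2 water loss, so the disc darkens and the histogram shifts left;
* LBP (256 bins): 8-neighbor local binary pattern code histogram, a local
  texture descriptor (ties compare neighbor >= center; border excluded);
* PHOG (252 = 12 orientation bins x 21 pyramid cells): magnitude-weighted
  unsigned gradient-orientation histograms over pyramid levels 0-2, a
  shape descriptor.

Each block is normalized to sum 1 at extraction; at model input every
dimension is additionally z-scored with statistics fitted on the training
set. The classifier is a 572-300-150-5 multi-layer perceptron trained by
mini-batch stochastic gradient descent. The block split 64+256+252 is an
implementation convention (recorded in model metadata); alternatives with
the same total are admissible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from ._geometry import perp, sample_oriented_rect, unit
from .exceptions import NotTrainedError, TrainingError, ValidationError

__all__ = [
    "BLOCK_SPANS",
    "FEATURE_LENGTH",
    "FeatureVector572",
    "MlpConfig",
    "PfirrmannModel",
    "extract_hpi",
    "extract_lbp",
    "extract_phog",
    "build_feature_vector",
    "crop_pfirrmann_roi",
    "train_pfirrmann",
    "predict_pfirrmann",
]

BLOCK_SPANS = {"hpi": 64, "lbp": 256, "phog": 252}
FEATURE_LENGTH = 572

#: 8-neighbor offsets (dy, dx), bit k for neighbor k: E, NE, N, NW, W, SW, S, SE.
#: A 180-degree patch rotation maps bit k to bit (k + 4) mod 8.
_LBP_OFFSETS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class FeatureVector572:
    """Concatenated HPI + LBP + PHOG descriptor (length exactly 572)."""

    values: np.ndarray
    block_spans: tuple = (64, 256, 252)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (FEATURE_LENGTH,):
            raise ValidationError(
                f"feature vector must have length {FEATURE_LENGTH}, got {v.shape}"
            )
        if sum(self.block_spans) != FEATURE_LENGTH:
            raise ValidationError("block spans must sum to 572")
        object.__setattr__(self, "values", v)

    @property
    def hpi(self) -> np.ndarray:
        return self.values[: self.block_spans[0]]

    @property
    def lbp(self) -> np.ndarray:
        a = self.block_spans[0]
        return self.values[a : a + self.block_spans[1]]

    @property
    def phog(self) -> np.ndarray:
        return self.values[self.block_spans[0] + self.block_spans[1] :]


def extract_hpi(patch: np.ndarray, bins: int = 64) -> np.ndarray:
    """Intensity histogram over [0, 255] with equal-width bins, sum 1."""
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValidationError("cannot extract HPI from an empty patch")
    hist, _ = np.histogram(patch, bins=bins, range=(0.0, 256.0))
    return hist / hist.sum()


def extract_lbp(patch: np.ndarray) -> np.ndarray:
    """256-bin histogram of 8-neighbor LBP codes, borders excluded, sum 1."""
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] < 3 or patch.shape[1] < 3:
        raise ValidationError("LBP needs a patch of at least 3x3")
    center = patch[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.uint16)
    for k, (dy, dx) in enumerate(_LBP_OFFSETS):
        neighbor = patch[1 + dy : patch.shape[0] - 1 + dy, 1 + dx : patch.shape[1] - 1 + dx]
        codes |= ((neighbor >= center).astype(np.uint16)) << k
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


def _phog_cell_hist(gx, gy, bins: int) -> np.ndarray:
    mag = np.hypot(gx, gy)
    ang = np.mod(np.degrees(np.arctan2(gy, gx)), 180.0)
    idx = np.minimum((ang / (180.0 / bins)).astype(int), bins - 1)
    return np.bincount(idx.ravel(), weights=mag.ravel(), minlength=bins)


def extract_phog(patch: np.ndarray, bins: int = 12, levels: int = 3) -> np.ndarray:
    """Pyramid histogram of oriented gradients: 12 bins x (1+4+16) cells.

    Orientations are unsigned in [0, 180); histograms are magnitude
    weighted, concatenated level by level (row-major cells within a level)
    and normalized to sum 1. A gradient-free (constant) patch maps to the
    uniform vector.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 8:
        raise ValidationError("PHOG needs a patch of at least 8x8")
    gy, gx = np.gradient(patch)
    parts = []
    for level in range(levels):
        n = 2**level
        ys = np.linspace(0, patch.shape[0], n + 1, dtype=int)
        xs = np.linspace(0, patch.shape[1], n + 1, dtype=int)
        for i in range(n):
            for j in range(n):
                parts.append(
                    _phog_cell_hist(
                        gx[ys[i] : ys[i + 1], xs[j] : xs[j + 1]],
                        gy[ys[i] : ys[i + 1], xs[j] : xs[j + 1]],
                        bins,
                    )
                )
    vec = np.concatenate(parts)
    total = vec.sum()
    if total == 0.0:
        return np.full(vec.shape, 1.0 / vec.size)
    return vec / total


def build_feature_vector(patch: np.ndarray) -> FeatureVector572:
    """HPI, LBP and PHOG blocks concatenated in fixed order (64+256+252)."""
    return FeatureVector572(
        values=np.concatenate(
            [extract_hpi(patch), extract_lbp(patch), extract_phog(patch)]
        )
    )


def crop_pfirrmann_roi(
    image: np.ndarray,
    p_upper,
    p_lower,
    out_shape: tuple[int, int] = (48, 96),
    span_factor: float = 1.5,
) -> np.ndarray:
    """Oriented disc crop between two adjacent vertebra centers.

    The rectangle is centered between the centers; its width (along the
    inter-center line) equals the inter-center distance, and its long axis
    (perpendicular, spanning the disc) is ``span_factor`` times that.
    Resampled to ``out_shape`` = (rows along the inter-center direction,
    columns along the disc span); default 48x96.
    """
    p0 = np.asarray(p_upper, dtype=float)
    p1 = np.asarray(p_lower, dtype=float)
    if np.allclose(p0, p1):
        raise ValidationError("vertebra centers must be distinct")
    u = unit(p1 - p0)  # inter-center direction
    v = perp(u)  # disc-span direction
    dist = float(np.linalg.norm(p1 - p0))
    span = span_factor * dist
    center = (p0 + p1) / 2.0
    origin = center - (dist / 2.0) * u - (span / 2.0) * v
    rows, cols = out_shape
    return sample_oriented_rect(
        np.asarray(image, dtype=float), origin, u, v, dist, span, (rows, cols)
    ).astype(float)


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MlpConfig:
    """Architecture fixed at 572-300-150-5; optimizer settings configurable."""

    layer_sizes: tuple = (572, 300, 150, 5)
    activation: str = "relu"
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.layer_sizes) != (572, 300, 150, 5):
            raise ValidationError("layer_sizes are fixed to (572, 300, 150, 5)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if not 0 <= self.momentum < 1:
            raise ValidationError("momentum must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")


GRADES = (1, 2, 3, 4, 5)
ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}


@dataclass
class PfirrmannModel:
    """Trained grading model: z-scoring statistics + the MLP."""

    config: MlpConfig
    scaler: StandardScaler | None = None
    mlp: MLPClassifier | None = None
    block_spans: tuple = (64, 256, 252)
    loss_curve: tuple = field(default=(), repr=False)

    @property
    def trained(self) -> bool:
        return self.scaler is not None and self.mlp is not None


def _as_matrix(features) -> np.ndarray:
    rows = [
        f.values if isinstance(f, FeatureVector572) else np.asarray(f, dtype=float)
        for f in features
    ]
    x = np.asarray(rows, dtype=float)
    if x.ndim != 2 or x.shape[1] != FEATURE_LENGTH:
        raise ValidationError("features must be (n, 572)")
    return x


def train_pfirrmann(features, labels, cfg: MlpConfig | None = None) -> PfirrmannModel:
    """Train the 572-300-150-5 MLP with seeded mini-batch SGD.

    All five grades must be present in ``labels``; training is a pure
    function of (data, config, seed).
    """
    cfg = cfg or MlpConfig()
    x = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if y.shape != (x.shape[0],):
        raise ValidationError("one label per feature vector required")
    missing = sorted(set(GRADES) - set(y.tolist()))
    if missing:
        raise TrainingError(
            f"training data is missing Pfirrmann grade(s): {missing}"
        )
    scaler = StandardScaler().fit(x)
    mlp = MLPClassifier(
        hidden_layer_sizes=tuple(cfg.layer_sizes[1:-1]),
        activation=cfg.activation,
        solver="sgd",
        learning_rate_init=cfg.learning_rate,
        momentum=cfg.momentum,
        nesterovs_momentum=False,
        batch_size=cfg.batch_size,
        max_iter=cfg.epochs,
        shuffle=True,
        random_state=cfg.seed,
        alpha=1e-4,
        tol=1e-6,
        n_iter_no_change=cfg.epochs,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ConvergenceWarning at fixed epoch budget
        mlp.fit(scaler.transform(x), y)
    return PfirrmannModel(
        config=cfg,
        scaler=scaler,
        mlp=mlp,
        loss_curve=tuple(mlp.loss_curve_),
    )


def predict_pfirrmann(model: PfirrmannModel, fv) -> tuple[int, np.ndarray]:
    """Predicted grade (argmax, lowest grade on ties) and 5-class probabilities."""
    if not isinstance(model, PfirrmannModel) or not model.trained:
        raise NotTrainedError("Pfirrmann model has not been trained")
    x = _as_matrix([fv])
    proba = model.mlp.predict_proba(model.scaler.transform(x))[0]
    classes = np.asarray(model.mlp.classes_)
    order = np.argsort(classes)
    proba = proba[order]
    grade = int(classes[order][int(np.argmax(proba))])
    return grade, proba
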