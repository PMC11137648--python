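"""Vertebra localization on sagittal slices and anatomical chain repair.

Vertebral bodies (not discs) are detected because they carry stronger image
features; any detector honoring the ``callable(image) -> DetectorResult``
contract can be plugged in, and the bundled reference detector is a
classical bright-blob finder tuned to the phantoms. The centers form an
ordered cranial-to-caudal point chain P1..Pn.

Because lumbar mobility is limited, a detected chain must satisfy two
anatomical constraints at every interior point Pi:

* distance: ``lambda1 < Vi / Vi-1 < lambda2`` where ``Vi = |Pi+1 - Pi|``;
* angle: the angle at Pi between Pi->Pi-1 and Pi->Pi+1 lies in
  ``(theta1, theta2]`` degrees.

Defaults are lambda1=0.6, lambda2=1.25, theta1=140, theta2=180. A point
violating either constraint (as the shared vertex) is deviant and is
replaced from its trusted neighbors: midpoint interpolation when both
neighbors are clean, linear extrapolation from the nearest clean pair
otherwise, iterated to a fixed point. The upper angle bound is inclusive
because a perfectly straight chain (exactly 180 degrees) is the anatomical
ideal, not a violation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import (
    ChainTooShortError,
    DegenerateGeometryError,
    UnitError,
    UnrepairableChainError,
    ValidationError,
)

__all__ = [
    "PointChain",
    "ConstraintConfig",
    "DetectorResult",
    "RepairResult",
    "MatchResult",
    "BlobDetector",
    "detect_vertebrae",
    "segment_length",
    "distance_ok",
    "angle_at",
    "find_deviant_points",
    "repair_chain",
    "localization_sensitivity",
]


@dataclass(frozen=True)
class PointChain:
    """Ordered vertebra-center points, cranial to caudal, in pixel coords."""

    points: tuple
    pixel_spacing_mm: float | None = 0.2646

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)

    def replace_point(self, i: int, point) -> "PointChain":
        pts = list(self.points)
        pts[i - 1] = (float(point[0]), float(point[1]))
        return PointChain(points=tuple(pts), pixel_spacing_mm=self.pixel_spacing_mm)


@dataclass(frozen=True)
class ConstraintConfig:
    """Bounds for the distance-ratio and angle constraints."""

    lambda1: float = 0.6
    lambda2: float = 1.25
    theta1_deg: float = 140.0
    theta2_deg: float = 180.0
    max_repair_iters: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.lambda1 < 1 < self.lambda2:
            raise ValidationError("need 0 < lambda1 < 1 < lambda2")
        if not 0 < self.theta1_deg < self.theta2_deg <= 180:
            raise ValidationError("need 0 < theta1 < theta2 <= 180 degrees")
        if self.max_repair_iters < 1:
            raise ValidationError("max_repair_iters must be >= 1")


@dataclass(frozen=True)
class DetectorResult:
    """Axis-aligned boxes with scores, and their centers as candidates."""

    boxes: tuple  # (x0, y0, x1, y1) per box
    scores: tuple  # confidence in [0, 1] per box
    points: tuple  # box centers (x, y), sorted cranial -> caudal

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.points) or len(self.boxes) != len(self.scores):
            raise ValidationError("one point and one score per box required")
        if any(not 0.0 <= s <= 1.0 for s in self.scores):
            raise ValidationError("scores must lie in [0, 1]")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlobDetector:
    """Reference vertebra detector: smooth, threshold, connected components.

    Tuned to the phantom appearance (vertebral bodies brighter than any
    disc); size and aspect filters reject nucleus fragments and noise.
    """

    threshold: float = 245.0
    smooth_sigma: float = 1.5
    min_area: float = 1000.0
    max_area: float = 30000.0
    max_aspect: float = 3.0

    def __call__(self, image: np.ndarray) -> DetectorResult:
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValidationError("detector expects a single-channel 2-D image")
        smoothed = ndimage.gaussian_filter(image, self.smooth_sigma)
        fg = smoothed > self.threshold
        labels, n = ndimage.label(fg)
        boxes, scores, points = [], [], []
        for sl in ndimage.find_objects(labels):
            if sl is None:
                continue
            h = sl[0].stop - sl[0].start
            w = sl[1].stop - sl[1].start
            region = labels[sl] > 0
            area = int(region.sum())
            if not self.min_area <= area <= self.max_area:
                continue
            aspect = max(h, w) / max(min(h, w), 1)
            if aspect > self.max_aspect:
                continue
            ys, xs = np.nonzero(region)
            cx = float(xs.mean() + sl[1].start)
            cy = float(ys.mean() + sl[0].start)
            boxes.append((float(sl[1].start), float(sl[0].start), float(sl[1].stop), float(sl[0].stop)))
            scores.append(float(np.clip(smoothed[sl][region].mean() / 255.0, 0.0, 1.0)))
            points.append((cx, cy))
        order = np.argsort([p[1] for p in points]) if points else []
        return DetectorResult(
            boxes=tuple(boxes[i] for i in order),
            scores=tuple(scores[i] for i in order),
            points=tuple(points[i] for i in order),
        )


def detect_vertebrae(image: np.ndarray, detector=None) -> DetectorResult:
    """Run a (pluggable) vertebra detector; candidates sorted cranial->caudal."""
    if detector is None:
        detector = BlobDetector()
    result = detector(np.asarray(image))
    if len(result.points) < 3:
        raise ChainTooShortError(
            f"only {len(result.points)} vertebra candidates found; need >= 3"
        )
    return result


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def segment_length(chain: PointChain, i: int) -> float:
    """Euclidean length Vi = |P(i+1) - Pi| in pixels (1-based i)."""
    n = len(chain)
    if not 1 <= i <= n - 1:
        raise IndexError(f"segment index {i} out of range 1..{n - 1}")
    (x0, y0), (x1, y1) = chain.points[i - 1], chain.points[i]
    return math.hypot(x1 - x0, y1 - y0)


def distance_ok(chain: PointChain, i: int, cfg: ConstraintConfig | None = None) -> bool:
    """True iff lambda1 < Vi / V(i-1) < lambda2 strictly (1-based interior i)."""
    cfg = cfg or ConstraintConfig()
    n = len(chain)
    if not 2 <= i <= n - 1:
        raise IndexError(f"distance constraint needs 2 <= i <= {n - 1}, got {i}")
    v_prev = segment_length(chain, i - 1)
    if v_prev == 0.0:
        raise DegenerateGeometryError(f"segment V{i - 1} has zero length")
    ratio = segment_length(chain, i) / v_prev
    return cfg.lambda1 < ratio < cfg.lambda2


def angle_at(chain: PointChain, i: int) -> float:
    """Angle in degrees at Pi between Pi->P(i-1) and Pi->P(i+1) (1-based)."""
    n = len(chain)
    if not 2 <= i <= n - 1:
        raise IndexError(f"angle needs an interior index 2 <= i <= {n - 1}, got {i}")
    p = chain.as_array()
    u = p[i - 2] - p[i - 1]
    v = p[i] - p[i - 1]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError(f"zero-length segment adjacent to P{i}")
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def angle_ok(chain: PointChain, i: int, cfg: ConstraintConfig | None = None) -> bool:
    """True iff theta1 < angle at Pi <= theta2 (inclusive upper bound)."""
    cfg = cfg or ConstraintConfig()
    ang = angle_at(chain, i)
    return cfg.theta1_deg < ang <= cfg.theta2_deg


def _endpoint_deviant(chain: PointChain, i: int, cfg: ConstraintConfig) -> bool:
    """Endpoints are deviant when their single segment departs from the
    median segment length by more than the lambda band."""
    n = len(chain)
    lengths = [segment_length(chain, k) for k in range(1, n)]
    med = float(np.median(lengths))
    if med == 0.0:
        return False
    v = lengths[0] if i == 1 else lengths[-1]
    return not cfg.lambda1 < v / med < cfg.lambda2


def find_deviant_points(chain: PointChain, cfg: ConstraintConfig | None = None) -> set:
    """1-based indices of points violating a constraint as the shared vertex."""
    cfg = cfg or ConstraintConfig()
    n = len(chain)
    if n < 3:
        raise ChainTooShortError("constraint evaluation needs at least 3 points")
    deviant: set[int] = set()
    for i in range(2, n):
        try:
            if not distance_ok(chain, i, cfg) or not angle_ok(chain, i, cfg):
                deviant.add(i)
        except DegenerateGeometryError:
            deviant.add(i)
    for i in (1, n):
        if _endpoint_deviant(chain, i, cfg):
            deviant.add(i)
    return deviant


# ---------------------------------------------------------------------------
# repair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepairResult:
    chain: PointChain
    repaired_indices: tuple
    converged: bool


def _deviant_runs(deviant: set, n: int) -> list:
    """Maximal contiguous runs of deviant 1-based indices, as (a, b) pairs."""
    runs = []
    i = 1
    while i <= n:
        if i in deviant:
            a = i
            while i + 1 <= n and i + 1 in deviant:
                i += 1
            runs.append((a, i))
        i += 1
    return runs


def _repair_run(current: PointChain, a: int, b: int, n: int) -> PointChain | None:
    """Reposition the deviant run P_a..P_b from the bracketing clean points.

    A displaced point contaminates the distance ratios of its neighbors, so
    deviant indices come in contiguous runs around the true outlier. A run
    bracketed by clean points is re-spaced evenly along the segment between
    them (a single-point run reduces to the midpoint of its neighbors); a
    run touching an end of the chain is extrapolated point by point from
    the nearest clean pair. Returns None when no rule applies.
    """
    points = current.as_array()
    if a > 1 and b < n:
        p0, p1 = points[a - 2], points[b]
        k = b - a + 2  # segments spanned between the anchors
        for j, i in enumerate(range(a, b + 1), start=1):
            current = current.replace_point(i, p0 + (j / k) * (p1 - p0))
        return current
    if a == 1 and b + 2 <= n:
        for i in range(b, 0, -1):  # caudal clean pair, walking cranially
            points = current.as_array()
            current = current.replace_point(i, 2 * points[i] - points[i + 1])
        return current
    if b == n and a - 2 >= 1:
        for i in range(a, n + 1):  # cranial clean pair, walking caudally
            points = current.as_array()
            current = current.replace_point(i, 2 * points[i - 2] - points[i - 3])
        return current
    return None


def repair_chain(
    chain: PointChain, cfg: ConstraintConfig | None = None
) -> RepairResult:
    """Replace anatomically implausible points from their trusted neighbors.

    Iterates until every point satisfies the constraints or
    ``cfg.max_repair_iters`` is reached (then ``converged`` is False).
    Non-deviant points are never moved. Raises
    :class:`UnrepairableChainError` when no clean reference points remain.
    """
    cfg = cfg or ConstraintConfig()
    n = len(chain)
    if n < 4:
        raise ChainTooShortError("chain repair needs at least 4 points")
    current = chain
    repaired: set[int] = set()
    converged = False
    for _ in range(cfg.max_repair_iters):
        deviant = find_deviant_points(current, cfg)
        if not deviant:
            converged = True
            break
        if len(deviant) == n:
            raise UnrepairableChainError(
                "every point violates the constraints; no reference points remain"
            )
        # An endpoint whose neighbor is itself deviant is only flagged through
        # that neighbor's segment; defer it until the interior is clean so a
        # healthy endpoint is not dragged into a long extrapolation.
        effective = set(deviant)
        if 1 in effective and 2 in effective and len(effective) < n:
            effective.discard(1)
        if n in effective and n - 1 in effective and len(effective) < n:
            effective.discard(n)
        if not effective:
            effective = set(deviant)
        progressed = False
        for a, b in _deviant_runs(effective, n):
            candidate = _repair_run(current, a, b, n)
            if candidate is not None:
                current = candidate
                repaired.update(range(a, b + 1))
                progressed = True
        if not progressed:
            break
    if not converged:
        converged = not find_deviant_points(current, cfg)
    return RepairResult(
        chain=current,
        repaired_indices=tuple(sorted(repaired)),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    sensitivity: float
    mean_distance_mm: float
    min_distance_mm: float
    max_distance_mm: float
    matches: tuple = field(repr=False, default=())


def localization_sensitivity(
    pred: PointChain, truth: PointChain, threshold_mm: float = 4.0
) -> MatchResult:
    """Fraction of truth points with a predicted point within ``threshold_mm``.

    Matching is greedy one-to-one, nearest pair first. Distance statistics
    are over the matched pairs, in millimetres.
    """
    if len(pred) == 0 or len(truth) == 0:
        raise ValidationError("both chains must be nonempty")
    spacing = truth.pixel_spacing_mm or pred.pixel_spacing_mm
    if spacing is None:
        raise UnitError("pixel_spacing_mm is required to evaluate in millimetres")
    p = pred.as_array()
    t = truth.as_array()
    d = np.linalg.norm(t[:, None, :] - p[None, :, :], axis=2) * spacing
    pairs = sorted(
        ((d[ti, pi], ti, pi) for ti in range(len(t)) for pi in range(len(p)))
    )
    used_t: set[int] = set()
    used_p: set[int] = set()
    matches = []
    for dist, ti, pi in pairs:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matches.append((ti, pi, dist))
    hit = [m for m in matches if m[2] <= threshold_mm]
    dists = [m[2] for m in hit]
    return MatchResult(
        sensitivity=len(hit) / len(t),
        mean_distance_mm=float(np.mean(dists)) if dists else float("nan"),
        min_distance_mm=float(np.min(dists)) if dists else float("nan"),
        max_distance_mm=float(np.max(dists)) if dists else float("nan"),
        matches=tuple(matches),
    )
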