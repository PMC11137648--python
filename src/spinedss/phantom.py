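"""Seeded synthetic lumbar-spine phantoms with exact ground truth.

Two generators emulate the inputs the pipeline consumes:

* :func:`generate_sagittal` — a T2-like sagittal slice: bright vertebral
  bodies along a lordotic arc, intervertebral discs whose brightness and
  internal nucleus/annulus contrast degrade with Pfirrmann grade (water
  loss darkens the disc on T2), grade-5 discs with collapsed height, and
  optional posterior protrusions for herniated discs.
* :func:`generate_axial` — an axial slice through a disc: disc ellipse,
  spinal canal, four articular-process apices, the six MSU marker points,
  and (optionally) a herniation blob whose apex is placed by inverting the
  MSU grid transform so that the planted (size, zone) label is guaranteed
  with a safety margin from every region boundary.

Geometry is procedural (superellipses, arcs); exact analytic ground truth
is the point, not photorealism. Identical config + seed reproduces every
output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GenerationError, ValidationError
from .msu import HerniationMask, MsuLabel, MsuMarkerSet, build_grid, classify_msu

__all__ = [
    "PhantomConfig",
    "DiscGroundTruth",
    "SagittalPhantom",
    "AxialPhantom",
    "generate_sagittal",
    "generate_axial",
    "disc_intensity_for_grade",
]

# appearance constants (8-bit scale)
BACKGROUND = 30.0
VERTEBRA_INTENSITY = 255.0
NUCLEUS_CAP = 238.0  # keeps the brightest nucleus below the vertebra level
VERT_W = 56  # vertebral body width in px at image_size=512
VERT_H = 46  # vertebral body height in px at image_size=512
PROTRUSION_DEPTH = 13  # dorsal semi-axis of the herniation bulge
PROTRUSION_HALF_HEIGHT = 8


def disc_intensity_for_grade(grade: int) -> float:
    """Mean disc intensity for a Pfirrmann grade: 230 - 35*(grade-1)."""
    return 230.0 - 35.0 * (grade - 1)


def _contrast_for_grade(grade: int) -> float:
    """Nucleus/annulus contrast 1 - (grade-1)/4 (lost by grade 5)."""
    return 1.0 - (grade - 1) / 4.0


def _height_factor(grade: int) -> float:
    return 0.6 if grade == 5 else 1.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity-noise and reproducibility settings."""

    image_size: int = 512
    pixel_spacing_mm: float = 0.2646
    n_vertebrae: int = 6
    noise_sigma: float = 8.0
    lordosis_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 128:
            raise ValidationError("image_size must be >= 128")
        if self.pixel_spacing_mm <= 0:
            raise ValidationError("pixel_spacing_mm must be positive")
        if self.n_vertebrae < 3:
            raise ValidationError("n_vertebrae must be >= 3")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be nonnegative")


@dataclass(frozen=True)
class DiscGroundTruth:
    """Per-disc labels: herniation, Pfirrmann grade, MSU size/zone."""

    level_index: int  # 1-based, cranial to caudal
    herniated: bool
    pfirrmann: int
    msu_size: int | None = None
    msu_zone: str | None = None

    def __post_init__(self) -> None:
        if self.pfirrmann not in (1, 2, 3, 4, 5):
            raise ValidationError("pfirrmann grade must be in 1..5")
        has_msu = self.msu_size is not None or self.msu_zone is not None
        if self.herniated != has_msu or (
            self.herniated and (self.msu_size is None or self.msu_zone is None)
        ):
            raise ValidationError("MSU size/zone must be present iff herniated")
        if self.herniated:
            MsuLabel(self.msu_size, self.msu_zone)  # range check

    def as_dict(self) -> dict:
        return {
            "level_index": self.level_index,
            "herniated": self.herniated,
            "pfirrmann": self.pfirrmann,
            "msu_size": self.msu_size,
            "msu_zone": self.msu_zone,
        }


@dataclass(frozen=True)
class SagittalPhantom:
    image: np.ndarray  # uint8
    vertebra_centers: list  # (x, y) float pairs, cranial -> caudal
    dorsal_direction: tuple  # unit vector, dorsal = +x
    discs: list  # DiscGroundTruth
    pixel_spacing_mm: float
    disc_masks: list = field(repr=False, default_factory=list)
    protrusion_masks: list = field(repr=False, default_factory=list)


@dataclass(frozen=True)
class AxialPhantom:
    image: np.ndarray  # uint8
    markers: MsuMarkerSet
    mask_truth: HerniationMask
    msu_truth: MsuLabel | None
    pixel_spacing_mm: float


def _superellipse(xx, yy, cx, cy, rx, ry, power=4.0):
    return (np.abs((xx - cx) / rx) ** power + np.abs((yy - cy) / ry) ** power) <= 1.0


def _finish(canvas: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma > 0:
        canvas = canvas + rng.normal(0.0, sigma, size=canvas.shape)
    return np.clip(canvas, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# sagittal
# ---------------------------------------------------------------------------

def _chain_centers(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Vertebra centers along a gentle lordotic arc, cranial to caudal."""
    n = config.n_vertebrae
    s = config.image_size
    step = 0.72 * s / (n - 1)
    angles = np.deg2rad(
        np.linspace(config.lordosis_deg / 2, -config.lordosis_deg / 2, n - 1)
    )
    pts = [np.zeros(2)]
    for a in angles:
        pts.append(pts[-1] + step * np.array([np.sin(a), np.cos(a)]))
    pts = np.array(pts)
    pts += rng.uniform(-2.0, 2.0, size=pts.shape)  # per-vertebra jitter
    center = (pts.min(axis=0) + pts.max(axis=0)) / 2
    return pts - center + s / 2.0


def generate_sagittal(
    config: PhantomConfig, disc_specs: list[DiscGroundTruth]
) -> SagittalPhantom:
    """Render a sagittal slice with ``n_vertebrae`` bodies and labelled discs.

    ``disc_specs`` must hold exactly ``n_vertebrae - 1`` entries, cranial to
    caudal. Returns the raster plus exact ground truth (vertebra centers,
    per-disc region and protrusion masks).
    """
    if len(disc_specs) != config.n_vertebrae - 1:
        raise ValidationError(
            f"expected {config.n_vertebrae - 1} disc specs, got {len(disc_specs)}"
        )
    rng = np.random.default_rng(config.seed)
    s = config.image_size
    scale = s / 512.0
    vert_w, vert_h = VERT_W * scale, VERT_H * scale
    canvas = np.full((s, s), BACKGROUND, dtype=float)
    xx, yy = np.meshgrid(np.arange(s, dtype=float), np.arange(s, dtype=float))

    centers = _chain_centers(config, rng)
    for cx, cy in centers:
        canvas[_superellipse(xx, yy, cx, cy, vert_w / 2, vert_h / 2)] = (
            VERTEBRA_INTENSITY
        )

    disc_masks, protrusion_masks = [], []
    for spec, (p0, p1) in zip(disc_specs, zip(centers[:-1], centers[1:])):
        dc = (p0 + p1) / 2.0
        gap = float(np.linalg.norm(p1 - p0)) - vert_h
        h_disc = max(gap - 2.0, 6.0) * _height_factor(spec.pfirrmann)
        base = disc_intensity_for_grade(spec.pfirrmann)
        contrast = _contrast_for_grade(spec.pfirrmann)
        annulus_val = base * (1.0 - 0.1 * contrast)
        nucleus_val = min(base * (1.0 + 0.2 * contrast), NUCLEUS_CAP)
        disc = _superellipse(xx, yy, dc[0], dc[1], vert_w / 2, h_disc / 2)
        nucleus = _superellipse(
            xx, yy, dc[0], dc[1], vert_w * 0.275, h_disc * 0.25
        )
        canvas[disc] = annulus_val
        canvas[disc & nucleus] = nucleus_val
        disc_masks.append(disc)

        if spec.herniated:
            x_margin = dc[0] + vert_w / 2  # posterior disc margin (dorsal = +x)
            a = PROTRUSION_DEPTH * scale
            b = min(PROTRUSION_HALF_HEIGHT * scale, h_disc / 2 - 1.0)
            bulge = (
                (((xx - x_margin) / a) ** 2 + ((yy - dc[1]) / b) ** 2 <= 1.0)
                & (xx >= x_margin)
            )
            canvas[bulge] = annulus_val
            protrusion_masks.append(bulge & ~disc)
        else:
            protrusion_masks.append(np.zeros((s, s), dtype=bool))

    image = _finish(canvas, config.noise_sigma, rng)
    return SagittalPhantom(
        image=image,
        vertebra_centers=[(float(x), float(y)) for x, y in centers],
        dorsal_direction=(1.0, 0.0),
        discs=list(disc_specs),
        pixel_spacing_mm=config.pixel_spacing_mm,
        disc_masks=disc_masks,
        protrusion_masks=protrusion_masks,
    )


# ---------------------------------------------------------------------------
# axial
# ---------------------------------------------------------------------------

def _axial_markers(
    config: PhantomConfig, rng: np.random.Generator
) -> MsuMarkerSet:
    s = config.image_size
    scale = s / 512.0
    x0 = s / 2.0 + rng.uniform(-8, 8) * scale
    y_d = 0.37 * s + rng.uniform(-8, 8) * scale
    s0 = (70.0 + rng.uniform(-5, 5)) * scale  # posterior disc margin depth
    s_facet = s0 + (40.0 + rng.uniform(-4, 4)) * scale  # intra-facet line
    s_q = s_facet + (28.0 + rng.uniform(0, 8)) * scale  # dorsal canal point
    t_r = (52.0 + rng.uniform(-5, 5)) * scale
    t_l = -(52.0 + rng.uniform(-5, 5)) * scale
    dy = 5.0 * scale
    dx = 3.0 * scale
    return MsuMarkerSet(
        disc_center=(x0, y_d),
        canal_dorsal=(x0, y_d + s_q),
        facet_sup_left=(x0 + t_l + dx, y_d + s_facet + dy),
        facet_sup_right=(x0 + t_r - dx, y_d + s_facet + dy),
        facet_inf_left=(x0 + t_l - dx, y_d + s_facet - dy),
        facet_inf_right=(x0 + t_r + dx, y_d + s_facet - dy),
        posterior_disc_margin=(x0, y_d + s0),
    )


def _apex_interval(target: MsuLabel, grid, margin: float, rng) -> tuple[float, float]:
    """Sample apex grid coordinates (s_a, t_a) strictly inside the target region."""
    s_bands = {
        1: (grid.s0, grid.s_mid),
        2: (grid.s_mid, grid.s_if),
        3: (grid.s_if, grid.s_if + (grid.s_if - grid.s_mid) * 1.2),
    }
    lo, hi = s_bands[target.size]
    lo, hi = lo + margin, hi - margin
    if hi <= lo:
        raise GenerationError(f"cannot place apex for MSU target {target}: size band too narrow")
    s_a = rng.uniform(lo, hi)

    side = 1 if rng.random() < 0.5 else -1
    t_half = 0.5 * (grid.t_right if side > 0 else -grid.t_left)
    t_full = grid.t_right if side > 0 else -grid.t_left
    if target.zone == "A":
        t_lo, t_hi = 0.5 * grid.t_left + margin, 0.5 * grid.t_right - margin
    elif target.zone == "B":
        t_lo, t_hi = t_half + margin, t_full - margin
    else:
        t_lo, t_hi = t_full + margin, t_full + 16.0 - margin
    if t_hi <= t_lo:
        raise GenerationError(f"cannot place apex for MSU target {target}: zone band too narrow")
    t_a = rng.uniform(t_lo, t_hi)
    if target.zone in ("B", "C") and side < 0:
        t_a = -t_a
    return s_a, t_a


def generate_axial(
    config: PhantomConfig,
    target_msu: tuple[int, str] | MsuLabel | None,
    seed: int | None = None,
) -> AxialPhantom:
    """Render an axial slice; plant a herniation with the requested MSU label.

    When ``target_msu`` is given, the herniation apex is placed by inverting
    the MSU grid transform, at least 3 px inside every boundary of the
    target region, so the planted label is recovered unambiguously by
    :func:`spinedss.msu.classify_msu`. ``seed`` overrides ``config.seed``.
    """
    target = None
    if target_msu is not None:
        target = (
            target_msu
            if isinstance(target_msu, MsuLabel)
            else MsuLabel(size=target_msu[0], zone=target_msu[1])
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    s = config.image_size
    scale = s / 512.0

    last_err: GenerationError | None = None
    for _ in range(20):  # bounded retries over marker jitter
        markers = _axial_markers(config, rng)
        grid = build_grid(markers)
        xx, yy = np.meshgrid(np.arange(s, dtype=float), np.arange(s, dtype=float))
        canvas = np.full((s, s), BACKGROUND, dtype=float)
        x0, y_d = markers.disc_center
        # body cross-section, disc, canal, facet processes
        canvas[
            ((xx - x0) / (0.44 * s)) ** 2 + ((yy - y_d - 0.1 * s) / (0.36 * s)) ** 2
            <= 1.0
        ] = 70.0
        canvas[
            ((xx - x0) / (110.0 * scale)) ** 2 + ((yy - y_d) / grid.s0) ** 2 <= 1.0
        ] = 160.0
        canal_cy = y_d + (grid.s0 + (grid.s_if - grid.s0) * 2.0) / 2.0
        canal_ry = (grid.s_if - grid.s0) * 1.0
        canvas[
            ((xx - x0) / (0.55 * grid.t_right - 0.55 * grid.t_left) * 2) ** 2
            + ((yy - canal_cy) / canal_ry) ** 2
            <= 1.0
        ] = 85.0
        for px, py in (
            markers.facet_sup_left,
            markers.facet_inf_left,
            markers.facet_sup_right,
            markers.facet_inf_right,
        ):
            out = 6.0 * scale * (1 if px > x0 else -1)
            canvas[
                ((xx - px - out) / (9.0 * scale)) ** 2
                + ((yy - py - 4.0 * scale) / (7.0 * scale)) ** 2
                <= 1.0
            ] = 120.0

        mask = np.zeros((s, s), dtype=np.uint8)
        msu_truth = None
        if target is not None:
            try:
                s_a, t_a = _apex_interval(target, grid, margin=3.0 * scale, rng=rng)
            except GenerationError as exc:
                last_err = exc
                continue
            # pointed protrusion: half-ellipse body + 1-px spike to the apex
            x_apex = x0 + t_a  # AP axis is vertical in phantoms
            y_apex = y_d + s_a
            a_body = max(s_a - grid.s0 - 2.0, 1.0)
            b_body = rng.uniform(8.0, 13.0) * scale
            blob = (
                (((yy - y_d - grid.s0) / a_body) ** 2 + ((xx - x_apex) / b_body) ** 2)
                <= 1.0
            ) & (yy >= y_d + grid.s0)
            col = int(round(x_apex))
            y_top = int(np.floor(y_apex))
            y_base = int(np.ceil(y_d + grid.s0))
            blob[y_base : y_top + 1, col] = True
            mask = blob.astype(np.uint8)
            canvas[blob] = 230.0
            msu_truth = classify_msu(
                markers,
                HerniationMask(mask=mask, pixel_spacing_mm=config.pixel_spacing_mm),
            )
            if msu_truth != target:  # should be impossible given the margins
                last_err = GenerationError(
                    f"planted apex did not land in target region {target}"
                )
                continue
        image = _finish(canvas, config.noise_sigma, rng)
        return AxialPhantom(
            image=image,
            markers=markers,
            mask_truth=HerniationMask(
                mask=mask, pixel_spacing_mm=config.pixel_spacing_mm
            ),
            msu_truth=msu_truth,
            pixel_spacing_mm=config.pixel_spacing_mm,
        )
    raise GenerationError(
        f"could not satisfy MSU target {target} after bounded retries: {last_err}"
    )
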