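"""MSU classification of lumbar disc herniation on axial slices.

The MSU scheme grades a herniation's size (1/2/3, by how far it extrudes
posteriorly) and location (A/B/C, central to lateral) from the position of
the herniation apex inside a grid built from six anatomical marker points:
the disc center D, the dorsal point of the spinal canal Q, and the ventral
apices of the left/right superior and inferior articular processes. A
seventh point, the posterior disc margin M on the AP axis, anchors the
origin of the size bands.

Grid construction
-----------------
The anterior-posterior (AP) axis is the line D -> Q; ``s`` denotes the
signed coordinate along it (s = 0 at D, increasing dorsally) and ``t`` the
lateral coordinate perpendicular to it. Per side, the facet reference point
is the midpoint of the superior and inferior apices; the intra-facet line
connects the two reference points and crosses the AP axis at ``s_if``. The
size bands start at the posterior disc margin ``s0``: size 1 reaches half
way to the intra-facet line, size 2 up to it, size 3 beyond it. Lateral
zone boundaries sit at half the facet offsets (A/B) and at the facet
offsets themselves (B/C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._geometry import perp, unit
from .exceptions import (
    DegenerateGeometryError,
    EmptyMaskError,
    ValidationError,
)

__all__ = [
    "MsuMarkerSet",
    "MsuGrid",
    "HerniationMask",
    "MsuLabel",
    "build_grid",
    "segment_herniation",
    "threshold_segmenter",
    "find_apex",
    "classify_msu",
    "classify_apex_coords",
    "rasterize_regions",
]


Point = tuple[float, float]


@dataclass(frozen=True)
class MsuMarkerSet:
    """The six MSU marker points plus the posterior disc margin.

    All points are ``(x, y)`` pixel coordinates on the axial slice.
    """

    disc_center: Point
    canal_dorsal: Point
    facet_sup_left: Point
    facet_sup_right: Point
    facet_inf_left: Point
    facet_inf_right: Point
    posterior_disc_margin: Point

    def __post_init__(self) -> None:
        d = np.asarray(self.disc_center, dtype=float)
        q = np.asarray(self.canal_dorsal, dtype=float)
        if np.allclose(d, q):
            raise ValidationError("disc center and dorsal canal point coincide")
        ap = unit(q - d)
        lat = -perp(ap)  # +t to the image-right of the AP axis
        t_l = float(np.dot(self._mid("left") - d, lat))
        t_r = float(np.dot(self._mid("right") - d, lat))
        if t_l * t_r >= 0:
            raise ValidationError(
                "left and right facet points must lie on opposite sides of the AP axis"
            )
        s_m = float(np.dot(np.asarray(self.posterior_disc_margin, float) - d, ap))
        s_q = float(np.dot(q - d, ap))
        if not 0.0 <= s_m <= s_q:
            raise ValidationError(
                "posterior disc margin must lie between disc center and canal dorsal point"
            )

    def _mid(self, side: str) -> np.ndarray:
        if side == "left":
            a, b = self.facet_sup_left, self.facet_inf_left
        else:
            a, b = self.facet_sup_right, self.facet_inf_right
        return (np.asarray(a, float) + np.asarray(b, float)) / 2.0

    def as_dict(self) -> dict:
        return {
            "D": list(self.disc_center),
            "Q": list(self.canal_dorsal),
            "FsL": list(self.facet_sup_left),
            "FsR": list(self.facet_sup_right),
            "FiL": list(self.facet_inf_left),
            "FiR": list(self.facet_inf_right),
            "M": list(self.posterior_disc_margin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MsuMarkerSet":
        try:
            return cls(
                disc_center=tuple(d["D"]),
                canal_dorsal=tuple(d["Q"]),
                facet_sup_left=tuple(d["FsL"]),
                facet_sup_right=tuple(d["FsR"]),
                facet_inf_left=tuple(d["FiL"]),
                facet_inf_right=tuple(d["FiR"]),
                posterior_disc_margin=tuple(d["M"]),
            )
        except KeyError as exc:
            raise ValidationError(f"marker annotation missing field {exc}") from exc


@dataclass(frozen=True)
class MsuGrid:
    """The (s, t) frame and band boundaries derived from a marker set."""

    origin: tuple[float, float]  # disc center D
    ap_unit: tuple[float, float]  # s axis, D -> Q
    lat_unit: tuple[float, float]  # t axis, +t toward the side with t > 0
    s0: float  # posterior disc margin
    s_if: float  # intra-facet line on the AP axis
    t_left: float  # lateral offset of the left facet reference (< 0)
    t_right: float  # lateral offset of the right facet reference (> 0)

    def to_grid(self, point) -> tuple[float, float]:
        """Map an (x, y) pixel point to (s, t) grid coordinates."""
        p = np.asarray(point, dtype=float) - np.asarray(self.origin)
        return float(np.dot(p, self.ap_unit)), float(np.dot(p, self.lat_unit))

    def to_pixel(self, s: float, t: float) -> tuple[float, float]:
        """Inverse of :meth:`to_grid`."""
        p = (
            np.asarray(self.origin)
            + s * np.asarray(self.ap_unit)
            + t * np.asarray(self.lat_unit)
        )
        return float(p[0]), float(p[1])

    @property
    def s_mid(self) -> float:
        """Size-1/2 boundary, half way from the disc margin to the intra-facet line."""
        return self.s0 + 0.5 * (self.s_if - self.s0)


@dataclass(frozen=True)
class HerniationMask:
    """Binary raster of the herniated area, aligned with the axial image."""

    mask: np.ndarray
    pixel_spacing_mm: float = 0.2646

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValidationError("herniation mask must be a 2-D raster")
        if not np.isin(np.unique(m), (0, 1)).all():
            raise ValidationError("herniation mask values must be 0/1")
        object.__setattr__(self, "mask", m.astype(np.uint8))

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass(frozen=True)
class MsuLabel:
    size: int
    zone: str

    def __post_init__(self) -> None:
        if self.size not in (1, 2, 3):
            raise ValidationError("MSU size must be 1, 2 or 3")
        if self.zone not in ("A", "B", "C"):
            raise ValidationError("MSU zone must be A, B or C")

    def __str__(self) -> str:  # e.g. "2-B"
        return f"{self.size}-{self.zone}"


def build_grid(markers: MsuMarkerSet) -> MsuGrid:
    """Construct the MSU grid from the marker points.

    The per-side facet reference is the midpoint of the superior and
    inferior apices; ``s_if`` is where the line between the two references
    crosses the AP axis. Raises when that line is parallel to the AP axis.
    """
    d = np.asarray(markers.disc_center, dtype=float)
    q = np.asarray(markers.canal_dorsal, dtype=float)
    ap = unit(q - d)
    lat = -perp(ap)
    f_l = markers._mid("left")
    f_r = markers._mid("right")
    s_l, t_l = float(np.dot(f_l - d, ap)), float(np.dot(f_l - d, lat))
    s_r, t_r = float(np.dot(f_r - d, ap)), float(np.dot(f_r - d, lat))
    if t_l > t_r:  # orient +t toward the side whose reference has t > 0
        lat = -lat
        t_l, t_r = -t_l, -t_r
    if abs(t_r - t_l) < 1e-9:
        raise DegenerateGeometryError("intra-facet line is parallel to the AP axis")
    # intersection of the F_L -> F_R line with t = 0
    s_if = s_l + (s_r - s_l) * (0.0 - t_l) / (t_r - t_l)
    s0 = float(
        np.dot(np.asarray(markers.posterior_disc_margin, float) - d, ap)
    )
    if s_if <= s0:
        raise DegenerateGeometryError(
            "intra-facet line must lie dorsal of the posterior disc margin"
        )
    return MsuGrid(
        origin=(float(d[0]), float(d[1])),
        ap_unit=(float(ap[0]), float(ap[1])),
        lat_unit=(float(lat[0]), float(lat[1])),
        s0=s0,
        s_if=float(s_if),
        t_left=t_l,
        t_right=t_r,
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def threshold_segmenter(
    image: np.ndarray, markers: MsuMarkerSet, threshold: float = 180.0
) -> np.ndarray:
    """Reference herniation segmenter.

    Thresholds the band dorsal of the posterior disc margin, keeps the
    largest connected component and fills holes. Any learned segmenter with
    the same ``(image, markers) -> binary mask`` signature can replace it.
    """
    image = np.asarray(image, dtype=float)
    grid = build_grid(markers)
    h, w = image.shape
    xx, yy = np.meshgrid(np.arange(w), np.arange(h))
    rel_x = xx - grid.origin[0]
    rel_y = yy - grid.origin[1]
    s = rel_x * grid.ap_unit[0] + rel_y * grid.ap_unit[1]
    band = s > grid.s0
    fg = band & (image > threshold)
    if not fg.any():
        return np.zeros_like(image, dtype=np.uint8)
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return fg.astype(np.uint8)


def segment_herniation(
    image: np.ndarray,
    markers: MsuMarkerSet,
    segmenter=None,
    pixel_spacing_mm: float = 0.2646,
    expect_nonempty: bool = False,
) -> HerniationMask:
    """Segment the herniated area on an axial slice.

    ``segmenter`` is any callable ``(image, markers) -> binary raster``;
    the default is :func:`threshold_segmenter`. An empty result is legal
    (it warns rather than raises when ``expect_nonempty`` is set, since an
    upstream herniation diagnosis may simply be wrong).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError("axial image must be single-channel 2-D")
    if segmenter is None:
        segmenter = threshold_segmenter
    raw = np.asarray(segmenter(image, markers))
    mask = HerniationMask(mask=(raw > 0).astype(np.uint8), pixel_spacing_mm=pixel_spacing_mm)
    if expect_nonempty and mask.empty:
        warnings.warn(
            "herniation was asserted upstream but the segmenter returned an empty mask",
            stacklevel=2,
        )
    return mask


# ---------------------------------------------------------------------------
# apex extraction and classification
# ---------------------------------------------------------------------------

def find_apex(mask: HerniationMask, grid: MsuGrid) -> tuple[int, int]:
    """The most dorsal mask pixel in grid coordinates.

    Ties on the AP coordinate ``s`` are broken by minimal ``|t|``, then by
    raster order. Returns the pixel as ``(x, y)``.
    """
    m = np.asarray(mask.mask).astype(bool)
    ys, xs = np.nonzero(m)
    if len(xs) == 0:
        raise EmptyMaskError("cannot locate the apex of an empty herniation mask")
    rel_x = xs - grid.origin[0]
    rel_y = ys - grid.origin[1]
    s = rel_x * grid.ap_unit[0] + rel_y * grid.ap_unit[1]
    t = rel_x * grid.lat_unit[0] + rel_y * grid.lat_unit[1]
    raster = ys * m.shape[1] + xs
    order = np.lexsort((raster, np.abs(t), -s))
    k = order[0]
    return int(xs[k]), int(ys[k])


def classify_apex_coords(s_a: float, t_a: float, grid: MsuGrid) -> MsuLabel:
    """Assign the MSU label for an apex at grid coordinates (s_a, t_a).

    Size: 1 up to half way between the disc margin and the intra-facet
    line (inclusive), 2 up to the intra-facet line (inclusive), 3 strictly
    beyond it. Zone: A within half the facet offsets, B out to the facet
    offsets, C beyond; points exactly on a lateral boundary take the more
    lateral zone.
    """
    if s_a <= grid.s_mid:
        size = 1
    elif s_a <= grid.s_if:
        size = 2
    else:
        size = 3
    if t_a <= grid.t_left or t_a >= grid.t_right:
        zone = "C"
    elif t_a <= 0.5 * grid.t_left or t_a >= 0.5 * grid.t_right:
        zone = "B"
    else:
        zone = "A"
    return MsuLabel(size=size, zone=zone)


def classify_msu(markers: MsuMarkerSet, mask: HerniationMask) -> MsuLabel:
    """MSU size/zone label from the marker set and a herniation mask."""
    grid = build_grid(markers)
    apex = find_apex(mask, grid)
    s_a, t_a = grid.to_grid(apex)
    return classify_apex_coords(s_a, t_a, grid)


def rasterize_regions(grid: MsuGrid, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Paint the 9 MSU regions pixel-by-pixel (brute-force region map).

    Returns ``(size_map, zone_map)`` where ``size_map`` holds 1/2/3 and
    ``zone_map`` holds 0/1/2 for A/B/C at every pixel. Deliberately written
    as whole-image comparisons so it can serve as an independent check of
    :func:`classify_apex_coords`.
    """
    h, w = shape
    xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    rel_x = xx - grid.origin[0]
    rel_y = yy - grid.origin[1]
    s = rel_x * grid.ap_unit[0] + rel_y * grid.ap_unit[1]
    t = rel_x * grid.lat_unit[0] + rel_y * grid.lat_unit[1]
    size_map = np.full(shape, 1, dtype=np.int8)
    size_map[s > grid.s_mid] = 2
    size_map[s > grid.s_if] = 3
    zone_map = np.zeros(shape, dtype=np.int8)  # A
    zone_map[(t <= 0.5 * grid.t_left) | (t >= 0.5 * grid.t_right)] = 1  # B
    zone_map[(t <= grid.t_left) | (t >= grid.t_right)] = 2  # C
    return size_map, zone_map
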