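"""Oriented-rectangle resampling shared by the diagnosis and grading crops.

Coordinates are 0-based pixel coordinates, ``(x, y)`` with ``x`` the column
and ``y`` the row. Sampling is bilinear; pixels outside the image are 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateGeometryError, GeometryError


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise DegenerateGeometryError("zero-length vector has no direction")
    return v / n


def perp(v: np.ndarray) -> np.ndarray:
    """Rotate ``v`` by +90 degrees in image convention (y grows downward)."""
    return np.array([-v[1], v[0]], dtype=float)


def sample_oriented_rect(
    image: np.ndarray,
    origin: np.ndarray,
    u_dir: np.ndarray,
    v_dir: np.ndarray,
    length: float,
    width: float,
    out_shape: tuple[int, int],
) -> np.ndarray:
    """Resample the rectangle ``origin + s*u_dir + t*v_dir`` to ``out_shape``.

    ``s`` runs over ``[0, length]`` along rows of the output and ``t`` over
    ``[0, width]`` along columns. Raises :class:`GeometryError` when the
    rectangle lies entirely outside the image.
    """
    image = np.asarray(image, dtype=float)
    u = unit(u_dir)
    v = unit(v_dir)
    rows, cols = out_shape
    s = (np.arange(rows) + 0.5) / rows * length
    t = (np.arange(cols) + 0.5) / cols * width
    ss, tt = np.meshgrid(s, t, indexing="ij")
    xs = origin[0] + ss * u[0] + tt * v[0]
    ys = origin[1] + ss * u[1] + tt * v[1]
    h, w = image.shape
    if xs.max() < -0.5 or xs.min() > w - 0.5 or ys.max() < -0.5 or ys.min() > h - 0.5:
        raise GeometryError("sampling rectangle lies fully outside the image")
    return ndimage.map_coordinates(
        image, np.stack([ys, xs]), order=1, mode="constant", cval=0.0
    )


def rect_corners(
    origin: np.ndarray, u_dir: np.ndarray, v_dir: np.ndarray, length: float, width: float
) -> np.ndarray:
    """Corner points of the same rectangle, in traversal order."""
    u = unit(u_dir)
    v = unit(v_dir)
    o = np.asarray(origin, dtype=float)
    return np.array([o, o + length * u, o + length * u + width * v, o + width * v])
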