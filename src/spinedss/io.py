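"""Readers/writers, annotation schema, dataset-manifest arithmetic, augmentation.

Conventions used everywhere: coordinates are 0-based pixel ``(x, y)`` with
``x`` the column; masks are PNG rasters with foreground 255; images load
as 2-D grayscale with a pixel spacing in mm attached (taken from the DICOM
header when present, else the configured default of 0.2646 mm/px).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
import yaml
from PIL import Image
from skimage import transform as sktransform

from .exceptions import ValidationError

__all__ = [
    "DEFAULT_PIXEL_SPACING_MM",
    "StudyManifest",
    "disc_image_count",
    "read_image",
    "write_image",
    "read_annotation",
    "write_annotation",
    "read_config",
    "write_config",
    "augment",
]

DEFAULT_PIXEL_SPACING_MM = 0.2646


# ---------------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyManifest:
    """Patient/slice/disc bookkeeping for a study cohort."""

    n_patients: int
    slices_per_patient: int
    discs_per_patient: int
    train_patients: int
    test_patients: int

    def __post_init__(self) -> None:
        if min(
            self.n_patients,
            self.slices_per_patient,
            self.discs_per_patient,
            self.train_patients,
            self.test_patients,
        ) < 0:
            raise ValidationError("manifest counts must be nonnegative")
        if self.train_patients + self.test_patients != self.n_patients:
            raise ValidationError("train/test split must partition the patients")


def disc_image_count(m: StudyManifest, subset: str = "all") -> int:
    """patients_in_subset x slices_per_patient x discs_per_patient."""
    patients = {
        "all": m.n_patients,
        "train": m.train_patients,
        "test": m.test_patients,
    }
    if subset not in patients:
        raise ValidationError(f"unknown subset {subset!r}; use all/train/test")
    return patients[subset] * m.slices_per_patient * m.discs_per_patient


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path, default_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM):
    """Load a grayscale raster with its pixel spacing.

    PNG (8/16-bit grayscale; RGB is converted) or single-frame DICOM
    (PixelSpacing honored when present). Returns ``(array, spacing_mm)``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".png", ".jpg", ".jpeg", ".tif", ".tiff"):
        with Image.open(path) as im:
            if im.mode not in ("L", "I;16", "I"):
                im = im.convert("L")
            arr = np.asarray(im)
        return arr, default_spacing_mm
    if suffix in (".dcm", ".dicom", ""):
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ValidationError("only single-frame DICOM images are supported")
        spacing = default_spacing_mm
        if "PixelSpacing" in ds:
            spacing = float(ds.PixelSpacing[0])
        return arr, spacing
    raise ValidationError(f"unsupported image format: {path.suffix!r}")


def write_image(path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale PNG (masks: pass mask*255)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_KNOWN_SCHEMAS = {"points", "markers", "mask", "labels"}


def write_annotation(path, doc: dict) -> None:
    """Write an annotation JSON; unknown fields are preserved verbatim."""
    doc = dict(doc)
    doc.setdefault("schema_version", 1)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_annotation(path) -> dict:
    """Read and schema-check an annotation JSON."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed annotation JSON {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError("annotation root must be a JSON object")
    problems = []
    if "schema_version" not in doc:
        problems.append("schema_version")
    if "points" in doc:
        pts = doc["points"]
        if not isinstance(pts, list) or any(
            not (isinstance(p, list) and len(p) == 2) for p in pts
        ):
            problems.append("points")
    if "pixel_spacing_mm" in doc and not isinstance(
        doc["pixel_spacing_mm"], (int, float)
    ):
        problems.append("pixel_spacing_mm")
    if problems:
        raise ValidationError(
            f"annotation {path} failed schema validation on fields: {problems}"
        )
    return doc


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValidationError("config root must be a mapping")
    return doc


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------

def save_model(path, kind: str, model) -> None:
    """Serialize a trained model as a versioned archive."""
    import joblib

    from . import __version__

    joblib.dump(
        {"format_version": 1, "software_version": __version__, "kind": kind, "model": model},
        Path(path),
    )


def load_model(path, expect_kind: str):
    """Load a model archive, checking its kind."""
    import joblib

    doc = joblib.load(Path(path))
    if not isinstance(doc, dict) or doc.get("format_version") != 1:
        raise ValidationError(f"{path} is not a spinedss model archive")
    if doc.get("kind") != expect_kind:
        raise ValidationError(
            f"model archive holds a {doc.get('kind')!r} model, expected {expect_kind!r}"
        )
    return doc["model"]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _rotate_flip(image: np.ndarray, angle_deg: float, flip: bool) -> np.ndarray:
    out = sktransform.rotate(
        image.astype(float), angle_deg, preserve_range=True, mode="constant", cval=0.0
    )
    if flip:
        out = out[:, ::-1]
    return out


def augment(image: np.ndarray, policy: str, seed: int = 0):
    """Seeded augmentation under the named policy.

    ``localization`` draws minor rotations (+-10 deg), horizontal flips,
    additive Gaussian noise (sigma 0-5) and contrast gains (0.9-1.1);
    ``classification`` is restricted to rotations and flips so the
    diagnostic intensity features are untouched. Returns ``(image, params)``
    with the drawn parameters, so a transform can be reproduced exactly.
    """
    if policy not in ("localization", "classification"):
        raise ValidationError(f"unknown augmentation policy {policy!r}")
    rng = np.random.default_rng(seed)
    image = np.asarray(image, dtype=float)
    params = {
        "policy": policy,
        "angle_deg": float(rng.uniform(-10.0, 10.0)),
        "flip": bool(rng.random() < 0.5),
    }
    out = _rotate_flip(image, params["angle_deg"], params["flip"])
    if policy == "localization":
        params["contrast_gain"] = float(rng.uniform(0.9, 1.1))
        params["noise_sigma"] = float(rng.uniform(0.0, 5.0))
        out = out * params["contrast_gain"]
        out = out + rng.normal(0.0, params["noise_sigma"], size=out.shape)
    out = np.clip(out, 0, 255)
    return out.astype(np.uint8), params
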