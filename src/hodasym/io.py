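"""Reading and writing volumes, landmark/rating tables, and result reports.

Images are NIfTI-1, one 3-D volume per file; on load the image is
reoriented to the closest RAS (right-anterior-superior) axis order so
that "left/right" is unambiguous everywhere downstream.  Ratings and
landmarks are UTF-8 comma-separated tables with a header row; the cohort
report is JSON (machine-readable, value-preserving round trip) with the
per-subject rows additionally available as CSV.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    HeaderError,
    MODALITIES,
    MultiTimepointError,
    RatingRecord,
    ValidationError,
    Volume,
)
from .segmentation import LandmarkSet, SliceLandmarks


# --------------------------------------------------------------------- volumes

def _modality_from_path(path: str) -> Optional[str]:
    stem = os.path.basename(path)
    for ext in (".nii.gz", ".nii"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    tail = stem.rsplit("_", 1)[-1]
    return tail if tail in MODALITIES else None


def read_volume(
    path: str, modality: Optional[str] = None, subject_id: str = ""
) -> Volume:
    """Load a single 3-D NIfTI volume, normalized to RAS axis order.

    ``modality`` may be omitted when the filename ends in
    ``_<MODALITY>.nii[.gz]``.  Raises :class:`FileNotFoundError` for a
    missing file, :class:`MultiTimepointError` for 4-D images with more
    than one timepoint, and :class:`HeaderError` for unreadable headers.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        img = nib.load(path)
        shape = img.shape
    except Exception as exc:  # nibabel raises various header errors
        raise HeaderError(f"unreadable image header: {path}: {exc}") from exc
    if len(shape) > 3:
        if any(n > 1 for n in shape[3:]):
            raise MultiTimepointError(
                f"{path}: expected a single 3-D volume, got shape {shape}"
            )
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim > 3:
        data = data.reshape(data.shape[:3])
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if modality is None:
        modality = _modality_from_path(path)
        if modality is None:
            raise ValidationError(
                f"cannot infer modality from {path!r}; pass modality= explicitly"
            )
    return Volume(data=data, spacing=spacing, modality=modality,
                  subject_id=subject_id)


def write_volume(volume: Volume, path: str) -> None:
    """Write a Volume as NIfTI-1 with an RAS diagonal affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


def write_mask(mask: np.ndarray, spacing, path: str) -> None:
    """Write a binary mask as NIfTI (uint8) with the source volume's geometry."""
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), path)


# --------------------------------------------------------------------- ratings

RATING_COLUMNS = ["rater_id", "subject_id", "modality", "hod_present", "side"]


def read_ratings(path: str) -> list[RatingRecord]:
    """Read a rating table (CSV with a header row), validating every row.

    Invariant violations report the offending row number (1-based data
    rows, header excluded).
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"rating table missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        present = str(row.hod_present).strip().lower()
        if present not in ("true", "false", "0", "1", "yes", "no"):
            raise ValidationError(f"row {i}: unparseable hod_present {row.hod_present!r}")
        try:
            records.append(RatingRecord(
                rater_id=str(row.rater_id),
                subject_id=str(row.subject_id),
                modality=str(row.modality),
                hod_present=present in ("true", "1", "yes"),
                side=str(row.side),
            ))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_ratings(records: Sequence[RatingRecord], path: str) -> None:
    df = pd.DataFrame(
        [(r.rater_id, r.subject_id, r.modality, r.hod_present, r.side)
         for r in records],
        columns=RATING_COLUMNS,
    )
    df.to_csv(path, index=False)


# ------------------------------------------------------------------- landmarks

LANDMARK_COLUMNS = ["slice", "fissure_x", "fissure_y", "sulcusL_x", "sulcusL_y",
                    "sulcusR_x", "sulcusR_y"]


def write_landmarks(landmarks: LandmarkSet, path: str) -> None:
    rows = []
    for z in landmarks.slices():
        lm = landmarks.per_slice[z]
        rows.append([z, *lm.fissure, *lm.sulcus_left, *lm.sulcus_right])
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def read_landmarks(path: str) -> LandmarkSet:
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"landmark table missing columns: {sorted(missing)}")
    per_slice = {}
    for row in df.itertuples(index=False):
        per_slice[int(row.slice)] = SliceLandmarks(
            fissure=(float(row.fissure_x), float(row.fissure_y)),
            sulcus_left=(float(row.sulcusL_x), float(row.sulcusL_y)),
            sulcus_right=(float(row.sulcusR_x), float(row.sulcusR_y)),
        )
    return LandmarkSet(per_slice=per_slice)


# --------------------------------------------------------------------- reports

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and (obj != obj):  # NaN -> null
        return None
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict
        return _jsonable(asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_report(results: dict, path: str, *, csv_path: Optional[str] = None) -> None:
    """Write the cohort-level result bundle as JSON (and rows as CSV).

    An empty cohort produces a report with zero subject rows and explicit
    nulls for the calibration constants.  ``csv_path``, when given,
    receives the per-subject rows (``results['subjects']``) as CSV.
    """
    payload = _jsonable(results)
    payload.setdefault("subjects", [])
    payload.setdefault("calibration", None)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, allow_nan=False)
    if csv_path is not None:
        pd.DataFrame(payload["subjects"]).to_csv(csv_path, index=False)


def read_report(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
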