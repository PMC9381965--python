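"""Core domain types shared across the pipeline.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``[x, y, z]`` in RAS order: axis 0 increases toward
  the anatomical **right**, axis 1 toward **anterior**, axis 2 toward
  **superior** (inferior -> superior slice order).
* Voxel coordinates are 0-based; the physical position of a voxel centre
  along an axis is ``(index + 0.5) * spacing``.
* Percentages are carried as percentages: a value of 1.21 means 1.21 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Closed enumeration of supported image modalities / map types.
MODALITIES = ("PD", "T2", "FLAIR", "FA", "MD", "T1")

#: Structural contrasts rated by reviewers and thresholded quantitatively.
INTENSITY_MODALITIES = ("PD", "T2", "FLAIR")

#: Diffusion-derived scalar maps.
DTI_MAPS = ("FA", "MD")

SIDES = ("left", "right", "none")


class HodasymError(Exception):
    """Base class for package-specific errors."""


class VolumeFormatError(HodasymError):
    """The image file is structurally unsuitable (not a single 3-D volume)."""


class MultiTimepointError(VolumeFormatError):
    """The image contains more than one timepoint/volume."""


class HeaderError(VolumeFormatError):
    """The image header could not be read or is invalid."""


class ValidationError(HodasymError):
    """A record or table violates a domain invariant."""


class GridMismatchError(HodasymError):
    """A mask or second volume does not live on the same voxel grid."""


def _check_side(side: str) -> None:
    if side not in SIDES:
        raise ValidationError(f"side must be one of {SIDES}, got {side!r}")


def _check_modality(modality: str, allowed=MODALITIES) -> None:
    if modality not in allowed:
        raise ValidationError(
            f"modality must be one of {allowed}, got {modality!r}"
        )


@dataclass
class Volume:
    """A single 3-D scalar image with voxel spacing and a modality tag.

    Parameters
    ----------
    data:
        3-D array of intensities (arbitrary units).
    spacing:
        ``(dx, dy, dz)`` voxel size in mm; all components must be positive.
    modality:
        One of :data:`MODALITIES`.
    subject_id:
        Free-form subject identifier.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"Volume data must have 3 axes, got {self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValidationError("every Volume axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(
                f"spacing must be 3 positive components, got {self.spacing}"
            )
        _check_modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class SubjectMeta:
    """Cohort metadata for one subject.

    ``expected_hod_side`` is the olivary side where degeneration is
    anticipated from the causative lesion in the dentato-rubro-olivary
    loop (ipsilateral to central-tegmental-tract / red-nucleus lesions,
    contralateral to dentate / superior-cerebellar-peduncle lesions);
    it is supplied as metadata, never inferred from images.
    """

    subject_id: str
    role: str  # "patient" | "control"
    expected_hod_side: str = "none"
    lesion_location: str = ""
    modalities_present: Optional[frozenset] = None  # None => all available

    def __post_init__(self) -> None:
        if self.role not in ("patient", "control"):
            raise ValidationError(f"role must be patient/control, got {self.role!r}")
        _check_side(self.expected_hod_side)
        if self.role == "control" and self.expected_hod_side != "none":
            raise ValidationError("controls must have expected_hod_side='none'")
        if self.role == "patient" and self.expected_hod_side == "none":
            raise ValidationError(
                "patients must have expected_hod_side in {'left','right'}"
            )

    def has_modality(self, modality: str) -> bool:
        return self.modalities_present is None or modality in self.modalities_present


@dataclass(frozen=True)
class RatingRecord:
    """One reviewer's call (presence + laterality) for one subject/modality."""

    rater_id: str
    subject_id: str
    modality: str
    hod_present: bool
    side: str = "none"

    def __post_init__(self) -> None:
        _check_modality(self.modality, INTENSITY_MODALITIES)
        _check_side(self.side)
        if self.hod_present and self.side == "none":
            raise ValidationError(
                "hod_present=True requires side in {'left','right'}"
            )
        if not self.hod_present and self.side != "none":
            raise ValidationError("hod_present=False requires side='none'")
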