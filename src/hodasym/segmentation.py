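"""Landmark-driven quadrant segmentation of the medulla oblongata.

The medulla cross-section is split into quadrants using two easily
identifiable surface landmarks: the anterior median fissure (midline,
anterior surface) and the two posterolateral sulci.  On each axial slice,

* the **anterior/posterior** division is the straight line joining the
  left and right posterolateral sulci, and
* the **left/right** division is the perpendicular to that line passing
  through the fissure point (robust to in-plane head rotation).

The quantity of interest is the mean intensity of the two *anterior*
quadrants over an 8-mm craniocaudal slab, which contain the inferior
olivary nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import GridMismatchError, HodasymError, ValidationError, Volume

#: Craniocaudal extent of the measurement slab in mm.
SLAB_THICKNESS_MM = 8.0


class LandmarkError(HodasymError):
    """Missing or degenerate landmarks."""


@dataclass
class SliceLandmarks:
    """In-plane landmark coordinates for one axial slice (voxel units, float)."""

    fissure: tuple[float, float]
    sulcus_left: tuple[float, float]
    sulcus_right: tuple[float, float]


@dataclass
class LandmarkSet:
    """Per-slice landmarks plus an optional binary medulla mask.

    ``per_slice`` maps slice index (axis 2) to :class:`SliceLandmarks`.
    Coordinates are ``(x, y)`` voxel indices on the grid the landmarks were
    placed on.  ``medulla_mask``, when present, is a 3-D boolean array on
    the same grid outlining the medulla cross-section.
    """

    per_slice: dict[int, SliceLandmarks] = field(default_factory=dict)
    medulla_mask: Optional[np.ndarray] = None

    def slices(self) -> list[int]:
        return sorted(self.per_slice)

    def validate_slice(self, z: int, spacing: tuple[float, float, float]) -> None:
        """Check the geometric invariants of the landmarks on slice ``z``."""
        lm = self.per_slice[z]
        geom = _slice_geometry(lm, spacing)
        # fissure anterior to the sulcus-sulcus line
        if geom.anterior_signed(np.array([lm.fissure]))[0] <= 0:
            raise LandmarkError(
                f"slice {z}: fissure point is not anterior to the sulcus line"
            )
        # left sulcus on the anatomical left of the midsagittal axis
        if geom.lateral_signed(np.array([lm.sulcus_left]))[0] >= 0:
            raise LandmarkError(f"slice {z}: sulcus_left is not left of the fissure")
        if geom.lateral_signed(np.array([lm.sulcus_right]))[0] <= 0:
            raise LandmarkError(f"slice {z}: sulcus_right is not right of the fissure")


class _SliceGeometry:
    """Signed-distance helpers for the two dividing lines of one slice.

    Distances are computed in mm so the construction is invariant to
    anisotropic in-plane voxel sizes.
    """

    def __init__(self, lm: SliceLandmarks, spacing):
        dx, dy = float(spacing[0]), float(spacing[1])
        scale = np.array([dx, dy])
        sl = np.asarray(lm.sulcus_left, dtype=float) * scale
        sr = np.asarray(lm.sulcus_right, dtype=float) * scale
        f = np.asarray(lm.fissure, dtype=float) * scale
        v = sr - sl
        norm = np.hypot(*v)
        if norm == 0:
            raise LandmarkError("degenerate landmarks: the two sulci coincide")
        self._scale = scale
        self._f = f
        self._v = v / norm
        # normal to the sulcus line oriented anterior: volumes are in RAS,
        # so anatomical anterior is the +y axis direction
        n = np.array([-self._v[1], self._v[0]])
        if n[1] == 0:
            raise LandmarkError(
                "degenerate landmarks: the sulcus-sulcus line runs "
                "anterior-posterior"
            )
        if n[1] < 0:
            n = -n
        self._n = n
        self._sl = sl

    def anterior_signed(self, pts_vox: np.ndarray) -> np.ndarray:
        """> 0 anterior of the sulcus-sulcus line, < 0 posterior (mm)."""
        pts = np.asarray(pts_vox, dtype=float) * self._scale
        return (pts - self._sl) @ self._n

    def lateral_signed(self, pts_vox: np.ndarray) -> np.ndarray:
        """> 0 on the anatomical right of the midsagittal axis, < 0 left (mm)."""
        pts = np.asarray(pts_vox, dtype=float) * self._scale
        return (pts - self._f) @ self._v


def _slice_geometry(lm: SliceLandmarks, spacing) -> _SliceGeometry:
    return _SliceGeometry(lm, spacing)


@dataclass
class QuadrantMask:
    """Left/right anterior-quadrant ROIs with volume bookkeeping."""

    left_anterior: np.ndarray
    right_anterior: np.ndarray
    slab_slices: list[int]
    voxel_count_left: int
    voxel_count_right: int
    volume_mm3_left: float
    volume_mm3_right: float

    @classmethod
    def from_masks(cls, left, right, slab_slices, spacing) -> "QuadrantMask":
        if np.any(left & right):
            raise ValidationError("left and right anterior masks overlap")
        vox = float(np.prod(spacing))
        nl, nr = int(left.sum()), int(right.sum())
        return cls(left, right, list(slab_slices), nl, nr, nl * vox, nr * vox)


def select_slab(volume: Volume, olive_center_slice: int) -> list[int]:
    """Pick the consecutive slices covering an 8-mm craniocaudal section.

    The slab is centred as symmetrically as possible on
    ``olive_center_slice``, biased inferiorly when the slice count is
    even: 4 slices at 2-mm thickness, 2 slices at 4-mm thickness.
    """
    dz = volume.spacing[2]
    n = max(1, int(round(SLAB_THICKNESS_MM / dz)))
    start = olive_center_slice - n // 2
    stop = start + n
    if start < 0 or stop > volume.shape[2]:
        raise ValidationError(
            f"8-mm slab (slices {start}..{stop - 1}) extends past the volume "
            f"boundary (nz={volume.shape[2]})"
        )
    return list(range(start, stop))


def build_quadrant_masks(
    volume: Volume,
    landmarks: LandmarkSet,
    slab: list[int],
    *,
    medulla_disc_radius_mm: float = 9.0,
) -> QuadrantMask:
    """Segment the left/right anterior quadrants of the medulla on ``slab``.

    On each slab slice, the medulla cross-section is split by the
    midsagittal axis through the fissure (left vs right; the rare exact
    on-axis voxel goes to the left quadrant) and by the line joining the
    posterolateral sulci (anterior vs posterior; on-line voxels count as
    anterior).  When the landmark set carries no medulla mask, the
    cross-section is approximated by a disc of ``medulla_disc_radius_mm``
    centred on the landmark centroid — a declared approximation, not an
    inferred outline.
    """
    for z in slab:
        if z not in landmarks.per_slice:
            raise LandmarkError(f"no landmarks for slab slice {z}")
        landmarks.validate_slice(z, volume.spacing)

    nx, ny, _ = volume.shape
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)

    left = np.zeros(volume.shape, dtype=bool)
    right = np.zeros(volume.shape, dtype=bool)
    dx, dy = volume.spacing[0], volume.spacing[1]

    for z in slab:
        lm = landmarks.per_slice[z]
        geom = _slice_geometry(lm, volume.spacing)
        lat = geom.lateral_signed(pts).reshape(nx, ny)
        ant = geom.anterior_signed(pts).reshape(nx, ny)

        if landmarks.medulla_mask is not None:
            if landmarks.medulla_mask.shape != volume.shape:
                raise GridMismatchError("medulla mask grid differs from volume grid")
            medulla = landmarks.medulla_mask[:, :, z]
        else:
            centroid = np.mean(
                [lm.fissure, lm.sulcus_left, lm.sulcus_right], axis=0
            )
            r2 = ((xs - centroid[0]) * dx) ** 2 + ((ys - centroid[1]) * dy) ** 2
            medulla = r2 <= medulla_disc_radius_mm**2

        anterior = medulla & (ant >= 0)
        left[:, :, z] = anterior & (lat <= 0)
        right[:, :, z] = anterior & (lat > 0)

    return QuadrantMask.from_masks(left, right, slab, volume.spacing)


def roi_mean(volume: Volume, mask: np.ndarray) -> float:
    """Mean intensity under ``mask``, pooling voxels over all slab slices."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise GridMismatchError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("cannot take the mean over an empty mask")
    return float(volume.data[mask].mean())
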