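"""Synthetic brainstem phantoms with a plantable unilateral olivary lesion.

The phantom is a cylindrical medulla oblongata (axis along
inferior->superior) carrying two ellipsoidal olivary regions in the
anterior quadrants.  Structural contrasts (PD/T2/FLAIR) are piecewise
constant: background tissue at the modality's base intensity, olives at
a modality-specific relative contrast (the healthy inferior olive is
mildly hyperintense on PD and isointense on T2/FLAIR).  A planted
degeneration on one side

* scales that olive's intensity by ``(1 + hod_intensity_effect)`` on the
  structural contrasts and enlarges it by ``hod_enlargement`` (hypertrophy),
* decreases FA by ``hod_fa_effect`` and increases MD by ``hod_md_effect``
  over the affected anterior-quadrant olivary territory on the DTI grid.

A signed per-modality left/right intensity imbalance (percent) emulates
the residual asymmetry observed in healthy controls.  Gaussian voxel
noise is added last.  All outputs are a pure function of the spec,
including its seed.

Geometry conventions: physical position of a voxel centre along an axis
is ``(index + 0.5) * spacing`` mm; the medulla axis sits at the in-plane
field-of-view centre.  The FLAIR volume is produced at 4-mm slice
thickness by averaging pairs of 2-mm slices before adding noise,
mirroring a two-slice thick-slab acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import ValidationError, Volume
from .segmentation import LandmarkSet, SliceLandmarks, SLAB_THICKNESS_MM

STRUCTURAL = ("PD", "T2", "FLAIR")


def _default_background():
    return {"PD": 100.0, "T2": 100.0, "FLAIR": 100.0}


def _default_contrast():
    # healthy olive visible on PD, not on T2/FLAIR
    return {"PD": 1.15, "T2": 1.0, "FLAIR": 1.0}


def _default_noise():
    return {"PD": 0.02, "T2": 0.02, "FLAIR": 0.03, "FA": 0.02, "MD": 0.02}


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic subject.

    Intensity units are arbitrary; geometric parameters are mm.
    ``noise_sd`` entries are fractions of the modality's base intensity.
    ``lateral_imbalance_percent`` maps a structural modality to a signed
    percentage by which the whole left half of the image is scaled.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 24)
    spacing: tuple[float, float, float] = (0.625, 0.625, 2.0)
    medulla_radius: float = 9.0
    olive_semiaxes: tuple[float, float, float] = (3.0, 2.0, 3.5)
    olive_lateral_offset: float = 3.2   # mm from midline
    olive_anterior_offset: float = 3.5  # mm anterior of the medulla axis
    olive_center_z: float = 24.0        # mm along the slice axis
    sulcus_angle_deg: float = 20.0      # sulci this far below the lateral equator
    background_intensity: dict = field(default_factory=_default_background)
    olive_contrast: dict = field(default_factory=_default_contrast)
    noise_sd: dict = field(default_factory=_default_noise)
    hod_side: str = "none"
    hod_intensity_effect: float = 0.0
    hod_enlargement: float = 0.1
    fa_baseline: float = 0.45
    md_baseline: float = 8.0e-4  # mm^2/s
    hod_fa_effect: float = 0.35
    hod_md_effect: float = 0.10
    dti_grid_shape: tuple[int, int, int] = (30, 30, 24)
    dti_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lateral_imbalance_percent: dict = field(default_factory=dict)
    subject_id: str = "phantom"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(n < 1 for n in self.grid_shape):
            raise ValidationError("invalid grid or spacing")
        if self.hod_side not in ("left", "right", "none"):
            raise ValidationError(f"invalid hod_side {self.hod_side!r}")
        if not 0.0 <= self.fa_baseline <= 1.0:
            raise ValidationError("fa_baseline must be in [0, 1]")
        if self.md_baseline <= 0:
            raise ValidationError("md_baseline must be > 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValidationError("noise_sd must be >= 0")
        a, b, c = self.olive_semiaxes
        off = math.hypot(self.olive_lateral_offset, self.olive_anterior_offset)
        if off + max(a, b) > self.medulla_radius:
            raise ValidationError("olive extends outside the medulla cylinder")
        nz_mm = self.grid_shape[2] * self.spacing[2]
        if self.olive_center_z - c < 0 or self.olive_center_z + c > nz_mm:
            raise ValidationError("olive extends outside the grid along z")
        fov = (self.grid_shape[0] * self.spacing[0], self.grid_shape[1] * self.spacing[1])
        cx, cy = fov[0] / 2, fov[1] / 2
        if self.medulla_radius > min(cx, cy):
            raise ValidationError("medulla cylinder extends outside the grid")

    # -- derived geometry ------------------------------------------------
    @property
    def center_mm(self) -> tuple[float, float]:
        return (
            self.grid_shape[0] * self.spacing[0] / 2,
            self.grid_shape[1] * self.spacing[1] / 2,
        )

    def olive_center_mm(self, side: str) -> tuple[float, float, float]:
        cx, cy = self.center_mm
        sgn = -1.0 if side == "left" else 1.0  # left = lower x (RAS)
        return (
            cx + sgn * self.olive_lateral_offset,
            cy + self.olive_anterior_offset,
            self.olive_center_z,
        )

    def center_slice(self, dz: float) -> int:
        return int(round(self.olive_center_z / dz))


@dataclass
class GroundTruth:
    """Everything planted into one phantom, for recovery checks."""

    subject_id: str
    hod_side: str
    intensity_effect: float
    enlargement: float
    fa_effect: float
    md_effect: float
    lateral_imbalance: dict
    center_slice: dict           # modality -> slab-centre slice index
    olive_masks: dict            # grid key ("fine"/"dti") -> {"left","right"}
    medulla_masks: dict          # grid key -> 3-D bool
    affected_territory: Optional[np.ndarray]  # DTI grid, None when no lesion


@dataclass
class PhantomResult:
    volumes: dict      # modality -> Volume
    landmarks: dict    # modality -> LandmarkSet
    truth: GroundTruth


def _coords_mm(shape, spacing):
    return [
        (np.arange(n, dtype=float) + 0.5) * s
        for n, s in zip(shape, spacing)
    ]


def _cylinder_mask(shape, spacing, center_mm, radius):
    x, y, _ = _coords_mm(shape, spacing)
    r2 = (x[:, None] - center_mm[0]) ** 2 + (y[None, :] - center_mm[1]) ** 2
    return np.broadcast_to((r2 <= radius**2)[:, :, None], shape).copy()

def _ellipsoid_mask(shape, spacing, center_mm, semiaxes):
    x, y, z = _coords_mm(shape, spacing)
    a, b, c = semiaxes
    q = (
        ((x[:, None, None] - center_mm[0]) / a) ** 2
        + ((y[None, :, None] - center_mm[1]) / b) ** 2
        + ((z[None, None, :] - center_mm[2]) / c) ** 2
    )
    return q <= 1.0


def _landmark_set(spec: PhantomSpec, shape, spacing, medulla_mask) -> LandmarkSet:
    cx, cy = spec.center_mm
    R = spec.medulla_radius
    alpha = math.radians(spec.sulcus_angle_deg)
    dx, dy = spacing[0], spacing[1]

    def vox(p_mm):
        return (p_mm[0] / dx - 0.5, p_mm[1] / dy - 0.5)

    fissure = vox((cx, cy + R))
    s_left = vox((cx - R * math.cos(alpha), cy - R * math.sin(alpha)))
    s_right = vox((cx + R * math.cos(alpha), cy - R * math.sin(alpha)))
    per_slice = {
        z: SliceLandmarks(fissure, s_left, s_right) for z in range(shape[2])
    }
    return LandmarkSet(per_slice=per_slice, medulla_mask=medulla_mask)


def _structural_image(spec, shape, spacing, modality, olives, affected):
    """Noiseless structural contrast on the given grid; noise added by caller."""
    B = spec.background_intensity[modality]
    c = spec.olive_contrast[modality]
    medulla = _cylinder_mask(shape, spacing, spec.center_mm, spec.medulla_radius)
    img = np.zeros(shape, dtype=float)
    img[medulla] = B
    for side in ("left", "right"):
        img[olives[side]] = B * c
    if affected is not None:
        img[affected] = B * c * (1.0 + spec.hod_intensity_effect)
    g = spec.lateral_imbalance_percent.get(modality, 0.0)
    if g != 0.0:
        x = _coords_mm(shape, spacing)[0]
        img[x < spec.center_mm[0], :, :] *= 1.0 + g / 100.0
    return img, medulla


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate all per-modality volumes, landmarks and the ground truth.

    Identical specs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    fine_shape, fine_sp = spec.grid_shape, spec.spacing

    # ground-truth regions on the fine structural grid
    olives_fine = {
        s: _ellipsoid_mask(fine_shape, fine_sp, spec.olive_center_mm(s),
                           spec.olive_semiaxes)
        for s in ("left", "right")
    }
    affected_fine = None
    if spec.hod_side != "none":
        semi = tuple(a * (1.0 + spec.hod_enlargement) for a in spec.olive_semiaxes)
        affected_fine = _ellipsoid_mask(
            fine_shape, fine_sp, spec.olive_center_mm(spec.hod_side), semi
        )

    volumes: dict[str, Volume] = {}
    landmarks: dict[str, LandmarkSet] = {}
    medulla_fine = None

    # PD and T2 on the fine grid (noise drawn in a fixed modality order)
    for m in ("PD", "T2"):
        img, medulla_fine = _structural_image(
            spec, fine_shape, fine_sp, m, olives_fine, affected_fine
        )
        img = img + rng.normal(
            0.0, spec.noise_sd[m] * spec.background_intensity[m], fine_shape
        )
        volumes[m] = Volume(img, fine_sp, m, spec.subject_id)

    fine_lms = _landmark_set(spec, fine_shape, fine_sp, medulla_fine)
    landmarks["PD"] = fine_lms
    landmarks["T2"] = fine_lms

    # FLAIR: average pairs of 2-mm slices into 4-mm slices, then add noise
    if fine_shape[2] % 2 != 0:
        raise ValidationError("FLAIR downsampling requires an even slice count")
    img, _ = _structural_image(
        spec, fine_shape, fine_sp, "FLAIR", olives_fine, affected_fine
    )
    flair = 0.5 * (img[:, :, 0::2] + img[:, :, 1::2])
    flair_sp = (fine_sp[0], fine_sp[1], 2.0 * fine_sp[2])
    flair_shape = flair.shape
    flair = flair + rng.normal(
        0.0, spec.noise_sd["FLAIR"] * spec.background_intensity["FLAIR"], flair_shape
    )
    medulla_flair = _cylinder_mask(
        flair_shape, flair_sp, spec.center_mm, spec.medulla_radius
    )
    volumes["FLAIR"] = Volume(flair, flair_sp, "FLAIR", spec.subject_id)
    landmarks["FLAIR"] = _landmark_set(spec, flair_shape, flair_sp, medulla_flair)

    # FA / MD on the DTI grid
    dti_shape, dti_sp = spec.dti_grid_shape, spec.dti_spacing
    medulla_dti = _cylinder_mask(dti_shape, dti_sp, spec.center_mm,
                                 spec.medulla_radius)
    olives_dti = {
        s: _ellipsoid_mask(dti_shape, dti_sp, spec.olive_center_mm(s),
                           spec.olive_semiaxes)
        for s in ("left", "right")
    }
    territory = None
    if spec.hod_side != "none":
        territory = _affected_territory(spec, dti_shape, dti_sp, medulla_dti)

    fa = np.full(dti_shape, 0.10)
    fa[medulla_dti] = spec.fa_baseline
    md = np.full(dti_shape, 1.5e-3)
    md[medulla_dti] = spec.md_baseline
    if territory is not None:
        fa[territory] *= 1.0 - spec.hod_fa_effect
        md[territory] *= 1.0 + spec.hod_md_effect
    fa = fa + rng.normal(0.0, spec.noise_sd["FA"] * spec.fa_baseline, dti_shape)
    md = md + rng.normal(0.0, spec.noise_sd["MD"] * spec.md_baseline, dti_shape)
    volumes["FA"] = Volume(fa, dti_sp, "FA", spec.subject_id)
    volumes["MD"] = Volume(md, dti_sp, "MD", spec.subject_id)
    dti_lms = _landmark_set(spec, dti_shape, dti_sp, medulla_dti)
    landmarks["FA"] = dti_lms
    landmarks["MD"] = dti_lms

    truth = GroundTruth(
        subject_id=spec.subject_id,
        hod_side=spec.hod_side,
        intensity_effect=(
            spec.hod_intensity_effect if spec.hod_side != "none" else 0.0
        ),
        enlargement=spec.hod_enlargement if spec.hod_side != "none" else 0.0,
        fa_effect=spec.hod_fa_effect if spec.hod_side != "none" else 0.0,
        md_effect=spec.hod_md_effect if spec.hod_side != "none" else 0.0,
        lateral_imbalance=dict(spec.lateral_imbalance_percent),
        center_slice={
            "PD": spec.center_slice(fine_sp[2]),
            "T2": spec.center_slice(fine_sp[2]),
            "FLAIR": spec.center_slice(flair_sp[2]),
            "FA": spec.center_slice(dti_sp[2]),
            "MD": spec.center_slice(dti_sp[2]),
        },
        olive_masks={
            "fine": {s: olives_fine[s] for s in ("left", "right")},
            "dti": {s: olives_dti[s] for s in ("left", "right")},
        },
        medulla_masks={"fine": medulla_fine, "flair": medulla_flair,
                       "dti": medulla_dti},
        affected_territory=territory,
    )
    if affected_fine is not None:
        truth.olive_masks["fine"][spec.hod_side] = affected_fine

    return PhantomResult(volumes=volumes, landmarks=landmarks, truth=truth)


def _affected_territory(spec, shape, spacing, medulla):
    """Anterior-quadrant olivary territory on the affected side, restricted
    to the 8-mm slab around the olive (used for the DTI effect region)."""
    cx, cy = spec.center_mm
    alpha = math.radians(spec.sulcus_angle_deg)
    y_sulcus = cy - spec.medulla_radius * math.sin(alpha)
    x, y, z = _coords_mm(shape, spacing)
    half = SLAB_THICKNESS_MM / 2
    lateral = x < cx if spec.hod_side == "left" else x > cx
    in_slab = (z > spec.olive_center_z - half) & (z < spec.olive_center_z + half)
    region = (
        medulla
        & lateral[:, None, None]
        & (y > y_sulcus)[None, :, None]
        & in_slab[None, None, :]
    )
    return region


def expected_quadrant_means(
    spec: PhantomSpec, quadrants, truth: GroundTruth, modality: str
) -> tuple[float, float]:
    """Analytic noiseless anterior-quadrant means (left, right) on the fine grid.

    Derived purely from voxel counts of the ground-truth regions
    intersected with the measurement masks, independent of the generated
    image data: the olive contributes at its contrast (times the planted
    effect on the affected side), the rest of the quadrant at the base
    intensity, and the left half carries the lateral imbalance factor.
    """
    if modality not in ("PD", "T2"):
        raise ValidationError("analytic means are defined on the fine grid (PD/T2)")
    B = spec.background_intensity[modality]
    c = spec.olive_contrast[modality]
    g = spec.lateral_imbalance_percent.get(modality, 0.0)
    means = {}
    for side, q in (("left", quadrants.left_anterior),
                    ("right", quadrants.right_anterior)):
        n = int(q.sum())
        olive = truth.olive_masks["fine"][side]
        n_ol = int((q & olive).sum())
        val = c * (1.0 + spec.hod_intensity_effect) if side == truth.hod_side else c
        mean = B * ((n - n_ol) + val * n_ol) / n
        if side == "left":
            mean *= 1.0 + g / 100.0
        means[side] = mean
    return means["left"], means["right"]


def expected_diluted_effect(spec: PhantomSpec, quadrants, truth: GroundTruth,
                            modality: str) -> float:
    """Analytically expected unsigned asymmetry index (percent) at zero noise."""
    from .asymmetry import intensity_asymmetry

    left, right = expected_quadrant_means(spec, quadrants, truth, modality)
    return intensity_asymmetry(left, right, modality=modality).diff_percent
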