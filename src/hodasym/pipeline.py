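"""End-to-end quantitative pipeline over a (synthetic or measured) cohort.

Per subject and structural modality: select the 8-mm slab around the
olive, build the anterior-quadrant masks from the landmarks, pool the
ROI means and form the unsigned asymmetry index.  For patients with DTI,
form the signed expected-side FA/MD asymmetries on the DTI grid.  At
cohort level: calibrate the per-modality detection threshold from the
controls, classify every subject, compute exceedance rates, and contrast
FA/MD between the PD+ and PD- subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .asymmetry import AsymmetryResult, DTIAsymmetry, dti_asymmetry, intensity_asymmetry
from .calibration import (
    ControlCalibration,
    HODCall,
    calibrate_threshold,
    classify_subject,
    cohort_exceedance_rate,
)
from .cohort import CohortSpec, SubjectData, iter_cohort
from .core import INTENSITY_MODALITIES, SubjectMeta, ValidationError
from .segmentation import build_quadrant_masks, roi_mean, select_slab
from .stats import SubgroupContrast, paired_t, subgroup_contrast


@dataclass
class SubjectMeasurement:
    meta: SubjectMeta
    asymmetries: dict        # modality -> AsymmetryResult
    dti: dict                # map -> DTIAsymmetry
    roi_voxels: dict         # modality -> (n_left, n_right)
    roi_volume_mm3: dict     # modality -> (mm3_left, mm3_right)


def measure_subject(subject: SubjectData) -> SubjectMeasurement:
    """Segment and measure one subject on every available modality grid."""
    asyms: dict[str, AsymmetryResult] = {}
    roi_vox, roi_mm3 = {}, {}
    for m in INTENSITY_MODALITIES:
        if m not in subject.volumes:
            continue
        vol = subject.volumes[m]
        slab = select_slab(vol, subject.truth.center_slice[m])
        qm = build_quadrant_masks(vol, subject.landmarks[m], slab)
        left = roi_mean(vol, qm.left_anterior)
        right = roi_mean(vol, qm.right_anterior)
        asyms[m] = intensity_asymmetry(
            left, right, subject_id=subject.meta.subject_id, modality=m
        )
        roi_vox[m] = (qm.voxel_count_left, qm.voxel_count_right)
        roi_mm3[m] = (qm.volume_mm3_left, qm.volume_mm3_right)

    dti: dict[str, DTIAsymmetry] = {}
    expected = subject.meta.expected_hod_side
    if expected != "none":
        for m in ("FA", "MD"):
            if m not in subject.volumes:
                continue
            vol = subject.volumes[m]
            slab = select_slab(vol, subject.truth.center_slice[m])
            qm = build_quadrant_masks(vol, subject.landmarks[m], slab)
            means = {
                "left": roi_mean(vol, qm.left_anterior),
                "right": roi_mean(vol, qm.right_anterior),
            }
            contra = "right" if expected == "left" else "left"
            dti[m] = dti_asymmetry(
                means[expected], means[contra],
                subject_id=subject.meta.subject_id, map=m,
            )
            roi_vox[m] = (qm.voxel_count_left, qm.voxel_count_right)
            roi_mm3[m] = (qm.volume_mm3_left, qm.volume_mm3_right)

    return SubjectMeasurement(subject.meta, asyms, dti, roi_vox, roi_mm3)


@dataclass
class CohortAnalysis:
    """Cohort-level results of the quantitative pipeline."""

    measurements: list
    calibrations: dict       # modality -> ControlCalibration
    calls: list              # HODCall, patients and controls
    exceedance_pct: dict     # modality -> % of patients exceeding
    contrasts: dict          # map -> SubgroupContrast
    control_comparisons: dict  # "PD_vs_T2" etc -> TestResult


def analyze_measurements(measurements: list) -> CohortAnalysis:
    """Calibrate, classify and contrast from per-subject measurements."""
    controls = [m for m in measurements if m.meta.role == "control"]
    patients = [m for m in measurements if m.meta.role == "patient"]

    calibrations: dict[str, ControlCalibration] = {}
    for mod in INTENSITY_MODALITIES:
        diffs = [m.asymmetries[mod].diff_percent for m in controls
                 if mod in m.asymmetries]
        if len(diffs) >= 2:
            calibrations[mod] = calibrate_threshold(diffs, mod)

    calls: list[HODCall] = []
    for m in measurements:
        for mod, asym in m.asymmetries.items():
            if mod in calibrations:
                calls.append(classify_subject(asym, calibrations[mod], m.meta))

    exceedance = {}
    for mod in calibrations:
        if any(c.modality == mod and c.role == "patient" for c in calls):
            exceedance[mod] = cohort_exceedance_rate(calls, mod)

    dti_rows = [d for m in patients for d in m.dti.values()]
    pd_calls = [c for c in calls if c.modality == "PD" and c.role == "patient"]
    contrasts: dict[str, SubgroupContrast] = {}
    if dti_rows and pd_calls:
        contrasts = subgroup_contrast(dti_rows, pd_calls)

    # paired comparison of the control asymmetry level between modalities
    control_comparisons = {}
    for a_mod, b_mod in (("PD", "T2"), ("PD", "FLAIR"), ("T2", "FLAIR")):
        pairs = [
            (m.asymmetries[a_mod].diff_percent, m.asymmetries[b_mod].diff_percent)
            for m in controls
            if a_mod in m.asymmetries and b_mod in m.asymmetries
        ]
        if len(pairs) >= 2:
            xa, xb = zip(*pairs)
            try:
                control_comparisons[f"{a_mod}_vs_{b_mod}"] = paired_t(xa, xb)
            except ValidationError:
                pass  # degenerate (zero-variance) differences

    return CohortAnalysis(
        measurements=measurements,
        calibrations=calibrations,
        calls=calls,
        exceedance_pct=exceedance,
        contrasts=contrasts,
        control_comparisons=control_comparisons,
    )


def run_pipeline(spec: CohortSpec) -> CohortAnalysis:
    """Generate, measure and analyze a synthetic cohort (streamed)."""
    measurements = [measure_subject(s) for s in iter_cohort(spec)]
    return analyze_measurements(measurements)


def subjects_frame(analysis: CohortAnalysis) -> pd.DataFrame:
    """One row per subject per modality: asymmetry, threshold call, ROI size."""
    call_ix = {(c.subject_id, c.modality): c for c in analysis.calls}
    rows = []
    for m in analysis.measurements:
        for mod, asym in m.asymmetries.items():
            call = call_ix.get((m.meta.subject_id, mod))
            rows.append(dict(
                subject_id=m.meta.subject_id, role=m.meta.role, modality=mod,
                diff_percent=asym.diff_percent, higher_side=asym.higher_side,
                exceeds_threshold=None if call is None else call.exceeds_threshold,
                laterality_consistent=None if call is None
                else call.laterality_consistent,
            ))
        for map_name, d in m.dti.items():
            rows.append(dict(
                subject_id=m.meta.subject_id, role=m.meta.role, modality=map_name,
                diff_percent=d.signed_diff_percent, higher_side=None,
                exceeds_threshold=None, laterality_consistent=None,
            ))
    return pd.DataFrame(rows)


def build_report(analysis: CohortAnalysis) -> dict:
    """JSON-ready cohort report (see io.write_report)."""
    report = {
        "subjects": subjects_frame(analysis),
        "calibration": {
            mod: dict(
                control_mean=c.control_mean, control_sd=c.control_sd,
                threshold=c.threshold, n_controls=c.n_controls,
                degenerate=c.degenerate,
                label="99% threshold (mean + 2.576 x SD)",
            )
            for mod, c in analysis.calibrations.items()
        } or None,
        "exceedance_pct": analysis.exceedance_pct,
        "subgroup_contrasts": {
            k: dict(
                mean_diff_pd_plus=v.mean_diff_pd_plus,
                mean_diff_pd_minus=v.mean_diff_pd_minus,
                n_pd_plus=v.n_pd_plus, n_pd_minus=v.n_pd_minus,
                welch_p=None if v.test is None else v.test.p_value,
            )
            for k, v in analysis.contrasts.items()
        },
        "control_comparisons": {
            k: dict(statistic=t.statistic, p_value=t.p_value, n=t.n1)
            for k, t in analysis.control_comparisons.items()
        },
    }
    return report
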