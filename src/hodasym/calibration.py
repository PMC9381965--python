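"""Control-calibrated detection threshold and patient classification.

The detection threshold per modality is calibrated from the control
cohort's asymmetry-index distribution as

    threshold = mean + 2.576 * SD

with the sample SD (n-1 denominator).  The z-value 2.576 is the
two-sided 99% normal quantile; the threshold is reported as the
"99% threshold" by convention even though its one-sided coverage under
a normal model is 99.5% (see docs/methods.md).  A patient's asymmetry
strictly exceeding the threshold is considered indicative of olivary
degeneration; when the higher-intensity side contradicts the side
expected from the causative lesion, the exceedance is flagged as a
laterality-based (quantitative) false positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .asymmetry import AsymmetryResult
from .core import SubjectMeta, ValidationError

#: Two-sided 99% standard-normal quantile used by the threshold formula.
Z_99 = 2.576


@dataclass
class ControlCalibration:
    """Control-cohort mean/SD and the derived detection threshold (percent)."""

    modality: str
    control_mean: float
    control_sd: float
    threshold: float
    n_controls: int
    degenerate: bool = False  # zero control variance


@dataclass
class HODCall:
    """Threshold classification of one subject/modality."""

    subject_id: str
    modality: str
    diff_percent: float
    exceeds_threshold: bool
    higher_side: str
    expected_side: str
    laterality_consistent: Optional[bool]  # None when not applicable
    role: str = "patient"


def calibrate_threshold(
    control_diffs: Sequence[float], modality: str
) -> ControlCalibration:
    """Calibrate the per-modality threshold from control asymmetry indices."""
    diffs = np.asarray(control_diffs, dtype=float)
    if diffs.size < 2:
        raise ValidationError("threshold calibration needs at least 2 controls")
    if np.any(diffs < 0):
        raise ValidationError("control asymmetry indices must be >= 0")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        warnings.warn(
            f"{modality}: zero control variance - threshold degenerates to the mean",
            stacklevel=2,
        )
    return ControlCalibration(
        modality=modality,
        control_mean=mean,
        control_sd=sd,
        threshold=mean + Z_99 * sd,
        n_controls=int(diffs.size),
        degenerate=degenerate,
    )


def classify_subject(
    asym: AsymmetryResult, calib: ControlCalibration, meta: SubjectMeta
) -> HODCall:
    """Compare one subject's asymmetry against the calibrated threshold.

    The comparison is strict (``>``): a value exactly at the threshold
    does not count as exceeding.  ``laterality_consistent`` is defined
    only when the threshold is exceeded and an expected side exists.
    """
    if asym.modality != calib.modality:
        raise ValidationError(
            f"modality mismatch: asymmetry is {asym.modality}, "
            f"calibration is {calib.modality}"
        )
    exceeds = asym.diff_percent > calib.threshold
    consistent: Optional[bool] = None
    if exceeds and meta.expected_hod_side != "none":
        consistent = asym.higher_side == meta.expected_hod_side
    return HODCall(
        subject_id=asym.subject_id,
        modality=asym.modality,
        diff_percent=asym.diff_percent,
        exceeds_threshold=exceeds,
        higher_side=asym.higher_side,
        expected_side=meta.expected_hod_side,
        laterality_consistent=consistent,
        role=meta.role,
    )


def cohort_exceedance_rate(calls: Sequence[HODCall], modality: str) -> float:
    """Percentage of patients whose asymmetry exceeds the threshold.

    The denominator counts patients with that modality available (i.e.
    with a call); subjects missing a modality simply have no call for it.
    """
    patient_calls = [c for c in calls if c.modality == modality and c.role == "patient"]
    if not patient_calls:
        raise ValidationError(f"no patient calls for modality {modality}")
    n_exceed = sum(c.exceeds_threshold for c in patient_calls)
    return 100.0 * n_exceed / len(patient_calls)
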