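"""Normalized left/right percentage-difference statistics.

Two variants are used:

* **Unsigned intensity asymmetry** (PD/T2/FLAIR): the side with the
  *lower* mean is the reference, so the index is always >= 0::

      diff% = 100 * (mean_higher - mean_lower) / mean_lower

* **Signed DTI asymmetry** (FA/MD): the side where olivary degeneration
  is *expected* from the causative lesion is the reference, so the index
  can take either sign::

      diff% = 100 * (mean_expected - mean_contralateral) / mean_expected

Both indices are unit-free (scale invariant) and carried in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import ValidationError


@dataclass
class AsymmetryResult:
    """Unsigned anterior-quadrant intensity asymmetry for one subject/modality."""

    subject_id: str
    modality: str
    mean_intensity_a: float  # side with higher mean
    mean_intensity_b: float  # side with lower mean
    higher_side: str  # "left" | "right" | "none" (exact tie)
    diff_percent: float


@dataclass
class DTIAsymmetry:
    """Signed, expected-side FA/MD asymmetry for one subject."""

    subject_id: str
    map: str  # "FA" | "MD"
    mean_expected_side: float
    mean_contralateral: float
    signed_diff_percent: float


def intensity_asymmetry(
    left_mean: float,
    right_mean: float,
    *,
    subject_id: str = "",
    modality: str = "PD",
) -> AsymmetryResult:
    """Unsigned percentage difference of the two anterior-quadrant means.

    Exact equality of the two means yields ``higher_side='none'`` and a
    difference of 0 rather than an arbitrary side.
    """
    if left_mean <= 0 or right_mean <= 0:
        raise ValidationError(
            "nonpositive ROI mean - segmentation failure "
            f"(left={left_mean}, right={right_mean})"
        )
    if left_mean == right_mean:
        return AsymmetryResult(subject_id, modality, left_mean, right_mean, "none", 0.0)
    if left_mean > right_mean:
        a, b, side = left_mean, right_mean, "left"
    else:
        a, b, side = right_mean, left_mean, "right"
    return AsymmetryResult(subject_id, modality, a, b, side, 100.0 * (a - b) / b)


def dti_asymmetry(
    expected_side_mean: float,
    contralateral_mean: float,
    *,
    subject_id: str = "",
    map: str = "FA",
) -> DTIAsymmetry:
    """Signed percentage difference normalized by the expected-side mean."""
    if expected_side_mean <= 0:
        raise ValidationError(
            f"nonpositive expected-side mean ({expected_side_mean})"
        )
    diff = 100.0 * (expected_side_mean - contralateral_mean) / expected_side_mean
    return DTIAsymmetry(subject_id, map, expected_side_mean, contralateral_mean, diff)
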