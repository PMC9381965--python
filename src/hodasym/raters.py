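"""Reviewer-based analysis: Fleiss' kappa, diagnosis and false-positive rates.

Fleiss' kappa measures chance-corrected agreement among a fixed number of
raters assigning categorical labels.  With N subjects, n raters and
``n_ij`` the number of raters assigning subject i to category j:

    P_i  = (sum_j n_ij^2 - n) / (n (n - 1))
    Pbar = mean_i P_i
    p_j  = sum_i n_ij / (N n)
    Pe   = sum_j p_j^2
    kappa = (Pbar - Pe) / (1 - Pe)

When every rating falls in a single category, ``Pe = 1`` and kappa is
*undefined*; this is reported as an explicit state, never as a number.

Because reviewers report presence *and* laterality, the default category
set is three-valued: {no finding, finding-left, finding-right}.  A binary
{negative, positive} mode is available since published analyses do not
always state which convention was used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import RatingRecord, SubjectMeta, ValidationError

THREE_CATEGORIES = ("none", "left", "right")
BINARY_CATEGORIES = ("negative", "positive")


@dataclass
class KappaResult:
    modality: str
    kappa: Optional[float]  # None => undefined (all ratings one category)
    n_subjects: int
    n_raters: int
    categories: tuple

    @property
    def defined(self) -> bool:
        return self.kappa is not None


@dataclass
class RaterRates:
    """Per-rater and mean diagnosis percentages plus the consensus rate."""

    modality: str
    rater_ids: list
    per_rater_diagnosis_pct: list
    mean_diagnosis_pct: float
    consensus_pct: float
    n_subjects: int


@dataclass
class FalsePositiveRates:
    """Rater false positives among controls (any positive call) and among
    patients (positive call on the side opposite the expected one)."""

    modality: str
    rater_ids: list
    control_per_rater_pct: list
    control_mean_pct: float
    patient_per_rater_pct: list
    patient_mean_pct: float


def _category_of(record: RatingRecord, binary: bool) -> str:
    if binary:
        return "positive" if record.hod_present else "negative"
    return record.side if record.hod_present else "none"


def rating_count_table(
    ratings: Sequence[RatingRecord],
    modality: str,
    categories: Sequence[str],
    *,
    binary: bool = False,
    subject_ids: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, list, list]:
    """Build the N x k subject-by-category count table for ``modality``.

    Every included subject must be rated exactly once by every rater.
    """
    recs = [r for r in ratings if r.modality == modality]
    if subject_ids is not None:
        keep = set(subject_ids)
        recs = [r for r in recs if r.subject_id in keep]
    if not recs:
        raise ValidationError(f"no ratings for modality {modality}")
    subjects = sorted({r.subject_id for r in recs})
    raters = sorted({r.rater_id for r in recs})
    seen: dict[tuple, str] = {}
    for r in recs:
        key = (r.subject_id, r.rater_id)
        if key in seen:
            raise ValidationError(f"duplicate rating for {key}")
        seen[key] = _category_of(r, binary)
    cat_index = {c: j for j, c in enumerate(categories)}
    table = np.zeros((len(subjects), len(categories)), dtype=int)
    for i, sid in enumerate(subjects):
        for rid in raters:
            if (sid, rid) not in seen:
                raise ValidationError(
                    f"rater {rid!r} has no {modality} rating for subject {sid!r}"
                )
            cat = seen[(sid, rid)]
            if cat not in cat_index:
                raise ValidationError(f"rating category {cat!r} not in {categories}")
            table[i, cat_index[cat]] += 1
    return table, subjects, raters


def kappa_from_table(table: np.ndarray) -> Optional[float]:
    """Evaluate Fleiss' kappa from an N x k count table (None if undefined)."""
    table = np.asarray(table, dtype=float)
    n_per_subject = table.sum(axis=1)
    n = n_per_subject[0]
    if not np.all(n_per_subject == n):
        raise ValidationError("unbalanced rating counts across subjects")
    if n < 2:
        raise ValidationError("Fleiss' kappa needs at least 2 raters")
    N = table.shape[0]
    p_i = ((table**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_j = table.sum(axis=0) / (N * n)
    p_e = float((p_j**2).sum())
    if p_e >= 1.0:
        return None
    return float((p_bar - p_e) / (1.0 - p_e))


def fleiss_kappa(
    ratings: Sequence[RatingRecord],
    modality: str,
    *,
    binary: bool = False,
    subject_ids: Optional[Sequence[str]] = None,
) -> KappaResult:
    """Fleiss' kappa for one modality.

    ``subject_ids`` restricts the computation, e.g. to the patient cohort
    (the default convention for interrater reliability here).
    """
    categories = BINARY_CATEGORIES if binary else THREE_CATEGORIES
    table, subjects, raters = rating_count_table(
        ratings, modality, categories, binary=binary, subject_ids=subject_ids
    )
    return KappaResult(
        modality=modality,
        kappa=kappa_from_table(table),
        n_subjects=len(subjects),
        n_raters=len(raters),
        categories=categories,
    )


def _cohort_subjects(cohort: Sequence[SubjectMeta], role: str, modality: str):
    return [m for m in cohort if m.role == role and m.has_modality(modality)]


def _ratings_by_rater(ratings, modality, subject_ids):
    keep = set(subject_ids)
    by_rater: dict[str, dict[str, RatingRecord]] = {}
    for r in ratings:
        if r.modality == modality and r.subject_id in keep:
            by_rater.setdefault(r.rater_id, {})[r.subject_id] = r
    for rid, d in by_rater.items():
        missing = keep - set(d)
        if missing:
            raise ValidationError(
                f"rater {rid!r} missing {modality} ratings for {sorted(missing)}"
            )
    return by_rater


def diagnosis_rates(
    ratings: Sequence[RatingRecord],
    cohort: Sequence[SubjectMeta],
    modality: str,
) -> RaterRates:
    """Per-rater percentage of patients called positive, the mean over
    raters, and the consensus rate (all raters positive *on the same side*)."""
    patients = _cohort_subjects(cohort, "patient", modality)
    if not patients:
        raise ValidationError(f"no patients with modality {modality}")
    sids = [m.subject_id for m in patients]
    by_rater = _ratings_by_rater(ratings, modality, sids)
    rater_ids = sorted(by_rater)
    n = len(sids)
    per_rater = [
        100.0 * sum(by_rater[rid][s].hod_present for s in sids) / n
        for rid in rater_ids
    ]
    consensus = 0
    for s in sids:
        calls = [by_rater[rid][s] for rid in rater_ids]
        if all(c.hod_present for c in calls) and len({c.side for c in calls}) == 1:
            consensus += 1
    return RaterRates(
        modality=modality,
        rater_ids=rater_ids,
        per_rater_diagnosis_pct=per_rater,
        mean_diagnosis_pct=float(np.mean(per_rater)),
        consensus_pct=100.0 * consensus / n,
        n_subjects=n,
    )


def false_positive_rates(
    ratings: Sequence[RatingRecord],
    cohort: Sequence[SubjectMeta],
    modality: str,
) -> FalsePositiveRates:
    """False-positive percentages per rater and averaged over raters.

    Controls: any positive call is a false positive.  Patients: a positive
    call whose side differs from the expected degeneration side is counted
    as false positive (laterality criterion).
    """
    controls = _cohort_subjects(cohort, "control", modality)
    patients = _cohort_subjects(cohort, "patient", modality)
    expected = {m.subject_id: m.expected_hod_side for m in patients}

    control_pct: list[float] = []
    patient_pct: list[float] = []
    rater_ids: list[str] = []

    if controls:
        by_rater_c = _ratings_by_rater(
            ratings, modality, [m.subject_id for m in controls]
        )
        rater_ids = sorted(by_rater_c)
        for rid in rater_ids:
            fp = sum(r.hod_present for r in by_rater_c[rid].values())
            control_pct.append(100.0 * fp / len(controls))
    if patients:
        by_rater_p = _ratings_by_rater(
            ratings, modality, [m.subject_id for m in patients]
        )
        if not rater_ids:
            rater_ids = sorted(by_rater_p)
        for rid in rater_ids:
            fp = sum(
                r.hod_present and r.side != expected[s]
                for s, r in by_rater_p[rid].items()
            )
            patient_pct.append(100.0 * fp / len(patients))

    return FalsePositiveRates(
        modality=modality,
        rater_ids=rater_ids,
        control_per_rater_pct=control_pct,
        control_mean_pct=float(np.mean(control_pct)) if control_pct else float("nan"),
        patient_per_rater_pct=patient_pct,
        patient_mean_pct=float(np.mean(patient_pct)) if patient_pct else float("nan"),
    )
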