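"""Synthetic cohorts and simulated reviewers with known ground truth.

The cohort generator emulates the study conditions: a disease-control
group whose residual left/right asymmetry follows a zero-mean signed
imbalance (so the unsigned asymmetry index is folded-normal, with the
per-modality SD chosen so the control mean lands near the observed
1.2-2.1 % range), and a patient group carrying a unilateral lesion whose
olivary degeneration develops with probability
``hod_prevalence_in_patients`` (recruitment precedes the diagnosis, so
not every patient develops the finding).  Planted intensity effects are
drawn from a right-skewed truncated log-normal; FA/MD effects scale with
the intensity effect, so subthreshold patients also have mild diffusion
changes.

DTI maps are generated for patients only (controls were not scanned with
DTI in the emulated design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import RatingRecord, SubjectMeta, ValidationError
from .phantom import GroundTruth, PhantomResult, PhantomSpec, generate_phantom

#: sqrt(pi/2): folded-normal mean factor.  If the signed imbalance is
#: N(0, sigma), the unsigned asymmetry index has mean sigma*sqrt(2/pi);
#: these SDs put the control means at 1.21 / 1.37 / 2.14 %.
_FOLD = math.sqrt(math.pi / 2.0)


def _default_control_sd():
    return {"PD": 1.21 * _FOLD, "T2": 1.37 * _FOLD, "FLAIR": 2.14 * _FOLD}


@dataclass
class EffectDistribution:
    """Truncated log-normal over fractional intensity effects."""

    median: float = 0.25
    log_sd: float = 0.6
    lower: float = 0.0
    upper: float = 0.5

    def sample(self, rng: np.random.Generator) -> float:
        mu = math.log(self.median)
        lo = 0.0 if self.lower <= 0 else norm.cdf((math.log(self.lower) - mu) / self.log_sd)
        hi = norm.cdf((math.log(self.upper) - mu) / self.log_sd)
        u = rng.uniform(lo, hi)
        return float(math.exp(mu + self.log_sd * norm.ppf(u)))


@dataclass
class CohortSpec:
    n_patients: int
    n_controls: int
    control_asymmetry_sd: dict = field(default_factory=_default_control_sd)
    patient_effect: EffectDistribution = field(default_factory=EffectDistribution)
    hod_prevalence_in_patients: float = 0.8
    #: DTI effect severity ramps as (intensity_effect / ref)**exponent,
    #: capped: patients at or above the reference effect carry the nominal
    #: FA/MD effects while mild (subthreshold) cases carry only faint
    #: diffusion changes, mirroring the observed near-zero PD- subgroup.
    dti_severity_ref: float = 0.25
    dti_severity_exponent: float = 2.0
    dti_severity_cap: float = 1.0
    n_flair_missing_patients: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    include_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValidationError("cohort sizes must be >= 0")
        if not 0.0 <= self.hod_prevalence_in_patients <= 1.0:
            raise ValidationError("prevalence must be in [0, 1]")
        if self.n_flair_missing_patients > self.n_patients:
            raise ValidationError("cannot drop FLAIR from more patients than exist")


@dataclass
class SubjectData:
    meta: SubjectMeta
    volumes: dict
    landmarks: dict
    truth: GroundTruth


def _plan_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort-level ground truth (no volumes yet)."""
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = np.random.SeedSequence(spec.seed + 1).generate_state(
        spec.n_patients + spec.n_controls
    )

    rows = []
    idx = 0
    for i in range(spec.n_patients):
        sid = f"pat{i:03d}"
        side = "left" if rng.random() < 0.5 else "right"
        has_hod = rng.random() < spec.hod_prevalence_in_patients
        effect = spec.patient_effect.sample(rng) if has_hod else 0.0
        severity = min(
            (effect / spec.dti_severity_ref) ** spec.dti_severity_exponent,
            spec.dti_severity_cap,
        )
        g = {
            m: rng.normal(0.0, sd)
            for m, sd in spec.control_asymmetry_sd.items()
        }
        mods = {"PD", "T2", "FLAIR", "FA", "MD"}
        if i < spec.n_flair_missing_patients:
            mods.discard("FLAIR")
        rows.append(dict(
            subject_id=sid, role="patient", expected_side=side,
            has_hod=has_hod, hod_side=side if has_hod else "none",
            intensity_effect=effect,
            fa_effect=spec.phantom.hod_fa_effect * severity,
            md_effect=spec.phantom.hod_md_effect * severity,
            g_PD=g.get("PD", 0.0), g_T2=g.get("T2", 0.0),
            g_FLAIR=g.get("FLAIR", 0.0),
            modalities="|".join(sorted(mods)),
            seed=int(subject_seeds[idx]),
        ))
        idx += 1
    for i in range(spec.n_controls):
        sid = f"ctl{i:03d}"
        g = {m: rng.normal(0.0, sd) for m, sd in spec.control_asymmetry_sd.items()}
        rows.append(dict(
            subject_id=sid, role="control", expected_side="none",
            has_hod=False, hod_side="none", intensity_effect=0.0,
            fa_effect=0.0, md_effect=0.0,
            g_PD=g.get("PD", 0.0), g_T2=g.get("T2", 0.0),
            g_FLAIR=g.get("FLAIR", 0.0),
            modalities="PD|T2|FLAIR",
            seed=int(subject_seeds[idx]),
        ))
        idx += 1
    return pd.DataFrame(rows)


def _meta_from_row(row) -> SubjectMeta:
    return SubjectMeta(
        subject_id=row["subject_id"],
        role=row["role"],
        expected_hod_side=row["expected_side"],
        lesion_location="synthetic lesion" if row["role"] == "patient" else "",
        modalities_present=frozenset(row["modalities"].split("|")),
    )


def _spec_from_row(spec: CohortSpec, row) -> PhantomSpec:
    noise = dict(spec.phantom.noise_sd)
    if not spec.include_noise:
        noise = {k: 0.0 for k in noise}
    return replace(
        spec.phantom,
        subject_id=row["subject_id"],
        hod_side=row["hod_side"],
        hod_intensity_effect=float(row["intensity_effect"]),
        hod_fa_effect=float(row["fa_effect"]),
        hod_md_effect=float(row["md_effect"]),
        lateral_imbalance_percent={
            "PD": float(row["g_PD"]), "T2": float(row["g_T2"]),
            "FLAIR": float(row["g_FLAIR"]),
        },
        noise_sd=noise,
        seed=int(row["seed"]),
    )


def realize_subject(spec: CohortSpec, row) -> SubjectData:
    """Generate one planned subject's volumes and landmarks."""
    meta = _meta_from_row(row)
    result: PhantomResult = generate_phantom(_spec_from_row(spec, row))
    volumes = {m: v for m, v in result.volumes.items() if meta.has_modality(m)}
    landmarks = {m: l for m, l in result.landmarks.items() if meta.has_modality(m)}
    return SubjectData(meta=meta, volumes=volumes, landmarks=landmarks,
                       truth=result.truth)


def iter_cohort(spec: CohortSpec) -> Iterator[SubjectData]:
    """Stream the cohort one subject at a time (memory-friendly)."""
    plan = _plan_cohort(spec)
    for _, row in plan.iterrows():
        yield realize_subject(spec, row)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectData], pd.DataFrame]:
    """Materialize the full cohort plus its ground-truth table.

    For large cohorts prefer :func:`iter_cohort` together with
    :func:`cohort_truth_table` to avoid holding every volume in memory.
    """
    plan = _plan_cohort(spec)
    subjects = [realize_subject(spec, row) for _, row in plan.iterrows()]
    return subjects, plan


def cohort_truth_table(spec: CohortSpec) -> pd.DataFrame:
    """The ground-truth table alone (deterministic given the spec)."""
    return _plan_cohort(spec)


@dataclass
class RaterModel:
    """A simulated reviewer with fixed operating characteristics."""

    rater_id: str
    sensitivity: float = 0.85
    specificity: float = 0.93
    laterality_error_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "laterality_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


_FLIP = {"left": "right", "right": "left"}


def simulate_raters(
    metas: Sequence[SubjectMeta],
    truth: pd.DataFrame,
    raters: Sequence[RaterModel],
    modalities: Sequence[str] = ("PD", "T2", "FLAIR"),
) -> list[RatingRecord]:
    """Simulate blinded reviews of the cohort.

    For degeneration-positive subjects each rater calls positive with
    probability ``sensitivity`` and, when positive, reports the wrong
    side with probability ``laterality_error_rate``.  For negative
    subjects the rater calls positive with probability
    ``1 - specificity`` with a uniformly random side.  Fully seeded and
    reproducible per rater.
    """
    by_id = truth.set_index("subject_id")
    records: list[RatingRecord] = []
    for rater in raters:
        rng = np.random.default_rng(rater.seed)
        for meta in metas:
            if meta.subject_id not in by_id.index:
                raise ValidationError(f"no ground truth for subject {meta.subject_id!r}")
            row = by_id.loc[meta.subject_id]
            positive_truth = bool(row["has_hod"])
            for m in modalities:
                if not meta.has_modality(m):
                    continue
                if positive_truth:
                    called = rng.random() < rater.sensitivity
                    if called:
                        side = row["hod_side"]
                        if rng.random() < rater.laterality_error_rate:
                            side = _FLIP[side]
                        records.append(RatingRecord(rater.rater_id, meta.subject_id,
                                                    m, True, side))
                        continue
                else:
                    called = rng.random() >= rater.specificity
                    if called:
                        side = "left" if rng.random() < 0.5 else "right"
                        records.append(RatingRecord(rater.rater_id, meta.subject_id,
                                                    m, True, side))
                        continue
                records.append(RatingRecord(rater.rater_id, meta.subject_id,
                                            m, False, "none"))
    return records
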