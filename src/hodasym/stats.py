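"""Statistical comparisons used by the study design.

Normality is screened with the Kolmogorov-Smirnov-Lilliefors test
(null parameters estimated from the sample; p-value by seeded
Monte-Carlo simulation of the null).  Normally distributed data are
compared with the paired t-test (within group) or Welch's t-test
(between groups); otherwise the Wilcoxon-Mann-Whitney test is used.
All tests are two-sided; significance is declared at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .asymmetry import DTIAsymmetry
from .calibration import HODCall
from .core import ValidationError

ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str  # lilliefors | paired_t | welch_t | wilcoxon_mann_whitney
    statistic: float
    p_value: float
    n1: int
    n2: int
    significant: bool
    df: Optional[float] = None
    degenerate: bool = False

    @classmethod
    def make(cls, name, stat, p, n1, n2, df=None, degenerate=False) -> "TestResult":
        return cls(name, float(stat), float(p), int(n1), int(n2),
                   bool(p < ALPHA), df, degenerate)


def _as_array(x, name="sample") -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValidationError(f"{name} must be 1-D")
    return a


def lilliefors_statistic(sample: np.ndarray) -> float:
    """KS distance of the standardized sample against the standard normal."""
    stat, _ = _sm_lilliefors(sample, dist="norm", pvalmethod="approx")
    return float(stat)


def _batch_lilliefors_null(n: int, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo sample of the Lilliefors statistic under the normal null."""
    x = rng.standard_normal((n_mc, n))
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    x.sort(axis=1)
    cdf = sps.norm.cdf(x)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_normality(
    sample: Sequence[float], *, n_mc: int = 10_000, seed: int = 0
) -> TestResult:
    """Kolmogorov-Smirnov-Lilliefors normality test.

    The p-value is the exceedance fraction of the observed KS distance in
    ``n_mc`` seeded Monte-Carlo replicates of the null (standard-normal
    samples of the same size, standardized the same way), with the +1
    correction so p is never exactly 0.
    """
    a = _as_array(sample)
    if a.size < 4:
        raise ValidationError("Lilliefors test needs n >= 4")
    if a.std(ddof=1) == 0:
        raise ValidationError("Lilliefors test undefined for zero-variance samples")
    d_obs = lilliefors_statistic(a)
    rng = np.random.default_rng(seed)
    d_null = _batch_lilliefors_null(a.size, n_mc, rng)
    p = (1 + int((d_null >= d_obs).sum())) / (n_mc + 1)
    return TestResult.make("lilliefors", d_obs, p, a.size, 0)


def paired_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided paired t-test (one-sample t on the differences)."""
    a, b = _as_array(sample_a, "sample_a"), _as_array(sample_b, "sample_b")
    if a.size != b.size:
        raise ValidationError("paired samples must have equal length")
    if a.size < 2:
        raise ValidationError("paired t-test needs n >= 2")
    if np.std(a - b, ddof=1) == 0:
        raise ValidationError("zero variance of the paired differences")
    res = sps.ttest_rel(a, b)
    return TestResult.make("paired_t", res.statistic, res.pvalue,
                           a.size, b.size, df=float(res.df))


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Welch t-test (unequal variances, Welch-Satterthwaite df).

    The degenerate case of two zero-variance samples is guarded: equal
    constants give t = 0, p = 1; distinct constants are flagged with an
    infinite statistic and p = 0.
    """
    a, b = _as_array(sample_a, "sample_a"), _as_array(sample_b, "sample_b")
    if a.size < 2 or b.size < 2:
        raise ValidationError("Welch test needs n >= 2 in both samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult.make("welch_t", 0.0, 1.0, a.size, b.size,
                                   degenerate=True)
        sign = math.copysign(1.0, a.mean() - b.mean())
        return TestResult.make("welch_t", sign * math.inf, 0.0, a.size, b.size,
                               degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult.make("welch_t", res.statistic, res.pvalue,
                           a.size, b.size, df=float(res.df))


def wilcoxon_mann_whitney(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney (Mann-Whitney U) test.

    The exact null distribution (full enumeration) is used when the
    smaller sample has at most 8 observations and there are no ties;
    otherwise the normal approximation with tie correction is used.
    """
    a, b = _as_array(sample_a, "sample_a"), _as_array(sample_b, "sample_b")
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(a.size, b.size) <= 8 and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult.make("wilcoxon_mann_whitney", res.statistic,
                           min(1.0, res.pvalue), a.size, b.size)


def compare_groups(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    *,
    paired: bool = False,
    seed: int = 0,
) -> tuple[TestResult, dict]:
    """Normality-routed comparison of two samples.

    Each sample (the paired differences, when ``paired``) is screened
    with the Lilliefors test; if nothing rejects normality at 0.05, the
    parametric test (paired or Welch t) is used, otherwise the
    Wilcoxon-Mann-Whitney test.  Returns the test result together with a
    routing log (the normality p-values and the chosen branch).
    """
    a, b = _as_array(sample_a, "sample_a"), _as_array(sample_b, "sample_b")
    routing: dict = {"paired": paired}
    if paired:
        norm = lilliefors_normality(a - b, seed=seed)
        routing["lilliefors_p"] = [norm.p_value]
        normal = not norm.significant
    else:
        norm_a = lilliefors_normality(a, seed=seed)
        norm_b = lilliefors_normality(b, seed=seed + 1)
        routing["lilliefors_p"] = [norm_a.p_value, norm_b.p_value]
        normal = not (norm_a.significant or norm_b.significant)
    routing["normal"] = normal
    if normal:
        result = paired_t(a, b) if paired else welch_t(a, b)
    else:
        result = wilcoxon_mann_whitney(a, b)
    routing["test"] = result.test_name
    return result, routing


@dataclass
class SubgroupContrast:
    """FA or MD expected-side asymmetry contrasted between patients whose
    PD asymmetry does (PD+) or does not (PD-) exceed the calibrated
    threshold."""

    map: str
    mean_diff_pd_minus: float
    mean_diff_pd_plus: float
    n_pd_minus: int
    n_pd_plus: int
    test: Optional[TestResult]  # None => not computable (an empty group)


def subgroup_contrast(
    dti: Sequence[DTIAsymmetry], pd_calls: Sequence[HODCall]
) -> dict[str, SubgroupContrast]:
    """Partition signed FA/MD asymmetries by the PD threshold call.

    Every DTI subject must have a PD call; group means and the Welch test
    are reported per map.  An empty group yields a contrast whose test is
    marked not-computable (``None``).
    """
    call_by_subject = {c.subject_id: c for c in pd_calls if c.modality == "PD"}
    out: dict[str, SubgroupContrast] = {}
    for map_name in ("FA", "MD"):
        rows = [d for d in dti if d.map == map_name]
        plus, minus = [], []
        for d in rows:
            if d.subject_id not in call_by_subject:
                raise ValidationError(
                    f"DTI subject {d.subject_id!r} has no PD threshold call"
                )
            if call_by_subject[d.subject_id].exceeds_threshold:
                plus.append(d.signed_diff_percent)
            else:
                minus.append(d.signed_diff_percent)
        test = None
        if len(plus) >= 2 and len(minus) >= 2:
            test = welch_t(plus, minus)
        out[map_name] = SubgroupContrast(
            map=map_name,
            mean_diff_pd_minus=float(np.mean(minus)) if minus else float("nan"),
            mean_diff_pd_plus=float(np.mean(plus)) if plus else float("nan"),
            n_pd_minus=len(minus),
            n_pd_plus=len(plus),
            test=test,
        )
    return out
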