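"""Interrater agreement and diagnosis-rate arithmetic."""

import itertools

import numpy as np
import pytest

from hodasym.core import RatingRecord, SubjectMeta, ValidationError
from hodasym.raters import (
    diagnosis_rates,
    false_positive_rates,
    fleiss_kappa,
    kappa_from_table,
)


def brute_force_kappa(assignments):
    """Independent oracle: agreement from raw per-subject assignment lists.

    ``assignments``: list over subjects of the list of category labels the
    raters gave.  Pairwise agreement fraction per subject, overall category
    proportions for chance agreement.
    """
    n = len(assignments[0])
    pbar_terms = []
    for cats in assignments:
        agree = sum(
            1 for r1, r2 in itertools.combinations(range(n), 2)
            if cats[r1] == cats[r2]
        )
        pbar_terms.append(agree / (n * (n - 1) / 2))
    pbar = float(np.mean(pbar_terms))
    flat = [c for cats in assignments for c in cats]
    pe = sum((flat.count(c) / len(flat)) ** 2 for c in set(flat))
    if pe >= 1.0:
        return None
    return (pbar - pe) / (1.0 - pe)


def _records_from_assignments(assignments, modality="PD"):
    cat_to_call = {
        "none": (False, "none"), "left": (True, "left"), "right": (True, "right")
    }
    records = []
    for i, cats in enumerate(assignments):
        for j, cat in enumerate(cats):
            present, side = cat_to_call[cat]
            records.append(RatingRecord(f"r{j}", f"s{i:02d}", modality,
                                        present, side))
    return records


class TestFleissKappa:
    def test_perfect_agreement_mixed_categories(self):
        assignments = [["left"] * 3, ["none"] * 3, ["right"] * 3, ["none"] * 3]
        res = fleiss_kappa(_records_from_assignments(assignments), "PD")
        assert res.kappa == pytest.approx(1.0)
        assert res.n_subjects == 4 and res.n_raters == 3

    def test_hand_value_minus_one_third(self):
        # 2 subjects, 3 raters, 2 categories, count rows (2,1) and (1,2)
        table = np.array([[2, 1], [1, 2]])
        assert kappa_from_table(table) == pytest.approx(-1 / 3)

    def test_single_category_undefined(self):
        assignments = [["none"] * 3, ["none"] * 3]
        res = fleiss_kappa(_records_from_assignments(assignments), "PD")
        assert res.kappa is None and not res.defined

    def test_unbalanced_rejected(self):
        records = _records_from_assignments([["left"] * 3, ["none"] * 3])
        with pytest.raises(ValidationError):
            fleiss_kappa(records[:-1], "PD")

    def test_matches_brute_force_and_statsmodels_on_random_tables(self, rng):
        """Exhaustive small-instance check: random tables with N <= 6
        subjects, n <= 4 raters, 3 categories against (a) a pairwise
        agreement oracle and (b) statsmodels' implementation."""
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa

        cats = ["none", "left", "right"]
        for _ in range(300):
            N = rng.integers(2, 7)
            n = rng.integers(2, 5)
            assignments = [
                [cats[k] for k in rng.integers(0, 3, size=n)] for _ in range(N)
            ]
            res = fleiss_kappa(_records_from_assignments(assignments), "PD")
            expected = brute_force_kappa(assignments)
            if expected is None:
                assert res.kappa is None
                continue
            assert res.kappa == pytest.approx(expected, abs=1e-12)
            table = np.zeros((N, 3))
            for i, row in enumerate(assignments):
                for c in row:
                    table[i, cats.index(c)] += 1
            assert res.kappa == pytest.approx(sm_kappa(table), abs=1e-9)

    def test_invariant_under_relabeling_and_subject_permutation(self, rng):
        cats = ["none", "left", "right"]
        assignments = [
            [cats[k] for k in rng.integers(0, 3, size=3)] for _ in range(6)
        ]
        base = brute_force_kappa(assignments)
        relabel = {"none": "left", "left": "right", "right": "none"}
        relabeled = [[relabel[c] for c in row] for row in assignments]
        permuted = assignments[::-1]
        assert brute_force_kappa(relabeled) == pytest.approx(base)
        k1 = fleiss_kappa(_records_from_assignments(assignments), "PD").kappa
        k2 = fleiss_kappa(_records_from_assignments(permuted), "PD").kappa
        assert k1 == pytest.approx(k2)

    def test_binary_mode_collapses_laterality(self):
        # raters agree on presence but not side: binary kappa is perfect,
        # three-category kappa is not
        assignments = [["left", "right", "left"], ["none"] * 3]
        recs = _records_from_assignments(assignments)
        assert fleiss_kappa(recs, "PD", binary=True).kappa == pytest.approx(1.0)
        assert fleiss_kappa(recs, "PD").kappa < 1.0


def _patients(n, side="right"):
    return [SubjectMeta(f"s{i:02d}", "patient", side) for i in range(n)]


def _controls(n, offset=100):
    return [SubjectMeta(f"s{i + offset:03d}", "control") for i in range(n)]


def _ratings(positive_counts, cohort, modality="PD", side="right"):
    """rater j calls the first positive_counts[j] subjects positive."""
    records = []
    for j, k in enumerate(positive_counts):
        for i, meta in enumerate(cohort):
            present = i < k
            records.append(RatingRecord(
                f"r{j}", meta.subject_id, modality, present,
                side if present else "none"))
    return records


class TestDiagnosisRates:
    def test_printed_per_rater_and_mean(self):
        cohort = _patients(15)
        rates = diagnosis_rates(_ratings([8, 9, 10], cohort), cohort, "PD")
        assert rates.per_rater_diagnosis_pct == pytest.approx(
            [100 * 8 / 15, 100 * 9 / 15, 100 * 10 / 15])  # 53.3/60/66.7
        assert rates.mean_diagnosis_pct == pytest.approx(60.0)

    def test_consensus_requires_same_side(self):
        cohort = _patients(15)
        # all three raters positive on the first 6 patients, same side
        rates = diagnosis_rates(_ratings([6, 6, 6], cohort), cohort, "PD")
        assert rates.consensus_pct == pytest.approx(40.0)
        # divergent side on one consensus subject breaks its consensus
        recs = _ratings([6, 6, 6], cohort)
        recs = [
            RatingRecord(r.rater_id, r.subject_id, r.modality, r.hod_present, "left")
            if (r.rater_id == "r2" and r.subject_id == "s00" and r.hod_present)
            else r
            for r in recs
        ]
        assert diagnosis_rates(recs, cohort, "PD").consensus_pct == pytest.approx(
            100 * 5 / 15)

    def test_zero_positives(self):
        cohort = _patients(4)
        rates = diagnosis_rates(_ratings([0, 0, 0], cohort), cohort, "PD")
        assert rates.mean_diagnosis_pct == 0.0 and rates.consensus_pct == 0.0

    def test_missing_rating_errors(self):
        cohort = _patients(3)
        recs = _ratings([1, 1, 1], cohort)[:-1]
        with pytest.raises(ValidationError):
            diagnosis_rates(recs, cohort, "PD")


class TestFalsePositiveRates:
    def test_single_control_false_positive_means_2_2_percent(self):
        """One positive control call across 3 raters x 15 controls."""
        cohort = _controls(15)
        recs = _ratings([1, 0, 0], cohort, "T2", side="left")
        fp = false_positive_rates(recs, cohort, "T2")
        assert fp.control_per_rater_pct == pytest.approx([100 / 15, 0.0, 0.0])
        assert fp.control_mean_pct == pytest.approx(100 / 45)  # 2.2%

    def test_control_counts_0_1_2_mean_6_7_percent(self):
        cohort = _controls(15)
        fp = false_positive_rates(_ratings([0, 1, 2], cohort, "FLAIR", "left"),
                                  cohort, "FLAIR")
        assert fp.control_mean_pct == pytest.approx(100 * 3 / 45)  # 6.7%

    def test_patient_calls_on_expected_side_are_not_false_positive(self):
        cohort = _patients(10, side="right")
        recs = _ratings([5, 5, 5], cohort, side="right")
        fp = false_positive_rates(recs, cohort, "PD")
        assert fp.patient_mean_pct == 0.0

    def test_contralateral_patient_calls_are_false_positive(self):
        cohort = _patients(15, side="right")
        recs = _ratings([1, 1, 2], cohort, side="left")  # all on the wrong side
        fp = false_positive_rates(recs, cohort, "PD")
        assert fp.patient_mean_pct == pytest.approx(100 * 4 / 45)  # 8.9%
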