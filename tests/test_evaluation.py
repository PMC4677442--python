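"""Crossover design, arm summaries, and the statistical test battery
checked against independent closed-form / enumeration oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from lysisgate import CASE_TRUTH, MissModel, simulate_responses
from lysisgate.evaluation import (
    AssignmentError,
    MWMode,
    PUBLISHED_PER_ITEM_MISSES,
    REFERENCE_ASSIGNMENT,
    STUDY_ITEM_IDS,
    ArmResults,
    TVariant,
    analyze_study,
    chi_square_2x2,
    counterbalanced_assignment,
    mann_whitney,
    n_opportunities,
    replay_published_counts,
    summarize_arm,
    two_sample_t,
    validate_assignment,
)

CONTROL_ITEMS = [2, 6, 5, 2, 1, 7]
INTERVENTION_ITEMS = [0, 1, 1, 1, 0, 4]


# ---------------------------------------------------------------- oracles

def pooled_t_oracle(x, y):
    """Closed-form pooled-variance two-sample t, independent of scipy."""
    x, y = list(map(float, x)), list(map(float, y))
    n1, n2 = len(x), len(y)
    m1, m2 = sum(x) / n1, sum(y) / n2
    ss1 = sum((v - m1) ** 2 for v in x)
    ss2 = sum((v - m2) ** 2 for v in y)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2


def chi2_2x2_oracle(a, b, c, d):
    """n (ad - bc)^2 / (row and column products)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def exact_mw_p_oracle(x, y):
    """Independent exact two-sided U-test p via scipy's permutation_test
    (full enumeration; handles ties)."""

    def u_stat(xs, ys):
        ranks = sps.rankdata(np.concatenate([xs, ys]))
        n1 = len(xs)
        return ranks[:n1].sum() - n1 * (n1 + 1) / 2

    res = sps.permutation_test(
        (np.asarray(x, float), np.asarray(y, float)), u_stat,
        permutation_type="independent", alternative="two-sided",
        n_resamples=np.inf)
    return float(res.pvalue)


# ----------------------------------------------------------------- design

class TestDesign:
    def test_reference_layout(self):
        pa = REFERENCE_ASSIGNMENT.assignments[0]
        assert pa.control_cases == (1, 2) and pa.intervention_cases == (3, 4)
        counts = validate_assignment(REFERENCE_ASSIGNMENT)
        assert all(k == 6 for arm in counts.values() for k in arm.values())
        assert counterbalanced_assignment(12, (1, 2, 3, 4)) == REFERENCE_ASSIGNMENT

    def test_opportunities_per_arm(self):
        assert n_opportunities(REFERENCE_ASSIGNMENT, CASE_TRUTH) == 54

    def test_seeded_assignment_valid(self):
        seeded = counterbalanced_assignment(12, (1, 2, 3, 4), seed=5)
        counts = validate_assignment(seeded)
        assert all(k == 6 for arm in counts.values() for k in arm.values())

    def test_infeasible_balance_rejected(self):
        with pytest.raises(AssignmentError, match="multiple of 6"):
            counterbalanced_assignment(10, (1, 2, 3, 4))


# -------------------------------------------------------------- summaries

class TestSummaries:
    def _arm(self, name, counts, per_phys=None):
        return ArmResults(
            arm=name, item_ids=STUDY_ITEM_IDS,
            per_item_missed=dict(zip(STUDY_ITEM_IDS, counts)),
            per_physician_missed=per_phys, opportunities=54, n_physicians=12)

    def test_control_summary_matches_reference_display(self):
        s = summarize_arm(self._arm("control", CONTROL_ITEMS)).display()
        assert s["total_missed"] == 23
        assert s["pct_missed"] == 42.6
        assert s["per_item_mean"] == 3.8
        assert s["per_item_sd"] == 2.5
        assert s["per_item_median"] == 3.5
        assert s["per_physician_mean"] == 1.9

    def test_intervention_summary_matches_reference_display(self):
        s = summarize_arm(self._arm("intervention", INTERVENTION_ITEMS)).display()
        assert s["total_missed"] == 7
        assert s["pct_missed"] == 13.0
        assert s["per_item_mean"] == 1.2
        assert s["per_item_sd"] == 1.5
        assert s["per_item_median"] == 1.0
        assert s["per_physician_mean"] == 0.6

    def test_all_zero_counts(self):
        s = summarize_arm(self._arm("x", [0] * 6))
        assert (s.total_missed, s.pct_missed, s.per_item_sd) == (0, 0.0, 0.0)

    def test_per_physician_totals_must_agree(self):
        with pytest.raises(ValueError, match="per-physician total"):
            self._arm("x", CONTROL_ITEMS, per_phys={p: 0 for p in range(1, 13)})


# ------------------------------------------------------------------ tests

class TestTwoSampleT:
    def test_study_vectors_match_closed_form(self):
        res = two_sample_t(CONTROL_ITEMS, INTERVENTION_ITEMS, TVariant.POOLED)
        t, df = pooled_t_oracle(CONTROL_ITEMS, INTERVENTION_ITEMS)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == df == 10
        assert res.statistic == pytest.approx(2.262, abs=5e-3)
        assert res.p_value == pytest.approx(0.047, abs=5e-3)
        assert res.p_value < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_samples_match_closed_form_to_1e10(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(1.0, 2.0, size=rng.integers(3, 12))
        y = rng.normal(0.0, 1.5, size=rng.integers(3, 12))
        res = two_sample_t(x, y, TVariant.POOLED)
        t, df = pooled_t_oracle(x, y)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), df), abs=1e-10)

    def test_equal_samples_give_t_zero_p_one(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_welch_variant_flagged(self):
        res = two_sample_t(CONTROL_ITEMS, INTERVENTION_ITEMS, TVariant.WELCH)
        assert res.flags["variant"] == "WELCH"
        assert res.df != 10  # Welch df is fractional here

    def test_zero_variance_different_means_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1, 1, 1], [2, 2, 2])


class TestMannWhitney:
    def test_study_vectors_exact_matches_enumeration_oracle(self):
        """924-arrangement exact test on the per-item vectors."""
        res = mann_whitney(CONTROL_ITEMS, INTERVENTION_ITEMS, MWMode.EXACT)
        assert res.flags["arrangements"] == 924
        assert res.p_value == pytest.approx(
            exact_mw_p_oracle(CONTROL_ITEMS, INTERVENTION_ITEMS), abs=1e-10)
        assert res.p_value < 0.05

    def test_identical_singletons(self):
        assert mann_whitney([5], [5], MWMode.EXACT).p_value == 1.0

    @pytest.mark.parametrize(
        "x, y",
        [
            ([1, 2, 3], [4, 5, 6]),
            ([1, 1, 2, 2], [2, 3, 3]),
            ([0, 0, 0, 1], [1, 1, 2, 2, 2]),
            (list(range(8)), [v + 0.5 for v in range(8)]),
        ],
    )
    def test_exact_matches_independent_enumeration(self, x, y):
        res = mann_whitney(x, y, MWMode.EXACT)
        assert res.p_value == pytest.approx(exact_mw_p_oracle(x, y), abs=1e-10)

    def test_exact_and_normal_agree_on_untied_size_8(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        exact = mann_whitney(x, y, MWMode.EXACT)
        approx = mann_whitney(x, y, MWMode.NORMAL_APPROX)
        assert abs(exact.p_value - approx.p_value) < 0.02
        scipy_exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert exact.p_value == pytest.approx(float(scipy_exact.pvalue), abs=1e-10)

    def test_exact_beyond_enumeration_bound_rejected(self):
        with pytest.raises(ValueError, match="NORMAL_APPROX"):
            mann_whitney(list(range(12)), list(range(12)), MWMode.EXACT)


class TestChiSquare:
    def test_study_table_matches_hand_formula(self):
        res = chi_square_2x2([[23, 31], [7, 47]], correction=False)
        assert res.statistic == pytest.approx(chi2_2x2_oracle(23, 31, 7, 47), abs=1e-10)
        assert res.statistic == pytest.approx(11.82, abs=5e-3)
        assert res.p_value < 0.001

    def test_yates_correction_shrinks_statistic(self):
        plain = chi_square_2x2([[23, 31], [7, 47]], correction=False)
        yates = chi_square_2x2([[23, 31], [7, 47]], correction=True)
        assert yates.statistic < plain.statistic
        assert yates.statistic == pytest.approx(10.385, abs=5e-3)
        # both roundings agree the difference is significant at 0.001-ish
        assert yates.p_value < 0.0015

    def test_identical_rows_give_zero(self):
        res = chi_square_2x2([[10, 20], [10, 20]], correction=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])


# --------------------------------------------------------------- analysis

class TestAnalyzeStudy:
    def test_conservation_and_structure(self):
        responses = simulate_responses(REFERENCE_ASSIGNMENT, seed=9)
        report = analyze_study(REFERENCE_ASSIGNMENT, responses)
        for arm in ("control", "intervention"):
            summary = getattr(report, arm)
            per_item_total = sum(report.per_item_missed[arm].values())
            assert per_item_total == summary.total_missed
            assert summary.pct_missed == pytest.approx(100 * summary.total_missed / 54)
        row_sums = [sum(r) for r in report.missed_table]
        assert row_sums == [54, 54]

    def test_missing_cells_reported(self):
        responses = simulate_responses(REFERENCE_ASSIGNMENT, seed=9)
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            analyze_study(REFERENCE_ASSIGNMENT, responses[1:])

    def test_zero_miss_study_degenerates_gracefully(self):
        model = MissModel(p_control=0.0, p_intervention=0.0,
                          control_time_sd=0.0, intervention_time_sd=0.0)
        responses = simulate_responses(REFERENCE_ASSIGNMENT, miss_model=model, seed=1)
        report = analyze_study(REFERENCE_ASSIGNMENT, responses)
        assert report.control.total_missed == 0
        assert report.tests["chi2_missed"].flags.get("degenerate") or \
            report.tests["chi2_missed"].p_value == pytest.approx(1.0)
        t = report.tests["per_item_t"]
        assert t.flags.get("degenerate") or t.p_value == pytest.approx(1.0)


class TestReplay:
    def test_replayed_counts_reproduce_reference_results(self):
        control, intervention, tests = replay_published_counts()
        assert (control.total_missed, intervention.total_missed) == (23, 7)
        assert control.display()["pct_missed"] == 42.6
        assert intervention.display()["pct_missed"] == 13.0
        assert tests["per_item_t"].statistic == pytest.approx(2.263, abs=1e-3)
        assert tests["chi2_missed_uncorrected"].statistic == pytest.approx(11.815, abs=1e-3)
        # margins: 23 + 7 = 30 missed over both arms
        assert sum(PUBLISHED_PER_ITEM_MISSES["control"].values()) + \
            sum(PUBLISHED_PER_ITEM_MISSES["intervention"].values()) == 30
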