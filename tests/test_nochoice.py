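"""Anchoring, fecundity/viability estimators and the no-choice tests."""

import numpy as np
import pytest

from physaiso.nochoice import (
    F2CrossRecord,
    NoChoicePairRecord,
    anchor_week_one,
    delay_test,
    depressed_outcross_test,
    f2_fertility_summary,
    first_reproduction_test,
    pair_f1_viability,
    pair_mean_fecundity,
)


def record(embryos, hatchlings=None, alive=None, cross="outcross", pair_id="p"):
    n = len(embryos)
    if hatchlings is None:
        hatchlings = [0] * n
    if alive is None:
        alive = [True] * n
    return NoChoicePairRecord(pair_id, cross, tuple(embryos), tuple(hatchlings), tuple(alive))


def cohort_records(weekly_counts):
    """One record per pair; pair i starts ovipositing at its onset week."""
    # weekly_counts[w] = number of pairs laying in calendar week w+1
    n_pairs = max(weekly_counts, default=0)
    horizon = len(weekly_counts)
    recs = []
    for i in range(max(n_pairs, 3)):
        embryos = [10 if weekly_counts[w] > i else 0 for w in range(horizon)]
        recs.append(record(embryos, pair_id=f"p{i}"))
    return recs


class TestRecordInvariants:
    def test_hatchlings_bounded_by_cohort(self):
        with pytest.raises(ValueError, match="exceed embryos"):
            record([10], [11])

    def test_no_oviposition_after_death(self):
        with pytest.raises(ValueError, match="after parental death"):
            record([0, 5], [0, 0], alive=[False, False])

    def test_no_resurrection(self):
        with pytest.raises(ValueError, match="back to life"):
            record([0, 0], alive=[False, True])


class TestAnchorWeek:
    def test_first_week_with_three_pairs(self):
        assert anchor_week_one(cohort_records([0, 1, 2, 3, 4])) == 4

    def test_immediate(self):
        assert anchor_week_one(cohort_records([3, 0, 0])) == 1

    def test_study_like_onsets(self):
        # One set reaches the 3-pair threshold at week 5, another at week 7.
        early = cohort_records([0, 0, 1, 2, 3, 5])
        late = cohort_records([0, 0, 0, 1, 2, 2, 4])
        assert anchor_week_one(early) == 5
        assert anchor_week_one(late) == 7

    def test_no_anchor_flagged_as_none(self):
        assert anchor_week_one(cohort_records([0, 1, 2, 2, 1])) is None


class TestFirstReproductionTest:
    def test_complete_separation_hypergeometric_tail(self):
        p = first_reproduction_test([8] * 10, [3] * 10)
        assert p == pytest.approx(1 / 184756, rel=1e-9)

    def test_identical_groups(self):
        assert first_reproduction_test([4, 5, 6] * 3, [4, 5, 6] * 3) > 0.5

    def test_all_tied_at_median(self):
        assert first_reproduction_test([7] * 10, [7] * 10) == 1.0

    def test_symmetric_groups_not_significant(self):
        vals = [5, 6, 7, 8, 9] * 2
        assert first_reproduction_test(vals, list(vals)) > 0.5

    def test_antisymmetric_in_direction(self, rng):
        exp = rng.integers(3, 15, size=10).astype(float)
        ctrl = rng.integers(3, 15, size=10).astype(float)
        # Swapping the groups moves the same table to the opposite tail.
        from scipy.stats import fisher_exact

        med = np.median(np.concatenate([exp, ctrl]))
        table = [
            [int((exp > med).sum()), int((exp < med).sum())],
            [int((ctrl > med).sum()), int((ctrl < med).sum())],
        ]
        p_swapped = first_reproduction_test(ctrl, exp)
        assert p_swapped == pytest.approx(
            fisher_exact(table, alternative="less")[1]
        )

    def test_nonreproducers_fall_above_median(self):
        # +inf ages count as late, so an experiment full of non-reproducers
        # shows a significant delay.
        p = first_reproduction_test([np.inf] * 10, [3] * 10)
        assert p == pytest.approx(1 / 184756, rel=1e-9)

    def test_delay_conditions_on_slower_control(self):
        exp = [9] * 10
        fast = [3] * 10
        slow = [9] * 10
        assert delay_test(exp, fast, slow) == 1.0  # matches the slower control
        assert delay_test(exp, fast, fast) < 1e-4


class TestPairMeanFecundity:
    def test_leading_zeros_ignored_interior_zeros_kept(self):
        assert pair_mean_fecundity(record([0, 0, 5, 0, 7]), anchor=1) == 4.0

    def test_surviving_nonreproducer_scores_zero(self):
        assert pair_mean_fecundity(record([0] * 6), anchor=1) == 0.0

    def test_postmortem_weeks_censored(self):
        r = record([10, 10, 0, 0], alive=[True, True, False, False])
        assert pair_mean_fecundity(r, anchor=1) == 10.0

    def test_censoring_correctness(self):
        # Truncating the series at death never changes the estimate.
        full = record([0, 8, 4, 0, 0], alive=[True, True, True, False, False])
        trimmed = record([0, 8, 4], alive=[True, True, True])
        assert pair_mean_fecundity(full, 1) == pair_mean_fecundity(trimmed, 1)

    def test_dead_before_window_excluded(self):
        r = record([5, 0, 0], alive=[True, False, False])
        assert pair_mean_fecundity(r, anchor=2) is None

    def test_window_limits_exposure(self):
        r = record([0, 1, 1, 1, 99])
        assert pair_mean_fecundity(r, anchor=1, window=4) == 1.0


class TestPairF1Viability:
    def test_simple_ratio(self):
        r = record([50, 50], [30, 30])
        assert pair_f1_viability(r, 1) == pytest.approx(0.6)

    def test_zero_embryo_weeks_excluded_from_both_means(self):
        r = record([40, 0, 60], [20, 0, 40])
        assert pair_f1_viability(r, 1) == pytest.approx(0.6)

    def test_all_cohorts_fail(self):
        assert pair_f1_viability(record([30, 20], [0, 0]), 1) == 0.0

    def test_zero_fecundity_undefined(self):
        assert pair_f1_viability(record([0, 0, 0]), 1) is None

    def test_bounded_on_cohort_consistent_data(self, rng):
        from physaiso.simulate import NoChoiceSimParams, simulate_nochoice_experiment

        exp, _ = simulate_nochoice_experiment(NoChoiceSimParams(), rng)
        for cross in ("outcross", "control_a", "control_b"):
            anchor = anchor_week_one(exp.records(cross))
            for r in exp.records(cross):
                v = pair_f1_viability(r, anchor)
                assert v is None or 0.0 <= v <= 1.0


class TestDepressedOutcross:
    def test_complete_depression(self):
        res = depressed_outcross_test([0.0] * 10, [50.0] * 10, [50.0] * 10)
        # exact one-sided rank-sum tail 1/184756, Bonferroni-doubled
        assert res.p_vs_a == pytest.approx(2 / 184756, rel=1e-6)
        assert res.depressed(0.05)

    def test_identical_groups_not_significant(self):
        res = depressed_outcross_test([5.0] * 10, [5.0] * 10, [5.0] * 10)
        assert res.p_vs_a == 1.0 and res.kruskal_p == 1.0
        assert not res.depressed(0.05)

    def test_intermediate_experiment_not_depressed(self):
        res = depressed_outcross_test(
            [30.0 + i for i in range(10)],
            [50.0 + i for i in range(10)],
            [10.0 + i for i in range(10)],
        )
        assert res.p_vs_b > 0.5  # not below the lower control
        assert not res.depressed(0.05)

    def test_undefined_values_dropped_and_counted(self):
        res = depressed_outcross_test(
            [1.0, 2.0, None, np.nan], [3.0, 4.0, 5.0], [3.0, 4.0]
        )
        assert res.n_dropped == 2

    def test_type_one_error_calibrated(self, rng):
        # No true penalty: the depressed verdict should fire at <= alpha.
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            groups = rng.poisson(40.0, size=(3, 10)).astype(float)
            res = depressed_outcross_test(*groups)
            hits += res.depressed(0.05)
        assert hits / n_sim <= 0.05

    def test_power_against_halved_fecundity(self, rng):
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            exp = rng.poisson(20.0, size=10).astype(float)
            ctrl_a = rng.poisson(40.0, size=10).astype(float)
            ctrl_b = rng.poisson(40.0, size=10).astype(float)
            hits += depressed_outcross_test(exp, ctrl_a, ctrl_b).depressed(0.05)
        assert hits / n_sim > 0.5


class TestF2Summary:
    def test_sterile_despite_oviposition(self):
        recs = [F2CrossRecord(f"p{i}", "early", i < 8, False) for i in range(9)]
        s = f2_fertility_summary(recs)
        assert (s.n_ovipositing, s.n_with_viable_f2) == (8, 0)
        assert s.sterile

    def test_fully_fertile(self):
        recs = [F2CrossRecord(f"p{i}", "late", True, True) for i in range(9)]
        s = f2_fertility_summary(recs)
        assert (s.n_ovipositing, s.n_with_viable_f2) == (9, 9)
        assert not s.sterile

    def test_nothing_happened(self):
        recs = [F2CrossRecord(f"p{i}", "middle", False, False) for i in range(9)]
        s = f2_fertility_summary(recs)
        assert (s.n_ovipositing, s.n_with_viable_f2) == (0, 0)
        assert not s.sterile  # no oviposition: fertility unobserved, not nil

    def test_incomplete_series_warns(self):
        with pytest.warns(UserWarning, match="of 9 expected"):
            s = f2_fertility_summary([F2CrossRecord("p", "early", True, True)])
        assert not s.complete
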