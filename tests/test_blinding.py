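"""Bang/James index computation: worked examples and algebraic properties."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blindtrial.blinding import (
    ArmResponseTable,
    BlindingEstimate,
    CollapsedCounts,
    GuessCategory,
    bang_estimate,
    bang_point,
    bang_variance,
    classify_blinding,
    collapse_responses,
    james_ci,
    james_estimate,
    james_point,
    respondent_scores,
    round_half_away,
    summed_bang,
    wald_ci,
)

ACTIVE_TABLE = ArmResponseTable("active", strongly_active=6, dont_know=5)
CONTROL_TABLE = ArmResponseTable(
    "control", strongly_active=3, somewhat_active=1, dont_know=4, strongly_control=5)


def counts_strategy(min_guessers=0, max_n=60):
    def build(parts):
        return CollapsedCounts(*parts)

    return st.tuples(
        st.integers(0, max_n), st.integers(0, max_n), st.integers(0, max_n)
    ).filter(lambda t: sum(t) >= 1 and t[0] + t[1] >= min_guessers).map(build)


def table_strategy(max_count=20):
    return st.tuples(
        st.sampled_from(["active", "control"]),
        *(st.integers(0, max_count) for _ in range(5)),
    ).map(lambda t: ArmResponseTable(t[0], *t[1:]))


class TestCollapse:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (ACTIVE_TABLE, CollapsedCounts(6, 0, 5)),
            (CONTROL_TABLE, CollapsedCounts(5, 4, 4)),
            (ArmResponseTable("active", dont_know=7), CollapsedCounts(0, 0, 7)),
            (ArmResponseTable("control", dont_know=0), CollapsedCounts(0, 0, 0)),
        ],
    )
    def test_examples(self, table, expected):
        c = collapse_responses(table)
        assert c == expected
        assert c.n == table.n

    def test_correctness_follows_arm_direction(self):
        # the same counts are correct for one arm and incorrect for the other
        active = ArmResponseTable("active", somewhat_active=3, strongly_control=2)
        control = ArmResponseTable("control", somewhat_active=3, strongly_control=2)
        assert collapse_responses(active) == CollapsedCounts(3, 2, 0)
        assert collapse_responses(control) == CollapsedCounts(2, 3, 0)


class TestBangPoint:
    def test_active_arm_point(self):
        c = CollapsedCounts(6, 0, 5)
        assert bang_point(c) == pytest.approx(6 / 11)
        assert round_half_away(bang_point(c)) == 0.55

    def test_no_guessers_is_undefinable(self):
        assert math.isnan(bang_point(CollapsedCounts(0, 0, 24)))

    def test_complete_correct_perception(self):
        assert bang_point(CollapsedCounts(11, 0, 0)) == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty group"):
            bang_point(CollapsedCounts(0, 0, 0))

    @given(counts_strategy(min_guessers=1))
    def test_bounded_and_sign_flip_antisymmetric(self, c):
        swapped = CollapsedCounts(c.r_incorrect, c.r_correct, c.r_dontknow)
        assert -1 <= bang_point(c) <= 1
        assert bang_point(swapped) == pytest.approx(-bang_point(c))
        assert bang_variance(swapped) == pytest.approx(bang_variance(c))


class TestBangVariance:
    @pytest.mark.parametrize(
        "c,expected",
        [
            (CollapsedCounts(6, 0, 5), 0.02254),
            (CollapsedCounts(5, 4, 4), 0.05280),
            (CollapsedCounts(11, 0, 0), 0.0),
        ],
    )
    def test_examples(self, c, expected):
        assert bang_variance(c) == pytest.approx(expected, abs=5e-6)

    def test_no_guessers_propagates_nan(self):
        assert math.isnan(bang_variance(CollapsedCounts(0, 0, 10)))

    @given(counts_strategy(min_guessers=1))
    def test_non_negative(self, c):
        assert bang_variance(c) >= 0

    @given(st.integers(1, 40))
    def test_zero_variance_iff_unanimous_guessing(self, k):
        assert bang_variance(CollapsedCounts(k, 0, 0)) == pytest.approx(0, abs=1e-12)
        assert bang_variance(CollapsedCounts(0, k, 0)) == pytest.approx(0, abs=1e-12)
        if k >= 2:
            assert bang_variance(CollapsedCounts(k - 1, 1, 0)) > 0
        assert bang_variance(CollapsedCounts(k, 0, 1)) > 0


class TestWaldCI:
    def test_active_arm_interval(self):
        lo, hi = wald_ci(6 / 11, bang_variance(CollapsedCounts(6, 0, 5)))
        assert (round_half_away(lo), round_half_away(hi)) == (0.25, 0.84)

    def test_control_arm_interval(self):
        lo, hi = wald_ci(1 / 13, bang_variance(CollapsedCounts(5, 4, 4)))
        assert (round_half_away(lo), round_half_away(hi)) == (-0.37, 0.53)

    def test_zero_variance_degenerate(self):
        assert wald_ci(0.3, 0.0) == (0.3, 0.3)

    def test_nan_propagates(self):
        lo, hi = wald_ci(float("nan"), float("nan"))
        assert math.isnan(lo) and math.isnan(hi)

    def test_not_truncated_to_index_range(self):
        lo, hi = wald_ci(0.9, 0.1)
        assert hi > 1


class TestBangEstimate:
    def test_composition_active(self):
        e = bang_estimate(ACTIVE_TABLE)
        assert round_half_away(e.point) == 0.55
        assert (round_half_away(e.ci_lower), round_half_away(e.ci_upper)) == (0.25, 0.84)
        assert e.n == 11 and not e.undefined

    def test_composition_control(self):
        e = bang_estimate(CONTROL_TABLE)
        assert round_half_away(e.point) == 0.08
        assert (round_half_away(e.ci_lower), round_half_away(e.ci_upper)) == (-0.37, 0.53)

    def test_all_dont_know_undefined(self):
        e = bang_estimate(ArmResponseTable("active", dont_know=11))
        assert e.undefined and math.isnan(e.point)


class TestSummedBang:
    def test_rounded_summand_convention(self):
        s = summed_bang(bang_estimate(ACTIVE_TABLE), bang_estimate(CONTROL_TABLE))
        assert s.point == pytest.approx(0.63)
        assert (round_half_away(s.ci_lower), round_half_away(s.ci_upper)) == (0.09, 1.17)

    def test_exact_sum_mode(self):
        s = summed_bang(bang_estimate(ACTIVE_TABLE), bang_estimate(CONTROL_TABLE),
                        rounding_convention=False)
        assert s.point == pytest.approx(6 / 11 + 1 / 13)
        assert round_half_away(s.point, 4) == 0.6224

    def test_degenerate_zero_inputs(self):
        z = BlindingEstimate("bang_arm", 0.0, 0.0, 0.0, 0.0, n=5)
        s = summed_bang(z, z)
        assert (s.point, s.ci_lower, s.ci_upper) == (0.0, 0.0, 0.0)

    def test_undefined_propagates(self):
        undef = bang_estimate(ArmResponseTable("active", dont_know=4))
        s = summed_bang(undef, bang_estimate(CONTROL_TABLE))
        assert s.undefined and math.isnan(s.point)

    def test_variance_is_sum_of_arm_variances(self):
        a, c = bang_estimate(ACTIVE_TABLE), bang_estimate(CONTROL_TABLE)
        assert summed_bang(a, c).variance == pytest.approx(a.variance + c.variance)


def _swap_direction(table: ArmResponseTable) -> ArmResponseTable:
    """Mirror every directed guess to the opposite arm, same strength."""
    return ArmResponseTable(
        table.arm,
        strongly_active=table.strongly_control,
        somewhat_active=table.somewhat_control,
        dont_know=table.dont_know,
        somewhat_control=table.somewhat_active,
        strongly_control=table.strongly_active,
    )


class TestJames:
    def test_all_dont_know_is_one(self):
        a = ArmResponseTable("active", dont_know=11)
        c = ArmResponseTable("control", dont_know=13)
        assert james_point(a, c) == 1.0

    def test_all_strongly_correct_is_zero(self):
        a = ArmResponseTable("active", strongly_active=5)
        c = ArmResponseTable("control", strongly_control=7)
        assert james_point(a, c) == 0.0

    def test_study_fixture_value(self):
        assert james_point(ACTIVE_TABLE, CONTROL_TABLE) == pytest.approx(0.53125)

    def test_empty_pooled_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            james_point(ArmResponseTable("active"), ArmResponseTable("control"))

    @given(st.tuples(table_strategy(), table_strategy()).filter(
        lambda t: t[0].n + t[1].n >= 1))
    def test_bounded_and_swap_identity(self, tables):
        t0, t1 = tables
        active = ArmResponseTable("active", *(t0.count(c) for c in GuessCategory))
        control = ArmResponseTable("control", *(t1.count(c) for c in GuessCategory))
        bi = james_point(active, control)
        assert 0 <= bi <= 1
        p_dk = (active.dont_know + control.dont_know) / (active.n + control.n)
        bi_swapped = james_point(_swap_direction(active), _swap_direction(control))
        assert bi + bi_swapped == pytest.approx(1 + p_dk)


class TestJamesCI:
    def test_all_dont_know_degenerate_at_one(self):
        recs = [("active", GuessCategory.DONT_KNOW)] * 24
        assert james_ci(recs, seed=0) == (1.0, 1.0)

    def test_constant_strongly_correct_degenerate_at_zero(self):
        recs = [("active", GuessCategory.STRONGLY_ACTIVE)] * 10
        assert james_ci(recs, seed=0) == (0.0, 0.0)

    def test_fixture_bootstrap_interval(self):
        recs = [("active", g) for g in ACTIVE_TABLE.to_responses()]
        recs += [("control", g) for g in CONTROL_TABLE.to_responses()]
        lo, hi = james_ci(recs, n_resamples=10_000, seed=7)
        assert lo < 0.53125 < hi
        # same order of magnitude as a reported interval of roughly (0.35, 0.72)
        assert 0.25 <= lo <= 0.45
        assert 0.60 <= hi <= 0.85

    def test_reproducible_for_fixed_seed(self):
        recs = [("active", g) for g in ACTIVE_TABLE.to_responses()]
        assert james_ci(recs, seed=3) == james_ci(recs, seed=3)

    def test_few_resamples_warns(self):
        recs = [("active", GuessCategory.STRONGLY_ACTIVE),
                ("active", GuessCategory.DONT_KNOW)] * 3
        with pytest.warns(UserWarning, match="resamples"):
            james_ci(recs, n_resamples=50, seed=0)

    def test_estimate_contains_point(self):
        e = james_estimate(ACTIVE_TABLE, CONTROL_TABLE, seed=11)
        assert e.ci_lower <= e.point <= e.ci_upper
        assert e.index_type == "james" and e.n == 24


class TestClassify:
    @pytest.mark.parametrize(
        "index_type,point,ci_upper,expected",
        [
            ("bang_arm", 0.55, 0.84, "not_adequate"),
            ("bang_arm", 0.08, 0.53, "adequate"),
            ("bang_arm", 0.2, 0.5, "adequate"),  # closed boundary
            ("bang_arm", -0.21, 0.1, "not_adequate"),
            ("bang_summed", 0.63, 1.17, "not_adequate"),
            ("bang_summed", 0.3, 0.8, "adequate"),
            ("james", 0.4, 0.49, "not_adequate"),
            ("james", 0.4, 0.5, "adequate"),
        ],
    )
    def test_thresholds(self, index_type, point, ci_upper, expected):
        e = BlindingEstimate(index_type, point, 0.01, point - 1, ci_upper, n=10)
        assert classify_blinding(e) == expected

    def test_undefined_is_undetermined(self):
        nan = float("nan")
        e = BlindingEstimate("bang_arm", nan, nan, nan, nan, n=10, undefined=True)
        assert classify_blinding(e) == "undetermined"


class TestContainers:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ArmResponseTable("active", strongly_active=-1)
        with pytest.raises(ValueError):
            CollapsedCounts(-1, 0, 1)

    def test_bad_arm_rejected(self):
        with pytest.raises(ValueError, match="arm"):
            ArmResponseTable("placebo", dont_know=3)

    def test_table_round_trips_through_responses(self):
        back = ArmResponseTable.from_responses("active", ACTIVE_TABLE.to_responses())
        assert back == ACTIVE_TABLE

    def test_estimate_invariants_enforced(self):
        with pytest.raises(ValueError, match="bracket"):
            BlindingEstimate("bang_arm", 0.5, 0.1, 0.6, 0.9, n=5)
        with pytest.raises(ValueError, match="NaN"):
            BlindingEstimate("bang_arm", 0.5, 0.1, 0.4, 0.6, n=5, undefined=True)

    def test_respondent_scores_match_cell_values(self):
        recs = [("active", GuessCategory.STRONGLY_ACTIVE),
                ("active", GuessCategory.SOMEWHAT_ACTIVE),
                ("active", GuessCategory.DONT_KNOW),
                ("active", GuessCategory.SOMEWHAT_CONTROL),
                ("active", GuessCategory.STRONGLY_CONTROL)]
        assert respondent_scores(recs).tolist() == [0.0, 0.25, 1.0, 0.75, 1.0]
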