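import math

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from pttquant.errors import ConfigError, DataError, DegenerateRatioError
from pttquant.examples import (
    CONTROL_GENES,
    EXAMPLE_IR_TABLE,
    EXAMPLE_PRINTED_DIFFERENCES,
    TIMEPOINTS_H,
    example_induction_results,
)
from pttquant.ptt import (
    AssayDesign,
    Condition,
    InductionResult,
    cleavage_efficiency,
    induction_ratio,
    induction_ratio_star,
    ir_percent_difference,
    ptt_estimate,
    round_half_away,
    summarize_cleavage_effect,
)

from .conftest import make_measurement

concs = st.floats(min_value=0.1, max_value=1e5, allow_nan=False)


class TestAssayDesign:
    def test_valid_design_distances(self, design):
        assert design.p1_distance_on_5prime_fragment == 201
        assert design.p3_distance_on_full_length == 201
        assert design.p1_distance_on_full_length > design.p3_distance_on_full_length

    def test_p1_must_precede_ptt_site(self):
        with pytest.raises(ConfigError, match="P1"):
            AssayDesign("g", (20, 300), (270, 330), (340, 420),
                        ptt_site=280, cleavage_site=300, full_length=620)

    def test_p2_must_span_cleavage_site(self):
        with pytest.raises(ConfigError, match="P2"):
            AssayDesign("g", (20, 100), (310, 330), (340, 420),
                        ptt_site=280, cleavage_site=300, full_length=620)

    def test_site_ordering_enforced(self):
        with pytest.raises(ConfigError, match="ptt_site"):
            AssayDesign("g", (20, 100), (270, 330), (340, 420),
                        ptt_site=300, cleavage_site=280, full_length=620)

    def test_unequal_3prime_distances_rejected(self):
        # P3 at distance 501 vs P1 fragment distance 201
        with pytest.raises(ConfigError, match="3'-distance"):
            AssayDesign("g", (20, 100), (270, 330), (340, 420),
                        ptt_site=280, cleavage_site=300, full_length=920)


class TestPttEstimate:
    def test_no_termination(self):
        est = ptt_estimate(make_measurement(P1=100, P3=100))
        assert est.T == 0
        assert est.termination_fraction == 0
        assert math.isnan(est.fl_to_t_ratio)

    def test_complete_termination(self):
        est = ptt_estimate(make_measurement(P1=100, P3=0))
        assert est.T == 100
        assert est.termination_fraction == 1

    def test_arithmetic_example(self):
        est = ptt_estimate(make_measurement(P1=100, P3=25))
        assert est.T == 75
        assert est.FL == 25
        assert est.termination_fraction == pytest.approx(0.75)
        assert est.fl_to_t_ratio == pytest.approx(1 / 3)

    def test_zero_p1_rejected(self):
        with pytest.raises(DegenerateRatioError, match="P1"):
            ptt_estimate(make_measurement(P1=0, P3=0))

    def test_negative_T_flagged_not_clamped(self):
        est = ptt_estimate(make_measurement(P1=50, P3=80))
        assert est.negative_T_flag
        assert est.T == -30
        assert est.termination_fraction < 0

    @given(p1=concs, p3=concs)
    def test_conservation_fl_plus_t_equals_p1(self, p1, p3):
        est = ptt_estimate(make_measurement(P1=p1, P3=p3))
        # exact up to the rounding of the single subtraction that formed T
        assert est.FL + est.T == pytest.approx(p1, abs=1e-9 * max(p1, p3))


class TestCleavageEfficiency:
    def test_complete_cleavage(self):
        assert cleavage_efficiency(0, 500) == (1.0, False)

    def test_no_cleavage(self):
        assert cleavage_efficiency(500, 500) == (0.0, False)

    def test_97_percent(self):
        eff, flag = cleavage_efficiency(15, 500)
        assert eff == pytest.approx(0.97)
        assert not flag

    def test_out_of_range_clamped_and_flagged(self):
        eff, flag = cleavage_efficiency(600, 500)
        assert eff == 0.0
        assert flag

    def test_zero_denominator_rejected(self):
        with pytest.raises(DegenerateRatioError):
            cleavage_efficiency(10, 0)


def estimate_pair(p1_minus, p3_minus, p1_plus, p3_plus):
    minus = ptt_estimate(
        make_measurement(P1=p1_minus, P3=p3_minus, condition=Condition.MET_MINUS)
    )
    plus = ptt_estimate(
        make_measurement(P1=p1_plus, P3=p3_plus, condition=Condition.MET_PLUS)
    )
    return minus, plus


class TestInductionRatios:
    def test_identical_conditions_give_unity(self):
        minus, plus = estimate_pair(100, 40, 100, 40)
        assert induction_ratio(minus, plus) == pytest.approx(1.0)
        assert induction_ratio_star(minus, plus) == pytest.approx(1.0)

    def test_ir_worked_example(self):
        minus, plus = estimate_pair(100, 80, 100, 20)
        assert induction_ratio(minus, plus) == pytest.approx(16.0)

    def test_ir_star_worked_example(self):
        minus, plus = estimate_pair(100, 80, 100, 20)
        assert induction_ratio_star(minus, plus) == pytest.approx(4.0)

    def test_zero_terminated_rejected_for_ir(self):
        minus, plus = estimate_pair(100, 100, 100, 20)
        with pytest.raises(DegenerateRatioError, match="T = 0"):
            induction_ratio(minus, plus)

    def test_negative_T_refused(self):
        minus = ptt_estimate(make_measurement(P1=50, P3=80, condition=Condition.MET_MINUS))
        plus = ptt_estimate(make_measurement(P1=100, P3=20, condition=Condition.MET_PLUS))
        with pytest.raises(DegenerateRatioError, match="negative T"):
            induction_ratio(minus, plus)
        with pytest.raises(DegenerateRatioError):
            induction_ratio_star(minus, plus)

    def test_ir_star_zero_fl_minus_warns(self):
        minus, plus = estimate_pair(100, 0, 100, 20)
        with pytest.warns(UserWarning, match="IR\\* = 0"):
            assert induction_ratio_star(minus, plus) == 0.0

    def test_ir_star_zero_fl_plus_rejected(self):
        minus, plus = estimate_pair(100, 80, 100, 0)
        with pytest.raises(DegenerateRatioError):
            induction_ratio_star(minus, plus)

    @given(
        p1m=concs, fm=st.floats(0.05, 0.95), p1p=concs, fp=st.floats(0.05, 0.95),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    def test_scale_invariance(self, p1m, fm, p1p, fp, scale):
        minus, plus = estimate_pair(p1m, p1m * (1 - fm), p1p, p1p * (1 - fp))
        minus_s, plus_s = estimate_pair(
            p1m * scale, p1m * (1 - fm) * scale, p1p, p1p * (1 - fp)
        )
        assert induction_ratio(minus_s, plus_s) == pytest.approx(
            induction_ratio(minus, plus), rel=1e-9
        )
        assert induction_ratio_star(minus_s, plus_s) == pytest.approx(
            induction_ratio_star(minus, plus), rel=1e-9
        )

    @given(fm=st.floats(0.01, 0.99), fp=st.floats(0.01, 0.99))
    def test_ir_dominates_ir_star_when_termination_higher_in_plus(self, fm, fp):
        assume(fp >= fm)
        minus, plus = estimate_pair(100, 100 * (1 - fm), 100, 100 * (1 - fp))
        ir = induction_ratio(minus, plus)
        ir_star = induction_ratio_star(minus, plus)
        if math.isclose(fm, fp):
            assert ir == pytest.approx(ir_star)
        else:
            assert ir > ir_star


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.5, 1), (-0.5, -1), (2.5, 3), (-2.5, -3), (2.4, 2), (-2.4, -2), (0.0, 0)],
    )
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected


class TestIrPercentDifference:
    def test_published_metic_2h_cell(self):
        assert ir_percent_difference(17.38, 25.91, rounded=True) == 49

    def test_published_mete_3h_cell(self):
        assert ir_percent_difference(18.79, 30.02, rounded=True) == 60

    def test_identity(self):
        assert ir_percent_difference(3.3, 3.3) == 0.0

    def test_raw_value(self):
        assert ir_percent_difference(10, 15) == pytest.approx(50.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DegenerateRatioError):
            ir_percent_difference(0, 10)


def ir_result(gene, t, ir, cleaved):
    return InductionResult(gene=gene, timepoint_h=t, IR=ir,
                           IR_star=math.nan, cleaved=cleaved)


class TestSummarizeCleavageEffect:
    def test_single_pair(self):
        res = [ir_result("g", 0, 10, False), ir_result("g", 0, 12, True)]
        summary = summarize_cleavage_effect(res)
        assert summary.mean_percent == pytest.approx(20.0)
        assert summary.max_percent == pytest.approx(20.0)

    def test_symmetric_pairs(self):
        res = [
            ir_result("a", 0, 10, False), ir_result("a", 0, 11, True),
            ir_result("b", 0, 10, False), ir_result("b", 0, 9, True),
        ]
        summary = summarize_cleavage_effect(res)
        assert summary.mean_percent == pytest.approx(0.0)
        assert summary.max_percent == pytest.approx(10.0)

    def test_orphans_listed(self):
        res = [ir_result("g", 0, 10, False), ir_result("h", 0, 12, True),
               ir_result("h", 0, 10, False)]
        with pytest.raises(DataError, match="g @ 0"):
            summarize_cleavage_effect(res)

    def test_duplicate_rejected(self):
        res = [ir_result("g", 0, 10, False), ir_result("g", 0, 10, False)]
        with pytest.raises(DataError, match="duplicate"):
            summarize_cleavage_effect(res)

    def test_control_exclusion_keeps_rows(self):
        res = [
            ir_result("ctrl", 0, 10, False), ir_result("ctrl", 0, 20, True),
            ir_result("g", 0, 10, False), ir_result("g", 0, 12, True),
        ]
        summary = summarize_cleavage_effect(res, control_genes=["ctrl"])
        assert summary.mean_percent == pytest.approx(20.0)
        assert len(summary.table) == 2
        assert not summary.table.set_index("gene").loc["ctrl", "included"]


class TestExampleTableRegression:
    """The bundled 5-gene x 4-timepoint example against its printed summary."""

    def setup_method(self):
        self.summary = summarize_cleavage_effect(
            example_induction_results(), control_genes=CONTROL_GENES
        )

    def test_mean_effect_is_23_percent(self):
        assert self.summary.mean_percent_rounded == 23

    def test_max_effect_is_60_percent(self):
        assert self.summary.max_percent_rounded == 60

    def test_exact_cells(self):
        table = self.summary.table.set_index(["gene", "timepoint_h"])
        assert table.loc[("metIC", 2.0), "percent_difference_rounded"] == 49
        assert table.loc[("metE", 1.0), "percent_difference_rounded"] == 33
        assert table.loc[("metE", 2.0), "percent_difference_rounded"] == 20
        assert table.loc[("metE", 3.0), "percent_difference_rounded"] == 60

    def test_all_20_cells_within_2_points_of_printed(self):
        table = self.summary.table.set_index(["gene", "timepoint_h"])
        for gene, printed in EXAMPLE_PRINTED_DIFFERENCES.items():
            for t, expected in zip(TIMEPOINTS_H, printed):
                got = table.loc[(gene, t), "percent_difference_rounded"]
                assert abs(got - expected) <= 2, (gene, t, got, expected)

    def test_including_control_changes_mean(self):
        with_control = summarize_cleavage_effect(example_induction_results())
        assert with_control.mean_percent_rounded != 23
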