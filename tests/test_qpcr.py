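"""Ct collapsing, ChIP fold enrichment, standard curves, relative expression."""

import math

import numpy as np
import pandas as pd
import pytest

from regvar.qpcr import (
    CtTable,
    compare_conditions,
    compare_enrichment_one_sided,
    enrichment_by_group,
    fit_standard_curve,
    fold_enrichment,
    mean_ct,
    relative_expression,
)
from regvar.simulate import (
    ChipPlan,
    ExpressionPlan,
    simulate_ct_table,
    simulate_dilution_series,
    simulate_expression_table,
)


def ct_rows(sample, antibody, target, cts, group="CT"):
    return [
        {
            "sample_id": sample,
            "group": group,
            "antibody": antibody,
            "target": target,
            "replicate": i + 1,
            "ct": ct,
        }
        for i, ct in enumerate(cts)
    ]


class TestMeanCt:
    def test_mean_sd_and_flag(self):
        table = CtTable(pd.DataFrame(
            ct_rows("s1", "IgG", "site", [30, 30, 30]) + ct_rows("s1", "FOXA1", "site", [29, 30, 31])
        ))
        out = mean_ct(table).set_index("antibody")
        assert out.at["IgG", "mean_ct"] == 30
        assert out.at["IgG", "sd_ct"] == 0
        assert not out.at["IgG", "flag_high_sd"]
        assert out.at["FOXA1", "mean_ct"] == 30
        assert out.at["FOXA1", "sd_ct"] == pytest.approx(1.0)
        assert out.at["FOXA1", "flag_high_sd"]

    def test_round_trip_against_generator_means(self, rng):
        plan = ChipPlan(ct_noise_sd=0.05, sample_base_sd=0.0)
        table = simulate_ct_table(plan, rng)
        out = mean_ct(table)
        igg = out.loc[(out["antibody"] == "IgG"), "mean_ct"]
        np.testing.assert_allclose(igg, plan.base_ct, atol=0.2)

    def test_ct_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            CtTable(pd.DataFrame(ct_rows("s1", "IgG", "site", [30, 50, 30])))


class TestFoldEnrichment:
    def test_equal_ct_gives_one(self):
        table = CtTable(pd.DataFrame(
            ct_rows("s1", "IgG", "site", [30, 30, 30]) + ct_rows("s1", "FOXA1", "site", [30, 30, 30])
        ))
        assert fold_enrichment(table, "FOXA1", "s1", "site") == pytest.approx(1.0)

    def test_delta_ct_three_gives_eight(self):
        table = CtTable(pd.DataFrame(
            ct_rows("s1", "IgG", "site", [30, 30, 30]) + ct_rows("s1", "FOXA1", "site", [27, 27, 27])
        ))
        assert fold_enrichment(table, "FOXA1", "s1", "site") == pytest.approx(8.0)

    def test_missing_igg_is_error(self):
        table = CtTable(pd.DataFrame(ct_rows("s1", "FOXA1", "site", [27, 27, 27])))
        with pytest.raises(KeyError, match="IgG"):
            fold_enrichment(table, "FOXA1", "s1", "site")

    def test_percent_input_route_matches_direct_ratio(self):
        rows = (
            ct_rows("s1", "IgG", "site", [30.0, 30.2, 29.8])
            + ct_rows("s1", "FOXA1", "site", [27.0, 27.1, 26.9])
            + ct_rows("s1", "input", "site", [24.0, 24.0, 24.0])
        )
        table = CtTable(pd.DataFrame(rows))
        direct = fold_enrichment(table, "FOXA1", "s1", "site")
        via_input = fold_enrichment(table, "FOXA1", "s1", "site", input_label="input")
        assert via_input == pytest.approx(direct)

    def test_constant_shift_of_block_leaves_fold_unchanged(self):
        rows = ct_rows("s1", "IgG", "site", [30, 30, 30]) + ct_rows("s1", "FOXA1", "site", [28, 28, 28])
        base = fold_enrichment(CtTable(pd.DataFrame(rows)), "FOXA1", "s1", "site")
        shifted = [dict(r, ct=r["ct"] + 2.5) for r in rows]
        assert fold_enrichment(CtTable(pd.DataFrame(shifted)), "FOXA1", "s1", "site") == pytest.approx(base)

    def test_monotone_in_antibody_and_igg_ct(self):
        def fe(ct_ab, ct_igg):
            rows = ct_rows("s1", "IgG", "site", [ct_igg] * 3) + ct_rows("s1", "FOXA1", "site", [ct_ab] * 3)
            return fold_enrichment(CtTable(pd.DataFrame(rows)), "FOXA1", "s1", "site")

        assert fe(27, 30) > fe(28, 30) > fe(29, 30)
        assert fe(28, 31) > fe(28, 30) > fe(28, 29)

    def test_generator_truth_recovered_by_group(self, rng):
        plan = ChipPlan(ct_noise_sd=0.0, sample_base_sd=0.5)
        table = simulate_ct_table(plan, rng)
        groups = enrichment_by_group(table, "FOXA1", plan.site_region)
        np.testing.assert_allclose(groups["CT"], 7.2, rtol=1e-9)
        np.testing.assert_allclose(groups["CC"], 1.0, rtol=1e-9)
        control = enrichment_by_group(table, "FOXA1", plan.control_region)
        np.testing.assert_allclose(control["CT"] + control["CC"], 1.0, rtol=1e-9)


class TestOneSidedComparison:
    def test_identical_groups_sit_on_null_boundary(self):
        _, p = compare_enrichment_one_sided({"CT": [2.0, 2.0, 2.0], "CC": [2.0, 2.0]}, "CT>CC")
        assert p == pytest.approx(0.5)

    def test_sidedness_sanity(self):
        groups = {"CT": [8.0, 7.5, 7.9], "CC": [1.0, 1.1]}
        _, p_right = compare_enrichment_one_sided(groups, "CT>CC")
        _, p_wrong = compare_enrichment_one_sided(groups, "CC>CT")
        assert p_right < 0.05
        assert p_wrong > 0.95

    def test_direction_must_be_declared(self):
        with pytest.raises(ValueError, match="direction"):
            compare_enrichment_one_sided({"CT": [1, 2], "CC": [1, 2]}, "")

    def test_group_too_small_is_error(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            compare_enrichment_one_sided({"CT": [1.0], "CC": [1.0, 2.0]}, "CT>CC")


class TestStandardCurve:
    def test_perfect_efficiency_two_closed_form(self):
        cts = [20 + i * math.log2(3) for i in range(5)]
        curve = fit_standard_curve(cts, dilution_factor=3)
        assert curve.slope == pytest.approx(-math.log2(10), abs=1e-9)
        assert curve.efficiency == pytest.approx(2.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_doubled_ct_steps_give_sqrt2_efficiency_with_warning(self):
        cts = [20 + 2 * i * math.log2(3) for i in range(5)]
        with pytest.warns(UserWarning, match="efficiency"):
            curve = fit_standard_curve(cts, dilution_factor=3)
        assert curve.efficiency == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_noisy_series_recovers_efficiency(self, rng):
        plan = ExpressionPlan(ct_noise_sd=0.15)
        cts = simulate_dilution_series(plan, intercept=25.0, rng=rng)
        curve = fit_standard_curve(cts, dilution_factor=plan.dilution_factor)
        assert curve.r_squared > 0.99
        assert abs(curve.efficiency - plan.efficiency) < 0.05

    def test_too_few_points_and_positive_slope_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_standard_curve([30, 28])
        with pytest.raises(ValueError, match="slope"):
            fit_standard_curve([20, 22, 24][::-1])

    def test_round_trip_recovers_slope_exactly(self):
        slope_true = -1.0 / math.log10(1.9)
        cts = [24.0 + slope_true * (-i * math.log10(3)) for i in range(6)]
        curve = fit_standard_curve(cts, dilution_factor=3)
        assert curve.slope == pytest.approx(slope_true, abs=1e-9)


class TestRelativeExpression:
    def curves(self):
        cts_gene = [28 + i * math.log2(3) for i in range(5)]
        cts_hk = [22 + i * math.log2(3) for i in range(5)]
        return {
            "CAMK1D": fit_standard_curve(cts_gene),
            "B2M": fit_standard_curve(cts_hk),
        }

    def test_identical_ct_on_identical_curves_gives_one(self):
        curves = self.curves()
        curves["B2M"] = curves["CAMK1D"]
        rows = ct_rows("s1", "cDNA", "CAMK1D", [28.5] * 3, group="low") + ct_rows(
            "s1", "cDNA", "B2M", [28.5] * 3, group="low"
        )
        out = relative_expression(CtTable(pd.DataFrame(rows)), "CAMK1D", "B2M", curves)
        assert out["normalized_quantity"].tolist() == pytest.approx([1.0])

    def test_one_cycle_lower_gene_ct_doubles_ratio(self):
        curves = self.curves()
        base_rows = ct_rows("s1", "cDNA", "CAMK1D", [29.0] * 3, group="low") + ct_rows(
            "s1", "cDNA", "B2M", [23.0] * 3, group="low"
        )
        shifted_rows = ct_rows("s2", "cDNA", "CAMK1D", [28.0] * 3, group="low") + ct_rows(
            "s2", "cDNA", "B2M", [23.0] * 3, group="low"
        )
        table = CtTable(pd.DataFrame(base_rows + shifted_rows))
        out = relative_expression(table, "CAMK1D", "B2M", curves).set_index("sample_id")
        ratio = out.at["s2", "normalized_quantity"] / out.at["s1", "normalized_quantity"]
        assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_generator_induction_recovered(self, rng):
        plan = ExpressionPlan(induction=1.8, ct_noise_sd=0.1)
        table = simulate_expression_table(plan, rng)
        curves = {
            plan.gene: fit_standard_curve(
                simulate_dilution_series(plan, plan.gene_intercept, rng, noise_sd=0.0)
            ),
            plan.housekeeping: fit_standard_curve(
                simulate_dilution_series(plan, plan.housekeeping_intercept, rng, noise_sd=0.0)
            ),
        }
        expr = relative_expression(table, plan.gene, plan.housekeeping, curves)
        fold, p = compare_conditions(expr, plan.low_label, plan.high_label)
        assert abs(fold - plan.induction) / plan.induction < 0.10
        assert p < 0.05


class TestCompareConditions:
    def frame(self, low, high):
        rows = [
            {"sample_id": f"l{i}", "group": "low", "normalized_quantity": v}
            for i, v in enumerate(low)
        ] + [
            {"sample_id": f"h{i}", "group": "high", "normalized_quantity": v}
            for i, v in enumerate(high)
        ]
        return pd.DataFrame(rows)

    def test_identical_groups(self):
        fold, p = compare_conditions(self.frame([1.0, 1.0], [1.0, 1.0]), "low", "high")
        assert (fold, p) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_deterministic_twofold_induction(self, rng):
        low = 1.0 + rng.normal(0, 1e-9, size=4)
        fold, _ = compare_conditions(self.frame(low, 2 * low), "low", "high")
        assert fold == pytest.approx(2.0, rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_conditions(self.frame([1.0], [1.0, 1.0]), "low", "high")
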