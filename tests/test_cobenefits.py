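"""Accounting layer: percent conversion, tons, bounding formula, money."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coben.cobenefits import (
    bound_lcp,
    build_report,
    cumulative_reductions,
    monetize,
    share_of_economy_wide,
    summarize_effects,
    to_percent,
)
from coben.gscm import estimate
from coben.inference import parametric_bootstrap
from coben.panel import CostConfig, LcpSeries
from coben.simulate import economy_wide_series, generate, emissions_like_preset, synthetic_lcp_series


class TestPercentConversion:
    def test_exponentiated_convention(self):
        assert to_percent(0.0) == 0.0
        assert to_percent(np.log(0.61)) == pytest.approx(-39.0)

    def test_log_points_convention(self):
        assert to_percent(-0.20, "log_points") == pytest.approx(-20.0)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            to_percent(0.1, "nope")


@pytest.fixture(scope="module")
def run(small_log_panel):
    fit, res = estimate(small_log_panel, r=2)
    bands = parametric_bootstrap(small_log_panel, fit, res, n_reps=60, seed=8)
    return small_log_panel, fit, res, bands


class TestSummarizeEffects:
    def test_mean_is_unweighted_over_units_and_periods(self, run):
        _, _, res, bands = run
        s = summarize_effects(res, bands)
        assert s.mean_log == pytest.approx(float(res.tau_hat.to_numpy().mean()))
        assert s.mean_pct == pytest.approx(100 * (np.exp(s.mean_log) - 1))
        assert s.mean_pct_log_points == pytest.approx(100 * s.mean_log)
        assert s.ci_pct[0] <= s.mean_pct <= s.ci_pct[1]

    def test_mismatched_runs_rejected(self, run):
        panel, fit, res, bands = run
        _, other = estimate(panel, r=1)
        with pytest.raises(ValueError, match="different"):
            summarize_effects(other, bands)


class TestPhysicalReductions:
    def test_zero_when_counterfactual_equals_observed(self, run):
        _, _, res, _ = run
        zero = res.observed_level - res.observed_level
        red = cumulative_reductions(
            type(res)(**{**res.__dict__, "y0_level": res.observed_level})
        )
        assert red["reduction_tons"].abs().max() == 0.0

    def test_single_cell_arithmetic(self, run):
        """Counterfactual 150 vs observed 100 in one year = 50 tons avoided."""
        _, _, res, _ = run
        y0 = res.observed_level.copy()
        year = res.tau_hat.index[0]
        unit = y0.columns[0]
        y0.loc[year] = res.observed_level.loc[year]
        y0.loc[year, unit] = res.observed_level.loc[year, unit] + 50.0
        res2 = type(res)(**{**res.__dict__, "y0_level": y0})
        red = cumulative_reductions(res2, window=(year, year))
        assert red["reduction_tons"].sum() == pytest.approx(50.0)

    def test_total_is_sum_of_per_year_terms(self, run):
        _, _, res, _ = run
        red = cumulative_reductions(res)
        total = red["reduction_tons"].sum()
        per_year = (res.y0_level.loc[res.tau_hat.index]
                    - res.observed_level.loc[res.tau_hat.index]).sum(axis=1)
        assert total == pytest.approx(per_year.sum(), rel=1e-12)

    def test_truth_implied_reduction_recovered(self):
        """Estimated cumulative tons match the generator's ground truth."""
        sp = generate(emissions_like_preset(seed=31, tau_profile=-0.40))
        panel = sp.panel
        from coben.panel import log_transform

        lg = log_transform(panel)
        _, res = estimate(lg, r=2)
        est = cumulative_reductions(res)["reduction_tons"].sum()
        treated = panel.treated_units
        y1 = sp.panel.wide_outcome(treated).loc[2005:]
        y0 = np.exp(sp.truth["y0_log"][treated].loc[2005:])
        truth = float((y0 - y1).to_numpy().sum())
        assert est == pytest.approx(truth, rel=0.10)


class TestShare:
    def test_simple_ratio(self):
        eco = pd.Series({2005: 60.0, 2006: 40.0})
        assert share_of_economy_wide(10.0, eco, (2005, 2006)) == pytest.approx(10.0)
        assert share_of_economy_wide(0.0, eco, (2005, 2006)) == 0.0

    def test_zero_denominator_rejected(self):
        eco = pd.Series({2005: 0.0})
        with pytest.raises(ZeroDivisionError):
            share_of_economy_wide(1.0, eco, (2005, 2005))


class TestBoundingFormula:
    def test_printed_formula_values(self):
        att = pd.Series({2008: 0.0, 2009: -0.5, 2010: -0.25})
        lcp = pd.Series({2008: 100.0, 2009: 100.0, 2010: 0.0})
        out = bound_lcp(att, lcp).set_index("year")["lcp_reduction_tons"]
        assert out[2008] == 0.0
        assert out[2009] == pytest.approx(100 / 1.5 - 100)  # -33.33 tons
        assert out[2010] == 0.0

    def test_starts_at_configured_year(self):
        att = pd.Series({2005: -0.5, 2008: -0.5})
        lcp = pd.Series({2005: 100.0, 2008: 100.0})
        out = bound_lcp(att, lcp, start_year=2008)
        assert list(out["year"]) == [2008]

    def test_att_at_or_above_one_rejected(self):
        att = pd.Series({2008: 1.0})
        lcp = pd.Series({2008: 100.0})
        with pytest.raises(ValueError, match="undefined"):
            bound_lcp(att, lcp)


class TestMonetize:
    def test_single_ton_and_zero(self):
        costs = CostConfig({"SO2": 15000.0})
        row = monetize({"SO2": 1.0}, {}, costs).iloc[0]
        assert row["joint_benefit"] == 15000.0
        row = monetize({"SO2": 0.0}, {}, costs).iloc[0]
        assert row["joint_benefit"] == 0.0

    def test_bounded_is_joint_minus_lcp(self):
        costs = CostConfig({"SO2": 1.0})
        row = monetize({"SO2": 100.0}, {"SO2": -30.0}, costs).iloc[0]
        assert row["joint_benefit"] == 100.0
        assert row["lcp_attributed_benefit"] == 30.0
        assert row["bounded_benefit"] == 70.0

    def test_missing_cost_factor_rejected(self):
        with pytest.raises(KeyError, match="NOx"):
            monetize({"NOx": 1.0}, {}, CostConfig({"SO2": 1.0}))

    @settings(max_examples=50, deadline=None)
    @given(
        tons=st.floats(0, 1e7, allow_nan=False),
        lcp=st.floats(-1e6, 0, allow_nan=False),
        cost=st.floats(1e-3, 1e5, allow_nan=False, exclude_min=True),
    )
    def test_linearity_in_tons(self, tons, lcp, cost):
        costs = CostConfig({"SO2": cost})
        one = monetize({"SO2": tons}, {"SO2": lcp}, costs).iloc[0]
        two = monetize({"SO2": 2 * tons}, {"SO2": 2 * lcp}, costs).iloc[0]
        assert two["joint_benefit"] == pytest.approx(2 * one["joint_benefit"])
        assert two["bounded_benefit"] == pytest.approx(2 * one["bounded_benefit"])
        # bounded never exceeds joint when LCP tons change is non-positive
        assert one["bounded_benefit"] <= one["joint_benefit"] + 1e-9


class TestBuildReport:
    def test_report_identities(self, run, small_synthetic):
        panel, fit, res, bands = run
        costs = CostConfig({"SO2": 15000.0})
        lcp = LcpSeries(synthetic_lcp_series(small_synthetic))
        eco = economy_wide_series(small_synthetic)
        rep = build_report("SO2", res, bands, costs, lcp=lcp, economy_series=eco)
        assert rep.bounded_benefit == pytest.approx(
            rep.joint_benefit - rep.lcp_attributed_benefit, rel=1e-12
        )
        assert rep.cumulative_reduction_tons == pytest.approx(
            rep.reductions_by_year["reduction_tons"].sum(), rel=1e-12
        )
        assert rep.joint_benefit == pytest.approx(
            rep.cumulative_reduction_tons * 15000.0, rel=1e-12
        )
        assert 0 < rep.share_of_economy_wide_pct < 100
        payload = rep.to_dict()
        assert payload["pollutant"] == "SO2"
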