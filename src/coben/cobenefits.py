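"""From estimated effects to tons avoided, bounded attribution and money.

Chains four accounting steps downstream of the estimator:

* summarize the mean effect across treated units and post-adoption years,
  in percent, with its bootstrap interval;
* cumulate physical reductions, counterfactual minus observed tons, by year
  and in total, and express the total as a share of an economy-wide series;
* bound the contribution of jointly regulated large combustion plants (LCPs)
  by scaling their observed emissions with the estimated proportional effect:
  ``Reductions_t = E_t / (1 - ATT_t) - E_t``, where a negative value denotes
  emissions avoided by the plants themselves;
* monetize tons with configured per-ton damage costs, reporting the joint
  benefit and the bounded benefit (joint minus the LCP-attributed part).

Effects estimated on log outcomes are reported under two conventions: log
points x100, and the exponentiated percent change 100*(exp(tau)-1); headline
numbers use the exponentiated convention by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .gscm import CounterfactualResult
from .inference import BootstrapResult
from .panel import CostConfig, LcpSeries

__all__ = [
    "EffectSummary",
    "CobenefitReport",
    "summarize_effects",
    "cumulative_reductions",
    "share_of_economy_wide",
    "bound_lcp",
    "monetize",
    "build_report",
    "to_percent",
]


def to_percent(tau_log, convention: str = "exponentiated"):
    """Convert a log-scale effect to percent under the stated convention."""
    if convention == "exponentiated":
        return 100.0 * (np.exp(tau_log) - 1.0)
    if convention == "log_points":
        return 100.0 * np.asarray(tau_log) if np.ndim(tau_log) else 100.0 * tau_log
    raise ValueError(f"unknown percent convention {convention!r}")


@dataclass(frozen=True)
class EffectSummary:
    """Mean effect across treated units and post years, with its interval."""

    mean_log: float
    mean_pct: float
    ci_pct: tuple[float, float]
    mean_pct_log_points: float
    level: float
    convention: str


def summarize_effects(
    result: CounterfactualResult,
    bands: BootstrapResult,
    convention: str = "exponentiated",
) -> EffectSummary:
    """Average the unit-period effects and convert to percent with CI.

    The point estimate is the unweighted mean of the log-scale effects over
    treated units and post-adoption years; the interval applies the same
    functional to the bootstrap draws. Result and bands must originate from
    the same estimation run.
    """
    if result.run_id != bands.run_id:
        raise ValueError("effects and bands come from different estimation runs")
    mean_log = result.mean_att
    lo, hi = bands.mean_att_ci
    return EffectSummary(
        mean_log=mean_log,
        mean_pct=float(to_percent(mean_log, convention)),
        ci_pct=(float(to_percent(lo, convention)), float(to_percent(hi, convention))),
        mean_pct_log_points=100.0 * mean_log,
        level=bands.level,
        convention=convention,
    )


def cumulative_reductions(
    result: CounterfactualResult,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Physical reductions by post year: sum over treated units of
    counterfactual minus observed tons.

    Positive values mean the policy avoided emissions. The ``total`` is the
    exact sum of the per-year terms over the window (default: all
    post-adoption years).
    """
    years = result.tau_hat.index.to_numpy()
    if window is not None:
        years = years[(years >= window[0]) & (years <= window[1])]
    diff = result.y0_level.loc[years] - result.observed_level.loc[years]
    out = pd.DataFrame({"year": years, "reduction_tons": diff.sum(axis=1).to_numpy()})
    return out


def share_of_economy_wide(
    total_tons: float,
    economy_series: pd.Series,
    window: tuple[int, int],
) -> float:
    """Cumulative reduction as a percent of economy-wide emissions over the window."""
    w = economy_series[
        (economy_series.index >= window[0]) & (economy_series.index <= window[1])
    ]
    denom = float(w.sum())
    if denom == 0:
        raise ZeroDivisionError("economy-wide emissions sum to zero over the window")
    return 100.0 * total_tons / denom


def bound_lcp(
    att_fraction: pd.Series,
    lcp: pd.Series,
    start_year: int = 2008,
) -> pd.DataFrame:
    """Per-year emissions change attributed to jointly regulated LCPs.

    Applies ``Reductions_t = E_t / (1 - ATT_t) - E_t`` from ``start_year`` on,
    where ``ATT_t`` is the proportional (level-scale) effect and ``E_t`` the
    plants' observed emissions.  With a negative effect the result is
    negative: the tons the plants themselves avoided.  Undefined at
    ``ATT_t >= 1``.

    Parameters
    ----------
    att_fraction:
        Proportional effect per year (e.g. ``exp(ATT_log) - 1``), indexed by
        year.
    lcp:
        Observed LCP emissions E_t in tons/year, indexed by year.
    start_year:
        First year the standards overlap is gauged (default 2008).
    """
    years = [y for y in lcp.index if y >= start_year and y in att_fraction.index]
    att = att_fraction.loc[years]
    if (att >= 1).any():
        bad = att[att >= 1].index.tolist()
        raise ValueError(f"bounding formula undefined at ATT >= 1 in years {bad}")
    E = lcp.loc[years]
    red = E / (1.0 - att) - E
    return pd.DataFrame({"year": years, "lcp_reduction_tons": red.to_numpy()})


def monetize(
    tons_by_pollutant: Mapping[str, float],
    lcp_tons_by_pollutant: Mapping[str, float],
    costs: CostConfig,
) -> pd.DataFrame:
    """Monetized benefits per pollutant: joint, LCP-attributed and bounded.

    Benefit is tons x configured cost-per-ton; bounded = joint minus the
    LCP-attributed part. Linear in tons by construction. Raises ``KeyError``
    for a pollutant with no configured cost factor.
    """
    rows = []
    for pol, tons in tons_by_pollutant.items():
        c = costs.cost_per_ton(pol)
        lcp_tons = float(lcp_tons_by_pollutant.get(pol, 0.0))
        joint = tons * c
        lcp_benefit = -lcp_tons * c  # negative LCP change = avoided tons = positive benefit
        rows.append(
            {
                "pollutant": pol,
                "cumulative_reduction_tons": tons,
                "lcp_attributed_tons": -lcp_tons,
                "cost_per_ton": c,
                "joint_benefit": joint,
                "lcp_attributed_benefit": lcp_benefit,
                "bounded_benefit": joint - lcp_benefit,
                "currency": costs.currency,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CobenefitReport:
    """Full downstream report for one pollutant run."""

    pollutant: str
    effects: EffectSummary
    reductions_by_year: pd.DataFrame
    cumulative_reduction_tons: float
    share_of_economy_wide_pct: float | None
    lcp_by_year: pd.DataFrame | None
    lcp_attributed_tons: float
    joint_benefit: float
    lcp_attributed_benefit: float
    bounded_benefit: float
    currency: str
    convention: str
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "pollutant": self.pollutant,
            "mean_effect_pct": self.effects.mean_pct,
            "mean_effect_ci_pct": list(self.effects.ci_pct),
            "mean_effect_log_points": self.effects.mean_pct_log_points,
            "convention": self.convention,
            "cumulative_reduction_tons": self.cumulative_reduction_tons,
            "share_of_economy_wide_pct": self.share_of_economy_wide_pct,
            "lcp_attributed_tons": self.lcp_attributed_tons,
            "joint_benefit": self.joint_benefit,
            "lcp_attributed_benefit": self.lcp_attributed_benefit,
            "bounded_benefit": self.bounded_benefit,
            "currency": self.currency,
            "notes": list(self.notes),
        }


def build_report(
    pollutant: str,
    result: CounterfactualResult,
    bands: BootstrapResult,
    costs: CostConfig,
    lcp: LcpSeries | None = None,
    economy_series: pd.Series | None = None,
    window: tuple[int, int] | None = None,
    lcp_start_year: int = 2008,
    convention: str = "exponentiated",
) -> CobenefitReport:
    """Assemble the per-pollutant co-benefit report from estimation outputs."""
    effects = summarize_effects(result, bands, convention)
    if window is None:
        post = result.tau_hat.index
        window = (int(post.min()), int(post.max()))
    red = cumulative_reductions(result, window)
    total = float(red["reduction_tons"].sum())
    share = (
        share_of_economy_wide(total, economy_series, window)
        if economy_series is not None
        else None
    )
    lcp_df = None
    lcp_total = 0.0
    if lcp is not None:
        att_frac = (
            result.att_fraction()
            if convention == "exponentiated"
            else result.att_by_year
        )
        lcp_df = bound_lcp(att_frac, lcp.for_pollutant(pollutant), lcp_start_year)
        lcp_total = float(lcp_df["lcp_reduction_tons"].sum())
    money = monetize({pollutant: total}, {pollutant: lcp_total}, costs).iloc[0]
    notes = (
        "level counterfactuals are plain exponentials of log imputations "
        "(no retransformation correction)",
        "negative LCP-attributed tons denote emissions avoided by the plants",
    )
    return CobenefitReport(
        pollutant=pollutant,
        effects=effects,
        reductions_by_year=red,
        cumulative_reduction_tons=total,
        share_of_economy_wide_pct=share,
        lcp_by_year=lcp_df,
        lcp_attributed_tons=float(money["lcp_attributed_tons"]),
        joint_benefit=float(money["joint_benefit"]),
        lcp_attributed_benefit=float(money["lcp_attributed_benefit"]),
        bounded_benefit=float(money["bounded_benefit"]),
        currency=costs.currency,
        convention=convention,
        notes=notes,
    )
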