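"""Parametric-bootstrap confidence bands and robustness re-runs.

The bootstrap follows the standard scheme for generalized synthetic control
inference: control outcomes are simulated from the fitted factor model with
resampled control residuals, treated outcomes from the imputed counterfactual
plus a resampled *prediction-error* process (obtained by treating each control
unit in turn as pseudo-treated and recording its out-of-sample gap), and the
estimator is re-run on every simulated panel with the factor count held fixed.
Because the simulated treated units carry no treatment effect, each
replication's ATT path is a draw of pure estimation error; bands are formed by
adding its percentiles to the point estimate, which is equivalent to
percentile bands of the re-centred draws.

Residuals are resampled in whole unit blocks by default, preserving each
unit's serial correlation; i.i.d. cell resampling is available via
``resample="iid"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gscm import (
    ConvergenceError,
    CounterfactualResult,
    FactorModelFit,
    _als_core,
    estimate,
)
from .panel import PanelDataset, UNIT, log_transform

__all__ = [
    "BootstrapResult",
    "parametric_bootstrap",
    "leave_one_out",
    "in_time_placebo",
]


@dataclass(frozen=True)
class BootstrapResult:
    """Pointwise confidence bands for the ATT path from the parametric bootstrap.

    ``att_draws`` (replications x post years) already includes the point
    estimate, so percentile bands of the draws are the reported intervals;
    ``mean_att_draws`` carries the same construction for the
    across-units-and-periods mean effect. Replications whose refit failed to
    converge are dropped and counted in ``n_failed``.
    """

    n_reps: int
    n_failed: int
    level: float
    seed: int
    resample: str
    att_draws: pd.DataFrame
    ci_lower: pd.Series
    ci_upper: pd.Series
    mean_att_draws: np.ndarray
    mean_att_ci: tuple[float, float]
    run_id: str


def _project_arrays(
    Z: np.ndarray, F: np.ndarray, pre_idx: np.ndarray, additive: bool
) -> np.ndarray:
    """Fit intercept+loadings on pretreatment rows of Z; return fitted values.

    ``Z`` is the covariate- and time-effect-adjusted outcome (T x n); the
    return value is the imputed factor-plus-intercept component for all T
    rows.
    """
    G = np.column_stack([np.ones(len(F))] + ([F] if F.shape[1] else [])) if additive else F
    if G.shape[1] == 0:
        return np.zeros_like(Z)
    theta = np.linalg.lstsq(G[pre_idx], Z[pre_idx], rcond=None)[0]
    return G @ theta


def _control_arrays(panel: PanelDataset, fit: FactorModelFit):
    """Wide arrays for the bootstrap: outcomes and covariates, controls/treated."""
    controls, treated = panel.control_units, panel.treated_units
    covs = fit.covariates
    Yc = panel.wide_outcome(controls).to_numpy()
    Yt = panel.wide_outcome(treated).to_numpy()
    p = len(covs)
    T = len(panel.years)
    Xc = panel.wide_covariates(controls, covs) if p else np.zeros((T, len(controls), 0))
    Xt = panel.wide_covariates(treated, covs) if p else np.zeros((T, len(treated), 0))
    return Yc, Xc, Yt, Xt


def _prediction_errors(
    panel: PanelDataset,
    fit: FactorModelFit,
) -> pd.DataFrame:
    """Out-of-sample gap series from treating each control as pseudo-treated.

    For every control unit j: refit the factor model on the remaining
    controls (same r and settings), project j's loadings on pretreatment
    years, impute all years, and record observed-minus-imputed. The pool of
    these series emulates the counterfactual prediction error of a genuinely
    treated unit.
    """
    Yc, Xc, _, _ = _control_arrays(panel, fit)
    years = panel.years
    pre_idx = years < panel.treatment_start
    cols = {}
    for k, j in enumerate(panel.control_units):
        Ym = np.delete(Yc, k, axis=1)
        Xm = np.delete(Xc, k, axis=1)
        beta, F, _, mu, _, g, _, _, _ = _als_core(
            Ym, Xm, fit.r, fit.additive_effects, 1e-8, 2000, beta0=fit.beta_hat,
        )
        Z = Yc[:, k] - (Xc[:, k, :] @ beta if beta.size else 0.0)
        if fit.additive_effects:
            Z = Z - mu - g
        imput = _project_arrays(Z[:, None], F, pre_idx, fit.additive_effects)[:, 0]
        cols[j] = Z - imput
    return pd.DataFrame(cols, index=years)


def parametric_bootstrap(
    panel: PanelDataset,
    fit: FactorModelFit,
    result: CounterfactualResult,
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    resample: str = "block",
    max_failure_frac: float = 0.10,
) -> BootstrapResult:
    """Parametric-bootstrap bands for the ATT path and the mean effect.

    Parameters
    ----------
    panel, fit, result:
        A converged three-step estimation on the (log) panel.
    n_reps:
        Bootstrap replications (the study-scale default is 1000).
    level:
        Band coverage level, e.g. 0.95.
    seed:
        Seeds every random draw; identical seeds give identical bands.
    resample:
        ``"block"`` resamples whole unit residual series, ``"iid"``
        resamples cells independently.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    if result.run_id != fit.run_id:
        raise ValueError("result was computed from a different fit")
    if resample not in ("block", "iid"):
        raise ValueError(f"unknown resample scheme {resample!r}")
    panel = log_transform(panel) if not panel.is_log else panel
    rng = np.random.default_rng(seed)

    controls = panel.control_units
    treated = panel.treated_units
    years = panel.years
    T, Nc, Nt = len(years), len(controls), len(treated)

    fitted_c = fit.fitted[controls].to_numpy()
    eps = fit.resid[controls].to_numpy()  # T x Nc in-sample residuals
    # degrees-of-freedom rescaling: in-sample residuals understate the error
    # variance because the additive intercepts and the rank-r component absorb
    # noise; inflate them as in a standard regression residual bootstrap
    n_cells = T * Nc
    df_model = len(fit.covariates) + fit.r * (T + Nc) - fit.r**2
    if fit.additive_effects:
        df_model += T + Nc - 1
    if 0 < df_model < n_cells:
        eps = eps * np.sqrt(n_cells / (n_cells - df_model))
    pred_err = _prediction_errors(panel, fit).to_numpy()  # T x Nc
    y0_tr = result.y0_log[treated].to_numpy()
    _, Xc, _, Xt = _control_arrays(panel, fit)
    L_parent = fit.factors_hat.to_numpy() @ fit.control_loadings.to_numpy().T

    pre_idx = years < panel.treatment_start
    post_idx = ~pre_idx
    post = years[post_idx]
    err_draws = np.empty((n_reps, len(post)))
    mean_err = np.empty(n_reps)
    n_failed = 0
    kept = 0

    for _ in range(n_reps):
        if resample == "block":
            e_c = eps[:, rng.integers(0, Nc, size=Nc)]
            e_t = pred_err[:, rng.integers(0, Nc, size=Nt)]
        else:
            e_c = rng.choice(eps.ravel(), size=(T, Nc))
            e_t = rng.choice(pred_err.ravel(), size=(T, Nt))
        Yc_sim = fitted_c + e_c
        Yt_sim = y0_tr + e_t  # no treatment effect added
        try:
            beta, F, _, mu, _, g, _, _, _ = _als_core(
                Yc_sim, Xc, fit.r, fit.additive_effects, 1e-8, 2000,
                beta0=fit.beta_hat, L0=L_parent,
            )
        except ConvergenceError:
            n_failed += 1
            continue
        Z = Yt_sim - (Xt.dot(beta) if beta.size else 0.0)
        if fit.additive_effects:
            Z = Z - mu - g[:, None]
        gap = Z - _project_arrays(Z, F, pre_idx, fit.additive_effects)
        att_err = gap[post_idx].mean(axis=1)
        err_draws[kept] = att_err
        mean_err[kept] = att_err.mean()
        kept += 1

    if n_failed > max_failure_frac * n_reps:
        raise RuntimeError(
            f"{n_failed}/{n_reps} bootstrap refits failed (> {max_failure_frac:.0%})"
        )
    err_draws = err_draws[:kept]
    mean_err = mean_err[:kept]

    att_hat = result.att_by_year.to_numpy()
    draws = pd.DataFrame(att_hat[None, :] + err_draws, columns=post)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    # empirical (inverted-CDF) quantiles: the percentile-bootstrap convention,
    # which degenerates to min/max for two draws
    lo, hi = np.quantile(draws.to_numpy(), [lo_q, hi_q], axis=0, method="inverted_cdf")
    ci_lower = pd.Series(lo, index=post)
    ci_upper = pd.Series(hi, index=post)
    mean_draws = result.mean_att + mean_err
    mean_ci = (
        float(np.quantile(mean_draws, lo_q, method="inverted_cdf")),
        float(np.quantile(mean_draws, hi_q, method="inverted_cdf")),
    )
    return BootstrapResult(
        n_reps=n_reps,
        n_failed=n_failed,
        level=level,
        seed=seed,
        resample=resample,
        att_draws=draws,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        mean_att_draws=mean_draws,
        mean_att_ci=mean_ci,
        run_id=fit.run_id,
    )


def leave_one_out(
    panel: PanelDataset,
    r: int | None = None,
    covariates: Sequence[str] | None = None,
    additive_effects: bool = True,
    omit_controls: bool = False,
    candidates: Sequence[int] = (0, 1, 2, 3, 4, 5),
) -> dict[object, CounterfactualResult]:
    """Re-estimate the full model once per omitted unit.

    Omits each treated unit in turn (and optionally each control unit) and
    returns the counterfactual result per omission, keyed by the omitted
    unit.  Requires at least 3 treated units so every re-fit keeps >=2.
    """
    if panel.n_treated < 3:
        raise ValueError("leave-one-out needs >=3 treated units")
    out: dict[object, CounterfactualResult] = {}
    omit = list(panel.treated_units) + (list(panel.control_units) if omit_controls else [])
    for u in omit:
        sub = PanelDataset(
            panel.data[panel.data[UNIT] != u].copy(),
            panel.covariates,
            panel.treatment_start,
            is_log=panel.is_log,
        )
        _, res = estimate(
            sub, r=r, candidates=candidates, covariates=covariates,
            additive_effects=additive_effects,
        )
        out[u] = res
    return out


def in_time_placebo(
    panel: PanelDataset,
    pseudo_start: int,
    r: int | None = None,
    covariates: Sequence[str] | None = None,
    additive_effects: bool = True,
    candidates: Sequence[int] = (0, 1, 2, 3, 4, 5),
) -> CounterfactualResult:
    """Placebo estimation pretending adoption at ``pseudo_start``.

    Uses only data strictly before the true adoption year, shifts the
    adoption to ``pseudo_start`` and re-runs the full estimation; under a
    well-specified model the placebo ATT should be indistinguishable from
    zero.  Requires >=3 pre-placebo years and at least one post-placebo year
    inside the truncated window.
    """
    true_start = panel.treatment_start
    if pseudo_start >= true_start:
        raise ValueError("pseudo_start must precede the true adoption year")
    years = panel.years
    kept = years[years < true_start]
    if pseudo_start > kept.max():
        raise ValueError("placebo window contains no post-placebo years")
    if (kept < pseudo_start).sum() < 3:
        raise ValueError("placebo needs >=3 pre-placebo years")
    sub = panel.restrict_years(int(true_start - 1)).with_treatment_start(pseudo_start)
    _, res = estimate(
        sub, r=r, candidates=candidates, covariates=covariates,
        additive_effects=additive_effects,
    )
    return res
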