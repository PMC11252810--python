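"""Generalized synthetic control estimation on interactive-fixed-effects panels.

The estimator imputes counterfactual (log) emissions for treated units in
three steps:

1. On control units only, fit the factor model
   ``Y_it = x_it' beta + mu + a_i + g_t + lambda_i' F_t + eps_it`` by
   alternating least squares: given the rank-r component, solve the covariate
   coefficients and two-way intercepts jointly in closed form (intercepts
   profiled out by double demeaning); given those, take the best rank-r
   approximation of the residual matrix.
2. For each treated unit, choose its intercept and loadings by least squares
   on pretreatment years only, regressing the covariate- and time-effect-
   adjusted outcome on the estimated factors.
3. Impute the counterfactual for every treated unit-year from the fitted
   components; the treatment effect is the observed-minus-imputed gap, and
   the ATT in year t is its average over treated units.

The factor count ``r`` is selected by leave-one-pretreatment-period-out
cross-validation on the treated units.  Factors are normalized so that
``F'F / T = I`` with mutually orthogonal loadings; all reported quantities
(counterfactuals, effects) are invariant to this rotation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import OUTCOME_LEVEL, PanelDataset, log_transform

__all__ = [
    "FactorModelFit",
    "TreatedProjection",
    "CounterfactualResult",
    "ConvergenceError",
    "fit_ife_controls",
    "project_treated",
    "impute_and_att",
    "cross_validate_r",
    "estimate",
]

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 2000
DEFAULT_CANDIDATES = (0, 1, 2, 3, 4, 5)


class ConvergenceError(RuntimeError):
    """Alternating least squares failed to converge within the iteration cap."""

    def __init__(self, n_iter: int, last_change: float, objective: float):
        self.n_iter = n_iter
        self.last_change = last_change
        self.objective = objective
        super().__init__(
            f"ALS did not converge in {n_iter} iterations "
            f"(last relative change {last_change:.3e}, objective {objective:.6e})"
        )


@dataclass(frozen=True)
class FactorModelFit:
    """Interactive-fixed-effects fit on the control units.

    ``factors_hat`` spans all panel years (T x r, normalization F'F/T = I);
    ``control_loadings`` are the per-control-unit loadings.  ``mu``, ``alpha``
    and ``xi`` are the grand, unit and time intercepts when two-way additive
    effects are on (zero otherwise).  ``resid`` holds the in-sample control
    residuals used by the parametric bootstrap.
    """

    beta_hat: np.ndarray
    factors_hat: pd.DataFrame
    control_loadings: pd.DataFrame
    r: int
    covariates: tuple[str, ...]
    additive_effects: bool
    mu: float
    alpha: pd.Series
    xi: pd.Series
    n_iterations: int
    converged: bool
    resid: pd.DataFrame
    fitted: pd.DataFrame
    treatment_start: int
    run_id: str
    mspe_by_r: dict[int, float] | None = None

    @property
    def years(self) -> np.ndarray:
        return self.factors_hat.index.to_numpy()


@dataclass(frozen=True)
class TreatedProjection:
    """Treated-unit loadings and pretreatment fit from step two."""

    loadings: pd.DataFrame        # treated units x r
    alpha_treated: pd.Series      # treated-unit intercepts (0 if additive off)
    eta_resid: pd.DataFrame       # pretreatment residuals, years x units
    pre_fit_rmse: pd.Series       # per treated unit
    run_id: str


@dataclass(frozen=True)
class CounterfactualResult:
    """Imputed counterfactuals and treatment effects for the treated set.

    ``tau_hat`` (post years x treated units) is the log-scale effect
    ``log Y_it(1) - log Yhat_it(0)``; ``att_by_year`` its cross-unit mean per
    post year; ``gap_by_year`` extends the same average to pretreatment years,
    where it measures fit error and is ~0 by construction of the projection.
    Level-scale counterfactuals are plain exponentials of the log imputation.
    """

    y0_log: pd.DataFrame
    y0_level: pd.DataFrame
    observed_log: pd.DataFrame
    observed_level: pd.DataFrame
    tau_hat: pd.DataFrame
    att_by_year: pd.Series
    gap_by_year: pd.Series
    treated_loadings: pd.DataFrame
    pre_fit_rmse: pd.Series
    eta_resid: pd.DataFrame
    treatment_start: int
    run_id: str

    @property
    def mean_att(self) -> float:
        """Unweighted mean effect across treated units and post years (log scale)."""
        return float(self.tau_hat.to_numpy().mean())

    def att_fraction(self) -> pd.Series:
        """Per-year proportional (level-scale) effect, exp(ATT_t) - 1."""
        return np.exp(self.att_by_year) - 1.0


# --------------------------------------------------------------------------
# step one: ALS on control units


def _demean2(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0) - M.mean(axis=1, keepdims=True) + M.mean()


def _als_core(
    Y: np.ndarray,
    X: np.ndarray,
    r: int,
    additive: bool,
    tol: float,
    max_iter: int,
    beta0: np.ndarray | None = None,
    L0: np.ndarray | None = None,
):
    """Array-level alternating least squares for the control factor model.

    Alternates between two exact blocks of ``||Y - X.beta - A - F Lam'||^2``:
    given the rank-r component L, the covariate coefficients and the two-way
    intercepts A are solved jointly in closed form (the intercepts are
    profiled out by double demeaning); given (beta, A), L is the best rank-r
    approximation of the residual, obtained from the Gram eigenvectors of the
    smaller matrix side.  ``L0`` warm-starts the low-rank block (used by the
    bootstrap, where each simulated panel sits close to the fitted one);
    ``beta0`` is accepted for symmetry but the covariate block is recomputed
    exactly each iteration.  Returns
    ``(beta, F, Lam, mu, a, g, resid, n_iter, converged)``.
    """
    T, N = Y.shape
    p = X.shape[2]
    beta = np.zeros(p)
    if p:
        Xd = (
            np.stack([_demean2(X[:, :, k]) for k in range(p)], axis=2)
            if additive
            else X
        )
        Xd_pinv = np.linalg.pinv(Xd.reshape(T * N, p))

    mu, a, g = 0.0, np.zeros(N), np.zeros(T)
    if r == 0:
        # no factor block: the (beta, intercepts) problem is solved in one shot
        if p:
            Yd = _demean2(Y) if additive else Y
            beta = Xd_pinv @ Yd.ravel()
        R = Y - X.dot(beta) if p else Y.copy()
        if additive:
            mu = R.mean()
            a = R.mean(axis=0) - mu
            g = R.mean(axis=1) - mu
            resid = R - mu - a[None, :] - g[:, None]
        else:
            resid = R
        F = np.zeros((T, 0))
        Lam = np.zeros((N, 0))
        return beta, F, Lam, mu, a, g, resid, 1, True

    L = np.zeros((T, N)) if L0 is None else np.asarray(L0, dtype=float)
    obj_prev = np.inf
    scale = float((Y**2).sum()) or 1.0
    n_iter = 0
    last_change = np.inf
    converged = False
    for n_iter in range(1, max_iter + 1):
        W = Y - L
        if p:
            Wd = _demean2(W) if additive else W
            beta = Xd_pinv @ Wd.ravel()
            R = Y - X.dot(beta)
        else:
            R = Y
        if additive:
            V = R - L
            mu = V.mean()
            a = V.mean(axis=0) - mu
            g = V.mean(axis=1) - mu
            Rd = R - mu - a[None, :] - g[:, None]
        else:
            Rd = R
        # rank-r projection via the Gram eigenvectors of the smaller side;
        # cheaper than a full SVD and division-free (factors extracted once
        # after convergence)
        if N <= T:
            _, v = np.linalg.eigh(Rd.T @ Rd)
            vr = v[:, -r:]
            L = (Rd @ vr) @ vr.T
        else:
            _, u = np.linalg.eigh(Rd @ Rd.T)
            ur = u[:, -r:]
            L = ur @ (ur.T @ Rd)
        obj = float(((Rd - L) ** 2).sum())
        delta = abs(obj_prev - obj)
        last_change = delta / max(obj_prev, 1e-300)
        # absolute guard: a near-perfect fit can leave the relative change
        # chattering in float noise while the objective is negligible
        if last_change < tol or delta < 1e-16 * scale or obj < 1e-24 * scale:
            converged = True
            break
        obj_prev = obj
    if not converged:
        raise ConvergenceError(n_iter, last_change, obj)
    # extract normalized factors/loadings once from the converged residual
    R = Y - X.dot(beta) if p else Y
    if additive:
        W = R - L
        mu = W.mean()
        a = W.mean(axis=0) - mu
        g = W.mean(axis=1) - mu
        Rd = R - mu - a[None, :] - g[:, None]
    else:
        Rd = R
    U, s, Vt = np.linalg.svd(Rd, full_matrices=False)
    F = np.sqrt(T) * U[:, :r]
    Lam = Rd.T @ F / T
    L = F @ Lam.T
    resid = Rd - L
    return beta, F, Lam, mu, a, g, resid, n_iter, converged


def _panel_digest(Y: np.ndarray, r: int, covs: tuple, additive: bool) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(Y).tobytes())
    h.update(repr((r, covs, additive)).encode())
    return h.hexdigest()[:12]


def fit_ife_controls(
    panel: PanelDataset,
    r: int,
    covariates: Sequence[str] | None = None,
    additive_effects: bool = True,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FactorModelFit:
    """Estimate covariate coefficients and common factors on control units.

    Alternating least squares with deterministic initialization (pooled OLS of
    the two-way demeaned outcome on the demeaned covariates, then SVD of the
    residual matrix), so fits are reproducible without a seed.  Raises
    :class:`ConvergenceError` past ``max_iter`` and ``ValueError`` when ``r``
    exceeds what the control block can support.
    """
    panel = log_transform(panel) if not panel.is_log else panel
    covs = tuple(panel.covariates if covariates is None else covariates)
    controls = panel.control_units
    years = panel.years
    T, N = len(years), len(controls)
    if r < 0 or r > min(N, T) - 1:
        raise ValueError(f"r={r} infeasible for {N} control units x {T} years")

    Y = panel.wide_outcome(controls).to_numpy()
    p = len(covs)
    X = panel.wide_covariates(controls, covs) if p else np.zeros((T, N, 0))
    beta, F, Lam, mu, a, g, resid, n_iter, converged = _als_core(
        Y, X, r, additive_effects, tol, max_iter
    )
    fitted = Y - resid
    return FactorModelFit(
        beta_hat=beta,
        factors_hat=pd.DataFrame(F, index=years, columns=[f"f{k+1}" for k in range(r)]),
        control_loadings=pd.DataFrame(
            Lam, index=controls, columns=[f"f{k+1}" for k in range(r)]
        ),
        r=r,
        covariates=covs,
        additive_effects=additive_effects,
        mu=float(mu),
        alpha=pd.Series(a, index=controls),
        xi=pd.Series(g, index=years),
        n_iterations=n_iter,
        converged=converged,
        resid=pd.DataFrame(resid, index=years, columns=controls),
        fitted=pd.DataFrame(fitted, index=years, columns=controls),
        treatment_start=panel.treatment_start,
        run_id=_panel_digest(Y, r, covs, additive_effects),
    )


# --------------------------------------------------------------------------
# step two: treated-unit loadings from the pretreatment window


def _adjusted_outcome(fit: FactorModelFit, panel: PanelDataset, units: list) -> pd.DataFrame:
    """Outcome net of covariates and common (time) intercepts, years x units."""
    Y = panel.wide_outcome(units)
    p = len(fit.covariates)
    if p:
        X = panel.wide_covariates(units, fit.covariates)
        Y = Y - X.dot(fit.beta_hat)
    if fit.additive_effects:
        Y = Y.sub(fit.xi + fit.mu, axis=0)
    return Y


def project_treated(
    fit: FactorModelFit,
    panel: PanelDataset,
    pre_years: Sequence[int] | None = None,
) -> TreatedProjection:
    """Select treated-unit loadings by minimizing pretreatment MSPE.

    For each treated unit the intercept (when additive effects are on) and
    loadings solve an ordinary least-squares problem on the pretreatment
    years: adjusted outcome on the estimated factor paths.  ``pre_years``
    restricts the fitting window (used by cross-validation to hold one year
    out).
    """
    panel = log_transform(panel) if not panel.is_log else panel
    treated = panel.treated_units
    pre = np.array(sorted(pre_years)) if pre_years is not None else panel.pre_years
    r = fit.r
    n_coef = r + (1 if fit.additive_effects else 0)
    if len(pre) < n_coef:
        raise ValueError(
            f"{len(pre)} pretreatment years cannot identify {n_coef} loading "
            f"coefficients (r={r}, intercept={fit.additive_effects})"
        )
    Z = _adjusted_outcome(fit, panel, treated)
    Zpre = Z.loc[pre].to_numpy()
    Fpre = fit.factors_hat.loc[pre].to_numpy()
    G = np.column_stack([np.ones(len(pre)), Fpre]) if fit.additive_effects else Fpre
    if n_coef:
        theta = np.linalg.lstsq(G, Zpre, rcond=None)[0]
    else:
        theta = np.zeros((0, len(treated)))
    if fit.additive_effects:
        alpha_tr = pd.Series(theta[0], index=treated)
        lam = theta[1:].T
    else:
        alpha_tr = pd.Series(0.0, index=treated)
        lam = theta.T
    eta = Zpre - G @ theta if n_coef else Zpre
    rmse = pd.Series(np.sqrt((eta**2).mean(axis=0)), index=treated)
    return TreatedProjection(
        loadings=pd.DataFrame(lam, index=treated, columns=list(fit.factors_hat.columns)),
        alpha_treated=alpha_tr,
        eta_resid=pd.DataFrame(eta, index=pre, columns=treated),
        pre_fit_rmse=rmse,
        run_id=fit.run_id,
    )


# --------------------------------------------------------------------------
# step three: counterfactual imputation and effects


def impute_and_att(
    fit: FactorModelFit,
    projection: TreatedProjection,
    panel: PanelDataset,
) -> CounterfactualResult:
    """Impute counterfactual outcomes and average effects for treated units.

    The log counterfactual combines covariates, additive intercepts, and the
    factor paths weighted by the treated unit's loadings; the effect is the
    observed-minus-imputed log gap from the adoption year on, and the ATT per
    year is its mean over treated units.  Level counterfactuals are the
    exponentials of the log imputation (no retransformation correction).
    """
    if projection.run_id != fit.run_id:
        raise ValueError("projection was computed from a different fit")
    panel = log_transform(panel) if not panel.is_log else panel
    treated = panel.treated_units
    years = panel.years
    obs_log = panel.wide_outcome(treated)
    obs_level = panel.wide_outcome(treated, column=OUTCOME_LEVEL)

    p = len(fit.covariates)
    base = np.zeros((len(years), len(treated)))
    if p:
        X = panel.wide_covariates(treated, fit.covariates)
        base = base + X.dot(fit.beta_hat)
    if fit.additive_effects:
        base = base + fit.mu + fit.xi.to_numpy()[:, None]
        base = base + projection.alpha_treated.to_numpy()[None, :]
    if fit.r:
        base = base + fit.factors_hat.to_numpy() @ projection.loadings.to_numpy().T
    y0_log = pd.DataFrame(base, index=years, columns=treated)

    gap = obs_log - y0_log
    post = years[years >= panel.treatment_start]
    tau = gap.loc[post]
    return CounterfactualResult(
        y0_log=y0_log,
        y0_level=np.exp(y0_log),
        observed_log=obs_log,
        observed_level=obs_level,
        tau_hat=tau,
        att_by_year=tau.mean(axis=1),
        gap_by_year=gap.mean(axis=1),
        treated_loadings=projection.loadings,
        pre_fit_rmse=projection.pre_fit_rmse,
        eta_resid=projection.eta_resid,
        treatment_start=panel.treatment_start,
        run_id=fit.run_id,
    )


# --------------------------------------------------------------------------
# factor-count selection


def cross_validate_r(
    panel: PanelDataset,
    candidates: Sequence[int] = DEFAULT_CANDIDATES,
    covariates: Sequence[str] | None = None,
    additive_effects: bool = True,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FactorModelFit:
    """Choose the factor count by leave-one-pretreatment-period-out MSPE.

    For each candidate ``r`` the control model is fit once on all years; then
    each pretreatment year of the treated units is held out in turn, loadings
    are re-estimated on the remaining pretreatment years, and the held-out
    year is predicted.  The fit with the smallest mean squared prediction
    error wins; exact ties break toward the smaller ``r`` (parsimony).
    """
    panel = log_transform(panel) if not panel.is_log else panel
    if not len(candidates):
        raise ValueError("no candidate factor counts supplied")
    pre = panel.pre_years
    if len(pre) < 3:
        raise ValueError("cross-validation needs >=3 pretreatment periods")
    mspe: dict[int, float] = {}
    fits: dict[int, FactorModelFit] = {}
    for r in sorted(set(int(c) for c in candidates)):
        n_coef = r + (1 if additive_effects else 0)
        if r > min(panel.n_control, len(panel.years)) - 1 or n_coef > len(pre) - 1:
            continue
        fit = fit_ife_controls(panel, r, covariates, additive_effects, tol, max_iter)
        errs = []
        Z = _adjusted_outcome(fit, panel, panel.treated_units)
        for held in pre:
            keep = pre[pre != held]
            proj = project_treated(fit, panel, pre_years=keep)
            Fh = fit.factors_hat.loc[held].to_numpy()
            pred = proj.loadings.to_numpy() @ Fh + proj.alpha_treated.to_numpy()
            errs.append((Z.loc[held].to_numpy() - pred) ** 2)
        mspe[r] = float(np.mean(errs))
        fits[r] = fit
    if not mspe:
        raise ValueError(f"no feasible candidate in {list(candidates)}")
    best = min(mspe, key=lambda r: (mspe[r], r))
    return replace(fits[best], mspe_by_r=mspe)


def estimate(
    panel: PanelDataset,
    r: int | None = None,
    candidates: Sequence[int] = DEFAULT_CANDIDATES,
    covariates: Sequence[str] | None = None,
    additive_effects: bool = True,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[FactorModelFit, CounterfactualResult]:
    """Run the full three-step estimation; cross-validate ``r`` when None."""
    panel = log_transform(panel) if not panel.is_log else panel
    if r is None:
        fit = cross_validate_r(panel, candidates, covariates, additive_effects, tol, max_iter)
    else:
        fit = fit_ife_controls(panel, r, covariates, additive_effects, tol, max_iter)
    proj = project_treated(fit, panel)
    return fit, impute_and_att(fit, proj, panel)
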