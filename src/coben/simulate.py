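"""Synthetic emission panels with known ground truth.

Panels are generated forward from the interactive-fixed-effects outcome model

    log y_it = a_i + tau_t * D_it + x_it' beta + lambda_i' F_t + eps_it,

where ``D_it`` is the adoption indicator (treated unit, year >= adoption).
Everything the estimator is asked to recover — factor paths, loadings,
covariate coefficients, the treatment-effect profile and the noise-free
counterfactual — is retained in :class:`SyntheticPanel.truth`, so estimation,
inference and reporting can be tested end-to-end without external data.

The default preset mimics the shape of the EU-25 study design: 25 countries
contributing one regulated and one unregulated aggregate each, annual data
1990-2021, adoption in 2005, two common factors, and log GDP (mean-centred)
plus its square as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import OUTCOME, PanelDataset, TREATED, UNIT, YEAR

__all__ = ["DgpSpec", "SyntheticPanel", "generate", "emissions_like_preset"]


@dataclass(frozen=True)
class DgpSpec:
    """Ground-truth configuration of the synthetic data-generating process.

    Attributes
    ----------
    n_control, n_treated:
        Unit counts in the control and treated sets.
    start_year, end_year:
        Inclusive calendar range of the balanced panel.
    treatment_start:
        Adoption year; effects apply to treated units from this year on.
    n_factors:
        True factor count ``r`` (0 for a pure covariate model).
    factor_scale:
        Standard deviation of factor innovations.
    loading_scale:
        Standard deviation of the i.i.d. normal loadings ``lambda_i``.
    factor_process:
        ``"iid"`` for independent innovations each year, ``"random_walk"``
        for trending factors (cumulated innovations).
    beta_true:
        Covariate coefficient vector; its length fixes the covariate count.
    covariate_model:
        ``"gdp_random_walk"`` generates a mean-centred log-GDP random walk per
        unit plus its square; ``"none"`` generates no covariates (requires an
        empty ``beta_true``).
    confound_scale:
        If nonzero, loadings receive a component proportional to the unit's
        mean log GDP, inducing covariate-factor confounding. Off by default.
    tau_profile:
        Mapping year -> true log-scale treatment effect ``tau_t``; must cover
        exactly the years >= adoption.
    noise_sd:
        Standard deviation of the idiosyncratic shock ``eps_it``.
    base_level:
        Mean of the unit intercepts on the log scale; the default puts levels
        near 2e5 tons/year, a national-aggregate order of magnitude.
    seed:
        Base seed; same seed implies a bit-identical panel.
    """

    n_control: int = 25
    n_treated: int = 25
    start_year: int = 1990
    end_year: int = 2021
    treatment_start: int = 2005
    n_factors: int = 2
    factor_scale: float = 0.2
    loading_scale: float = 1.0
    factor_process: str = "iid"
    beta_true: tuple[float, ...] = (0.5, -0.2)
    covariate_model: str = "gdp_random_walk"
    confound_scale: float = 0.0
    tau_profile: Mapping[int, float] | None = None
    noise_sd: float = 0.05
    base_level: float = 12.2
    base_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_treated < 1:
            raise ValueError("need >=2 control and >=1 treated units")
        if self.end_year < self.start_year:
            raise ValueError("empty year range")
        if self.n_factors < 0:
            raise ValueError("n_factors must be >= 0")
        if not self.noise_sd >= 0:
            raise ValueError("noise_sd must be non-negative")
        if self.factor_process not in ("iid", "random_walk"):
            raise ValueError(f"unknown factor_process {self.factor_process!r}")
        if self.covariate_model not in ("gdp_random_walk", "none"):
            raise ValueError(f"unknown covariate_model {self.covariate_model!r}")
        if self.covariate_model == "none" and len(self.beta_true) != 0:
            raise ValueError("covariate_model 'none' requires empty beta_true")
        post = [y for y in self.years if y >= self.treatment_start]
        tau = self.tau_profile if self.tau_profile is not None else {}
        if post and sorted(tau) != post:
            raise ValueError(
                f"tau_profile must cover exactly the post years {post[0]}-{post[-1]}"
            )
        for s in (self.factor_scale, self.loading_scale, self.noise_sd):
            if not np.isfinite(s):
                raise ValueError("all scales must be finite")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))

    @property
    def covariate_names(self) -> tuple[str, ...]:
        if self.covariate_model == "none":
            return ()
        return ("log_gdp", "log_gdp_sq")[: len(self.beta_true)]


@dataclass(frozen=True)
class SyntheticPanel:
    """A generated panel together with its realized ground truth.

    ``truth`` holds the drawn factors ``F`` (years x r), loadings ``lambda``
    (units x r), ``beta``, the per-year effect profile ``tau``, and the
    noise-free and noisy log counterfactuals ``y0_log`` for every unit-year,
    so that log Y(1) - log Y(0) equals the specified tau exactly on treated
    post-adoption cells.
    """

    panel: PanelDataset
    truth: dict
    spec: DgpSpec


def _declining_tau(years: list[int], treatment_start: int, final: float = -0.5) -> dict[int, float]:
    """Linearly deepening effect profile reaching ``final`` in the last year."""
    post = [y for y in years if y >= treatment_start]
    n = len(post)
    return {y: final * (k + 1) / n for k, y in enumerate(post)}


def emissions_like_preset(**overrides) -> DgpSpec:
    """Default spec shaped like the EU-25 study panel.

    25 treated + 25 control units over 1990-2021 with adoption in 2005, two
    strong i.i.d. factors, mean-centred log GDP and its square as covariates,
    and a linearly deepening treatment-effect profile. Any field can be
    overridden by keyword; ``tau_profile`` may be given as a constant float,
    which is broadcast over the post-adoption years.
    """
    tau = overrides.pop("tau_profile", None)
    kw = dict(overrides)
    start = kw.get("start_year", 1990)
    end = kw.get("end_year", 2021)
    t0 = kw.get("treatment_start", 2005)
    years = list(range(start, end + 1))
    if tau is None:
        tau = _declining_tau(years, t0)
    elif isinstance(tau, (int, float)):
        tau = {y: float(tau) for y in years if y >= t0}
    return DgpSpec(tau_profile=dict(tau), **kw)


def generate(spec: DgpSpec) -> SyntheticPanel:
    """Simulate the factor model forward and return panel plus ground truth.

    Outcomes are built on the log scale and exponentiated, so they are
    strictly positive by construction and the generated panel always passes
    validation. Reproducible: the same spec (including seed) yields a
    bit-identical panel.
    """
    rng = np.random.default_rng(spec.seed)
    years = np.array(spec.years)
    T = len(years)
    n = spec.n_treated + spec.n_control
    unit_ids = [f"T{i+1:02d}" for i in range(spec.n_treated)] + [
        f"C{i+1:02d}" for i in range(spec.n_control)
    ]
    treated_mask = np.array([u.startswith("T") for u in unit_ids])

    alpha = rng.normal(spec.base_level, spec.base_sd, size=n)

    # covariates
    p = len(spec.beta_true)
    X = np.zeros((T, n, p))
    if spec.covariate_model == "gdp_random_walk" and p:
        start = rng.normal(0.0, 0.6, size=n)
        steps = rng.normal(0.02, 0.03, size=(T - 1, n))
        log_gdp = np.vstack([start, start + np.cumsum(steps, axis=0)])
        X[:, :, 0] = log_gdp
        if p > 1:
            X[:, :, 1] = log_gdp**2

    # common factors and unit loadings
    r = spec.n_factors
    innov = rng.normal(0.0, spec.factor_scale, size=(T, r))
    F = np.cumsum(innov, axis=0) if spec.factor_process == "random_walk" else innov
    lam = rng.normal(0.0, spec.loading_scale, size=(n, r))
    if spec.confound_scale and p:
        lam = lam + spec.confound_scale * X[:, :, 0].mean(axis=0)[:, None]

    beta = np.asarray(spec.beta_true, dtype=float)
    eps = rng.normal(0.0, spec.noise_sd, size=(T, n))

    y0_clean = alpha[None, :] + X.reshape(T * n, p).dot(beta).reshape(T, n)
    if r:
        y0_clean = y0_clean + F @ lam.T
    y0_log = y0_clean + eps  # counterfactual incl. idiosyncratic shock

    tau_t = np.array([spec.tau_profile.get(int(y), 0.0) if spec.tau_profile else 0.0 for y in years])
    D = treated_mask[None, :] & (years >= spec.treatment_start)[:, None]
    y_log = y0_log + tau_t[:, None] * D

    rows = []
    for j, u in enumerate(unit_ids):
        rows.append(
            pd.DataFrame(
                {
                    UNIT: u,
                    TREATED: bool(treated_mask[j]),
                    YEAR: years,
                    OUTCOME: np.exp(y_log[:, j]),
                    **{
                        name: X[:, j, k]
                        for k, name in enumerate(spec.covariate_names)
                    },
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    panel = PanelDataset(df, spec.covariate_names, spec.treatment_start)

    truth = {
        "factors": pd.DataFrame(F, index=years, columns=[f"f{k+1}" for k in range(r)]),
        "loadings": pd.DataFrame(
            lam, index=unit_ids, columns=[f"f{k+1}" for k in range(r)]
        ),
        "beta": beta,
        "alpha": pd.Series(alpha, index=unit_ids),
        "tau": pd.Series(tau_t, index=years, name="tau"),
        "y0_log": pd.DataFrame(y0_log, index=years, columns=unit_ids),
        "y0_clean_log": pd.DataFrame(y0_clean, index=years, columns=unit_ids),
        "y0_level": pd.DataFrame(np.exp(y0_log), index=years, columns=unit_ids),
    }
    return SyntheticPanel(panel=panel, truth=truth, spec=spec)


def synthetic_lcp_series(
    sp: SyntheticPanel, pollutant: str = "SO2", fraction: float = 0.4,
    start_year: int = 2008,
) -> pd.DataFrame:
    """Synthetic stand-in for an LCP emissions series (no real register data).

    Takes a fixed ``fraction`` of the treated units' observed emissions in
    each year from ``start_year`` on, mimicking the share of regulated output
    coming from large combustion plants. Purely a plumbing fixture for the
    bounding computation; it encodes no empirical LCP information.
    """
    d = sp.panel.data
    post = d[(d[TREATED]) & (d[YEAR] >= start_year)]
    series = post.groupby(YEAR)[OUTCOME].sum() * fraction
    return pd.DataFrame(
        {"year": series.index, "pollutant": pollutant, "emissions": series.to_numpy()}
    ).reset_index(drop=True)


def economy_wide_series(sp: SyntheticPanel) -> pd.Series:
    """Economy-wide emissions by year: sum of all units' observed levels.

    In the synthetic world the panel covers the whole economy, so the
    denominator for the share-of-economy-wide statistic is the total across
    both treated and control units.
    """
    return sp.panel.data.groupby(YEAR)[OUTCOME].sum()
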