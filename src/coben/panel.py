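"""Balanced treated/control emission panels: data model, validation and I/O.

The canonical representation is a long-format :class:`pandas.DataFrame` with
one row per unit-year, holding a strictly positive emissions outcome (tons per
year), a treatment-group flag, and named real-valued covariate columns.  Wide
outcome/covariate matrices used by the estimator are built on demand.

Treatment timing is a single adoption year ``treatment_start`` (default 2005,
the first EU ETS trading period); the binary treatment indicator is derived,
never stored: it equals 1 iff the unit is in the treated set and the year is
at or after adoption.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "LcpSeries",
    "CostConfig",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "log_transform",
    "validate_panel_frame",
]

#: canonical column names of the long format
UNIT, TREATED, YEAR, OUTCOME = "unit", "treated", "year", "outcome"
#: level-scale outcome retained after a log transform
OUTCOME_LEVEL = "outcome_level"


class PanelValidationError(ValueError):
    """Raised when a long-format frame violates a panel invariant.

    Carries the full list of problems in :attr:`problems` so callers (and the
    JSON validation report) can show every offending unit/year at once.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid panel:\n  - " + "\n  - ".join(self.problems))


def validate_panel_frame(
    df: pd.DataFrame,
    covariates: Sequence[str],
    treatment_start: int,
    outcome_positive: bool = True,
) -> list[str]:
    """Check every panel invariant on ``df`` and return the list of violations.

    An empty list means the frame is a valid balanced panel: one row per
    unit-year over a single contiguous year range shared by all units, strictly
    positive outcomes, no missing covariate cells, at least two control units,
    and at least two pretreatment years for the treated group.
    """
    problems: list[str] = []
    required = [UNIT, TREATED, YEAR, OUTCOME, *covariates]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        return [f"missing required columns: {missing_cols}"]

    if df.empty:
        return ["panel has no rows"]

    dup = df.duplicated(subset=[UNIT, YEAR])
    if dup.any():
        pairs = df.loc[dup, [UNIT, YEAR]].itertuples(index=False)
        problems.append(
            "duplicate unit-year rows: " + ", ".join(f"({u}, {y})" for u, y in pairs)
        )

    years = np.sort(df[YEAR].unique())
    full_range = np.arange(years.min(), years.max() + 1)
    if not np.array_equal(years, full_range):
        gaps = sorted(set(full_range) - set(years))
        problems.append(f"year range {years.min()}-{years.max()} has gaps at {gaps}")

    counts = df.groupby(UNIT)[YEAR].agg(["count", "nunique", "min", "max"])
    bad = counts[
        (counts["nunique"] != len(full_range))
        | (counts["min"] != full_range[0])
        | (counts["max"] != full_range[-1])
    ]
    for unit, row in bad.iterrows():
        have = set(df.loc[df[UNIT] == unit, YEAR])
        miss = sorted(set(full_range) - have)
        problems.append(f"unit {unit!r} is unbalanced: missing years {miss}")

    if outcome_positive:
        nonpos = df[~(df[OUTCOME] > 0)]
        for idx, row in nonpos.iterrows():
            problems.append(
                f"non-positive outcome {row[OUTCOME]!r} at unit {row[UNIT]!r}, "
                f"year {row[YEAR]} (row {idx}); log transform undefined"
            )
    elif df[OUTCOME].isna().any():
        problems.append("outcome column contains missing values")

    for cov in covariates:
        nan_rows = df[df[cov].isna()]
        if not nan_rows.empty:
            where = [(r[UNIT], r[YEAR]) for _, r in nan_rows.head(10).iterrows()]
            problems.append(
                f"covariate {cov!r} has {len(nan_rows)} missing cells, "
                f"e.g. {where}; no imputation is performed"
            )

    flags = df.groupby(UNIT)[TREATED].nunique()
    mixed = flags[flags > 1].index.tolist()
    if mixed:
        problems.append(f"units with inconsistent treated flag: {mixed}")

    treated_units = df.loc[df[TREATED].astype(bool), UNIT].unique()
    control_units = df.loc[~df[TREATED].astype(bool), UNIT].unique()
    if len(control_units) < 2:
        problems.append(f"need at least 2 control units, found {len(control_units)}")
    if len(treated_units) >= 1:
        n_pre = int((full_range < treatment_start).sum())
        if n_pre < 2:
            problems.append(
                f"treated units need >=2 pretreatment years before {treatment_start}, "
                f"panel provides {n_pre}"
            )
    return problems


@dataclass(frozen=True)
class PanelDataset:
    """A validated balanced long panel of emissions outcomes and covariates.

    Parameters
    ----------
    data:
        Long-format frame with canonical columns ``unit``, ``treated``,
        ``year``, ``outcome`` plus the declared covariate columns, sorted by
        (unit, year).
    covariates:
        Names of the covariate columns in :attr:`data`.
    treatment_start:
        Adoption year ``t_ETS``; the derived indicator is
        ``treated & (year >= treatment_start)``.
    is_log:
        Whether ``outcome`` currently holds natural-log values.  When True the
        original levels are kept in ``outcome_level``.
    """

    data: pd.DataFrame
    covariates: tuple[str, ...] = ()
    treatment_start: int = 2005
    is_log: bool = False

    def __post_init__(self) -> None:
        problems = validate_panel_frame(
            self.data, self.covariates, self.treatment_start,
            outcome_positive=not self.is_log,
        )
        if self.is_log:
            if OUTCOME_LEVEL not in self.data.columns:
                problems.append("log panel must retain the level outcome column")
            elif not (self.data[OUTCOME_LEVEL] > 0).all():
                problems.append("retained level outcomes must be strictly positive")
        if problems:
            raise PanelValidationError(problems)
        df = self.data.sort_values([UNIT, YEAR], kind="mergesort").reset_index(drop=True)
        df[TREATED] = df[TREATED].astype(bool)
        df[YEAR] = df[YEAR].astype(int)
        object.__setattr__(self, "data", df)
        object.__setattr__(self, "covariates", tuple(self.covariates))

    # ---- basic views -----------------------------------------------------

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data[YEAR].unique())

    @property
    def units(self) -> list:
        return sorted(self.data[UNIT].unique())

    @property
    def treated_units(self) -> list:
        return sorted(self.data.loc[self.data[TREATED], UNIT].unique())

    @property
    def control_units(self) -> list:
        return sorted(self.data.loc[~self.data[TREATED], UNIT].unique())

    @property
    def n_treated(self) -> int:
        return len(self.treated_units)

    @property
    def n_control(self) -> int:
        return len(self.control_units)

    @property
    def pre_years(self) -> np.ndarray:
        return self.years[self.years < self.treatment_start]

    @property
    def post_years(self) -> np.ndarray:
        return self.years[self.years >= self.treatment_start]

    def treatment_indicator(self) -> pd.Series:
        """The binary ETS indicator: 1 iff treated and year >= adoption."""
        d = self.data
        return (d[TREATED] & (d[YEAR] >= self.treatment_start)).astype(int)

    # ---- wide matrices for the estimator ---------------------------------

    def wide_outcome(self, units: Iterable | None = None, column: str = OUTCOME) -> pd.DataFrame:
        """Pivot ``column`` into a (years x units) matrix."""
        sub = self.data if units is None else self.data[self.data[UNIT].isin(list(units))]
        wide = sub.pivot(index=YEAR, columns=UNIT, values=column).sort_index()
        if units is not None:
            wide = wide[list(units)]
        return wide

    def wide_covariates(self, units: Sequence, covariates: Sequence[str]) -> np.ndarray:
        """Covariate array of shape (T, N, p) aligned with :meth:`wide_outcome`."""
        T, N, p = len(self.years), len(units), len(covariates)
        out = np.empty((T, N, p))
        for k, cov in enumerate(covariates):
            out[:, :, k] = self.wide_outcome(units, column=cov).to_numpy()
        return out

    def with_treatment_start(self, year: int) -> "PanelDataset":
        """Same panel, different adoption year (for in-time placebos)."""
        return replace(self, treatment_start=int(year))

    def restrict_years(self, last_year: int) -> "PanelDataset":
        """Drop all rows after ``last_year``."""
        return replace(self, data=self.data[self.data[YEAR] <= last_year].copy())

    def validation_report(self) -> dict:
        """Machine-readable summary used by the CLI's JSON report."""
        return {
            "n_rows": int(len(self.data)),
            "n_units": len(self.units),
            "n_treated": self.n_treated,
            "n_control": self.n_control,
            "years": [int(self.years.min()), int(self.years.max())],
            "treatment_start": self.treatment_start,
            "covariates": list(self.covariates),
            "is_log": self.is_log,
            "problems": [],
        }


@dataclass(frozen=True)
class LcpSeries:
    """Annual emissions of large combustion plants (LCPs), tons/year per pollutant.

    Used by the bounding correction that subtracts reductions attributable to
    plants jointly regulated by the trading system and combustion standards.
    """

    data: pd.DataFrame  # columns: year, pollutant, emissions

    def __post_init__(self) -> None:
        req = {"year", "pollutant", "emissions"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"LCP series needs columns {sorted(req)}")
        if (self.data["emissions"] < 0).any():
            raise ValueError("LCP emissions must be non-negative")

    def pollutants(self) -> list[str]:
        return sorted(self.data["pollutant"].unique())

    def for_pollutant(self, pollutant: str) -> pd.Series:
        sub = self.data[self.data["pollutant"] == pollutant]
        return sub.set_index("year")["emissions"].sort_index()


@dataclass(frozen=True)
class CostConfig:
    """Per-ton damage-cost factors by pollutant (currency units per ton).

    Values are pure configuration: the currency, price year and any inflation
    adjustment are echoed in outputs but never computed internally.
    """

    costs: Mapping[str, float]
    currency: str = "EUR"
    note: str = ""

    def __post_init__(self) -> None:
        bad = {p: c for p, c in self.costs.items() if not c > 0}
        if bad:
            raise ValueError(f"damage costs must be positive, got {bad}")

    def cost_per_ton(self, pollutant: str) -> float:
        try:
            return float(self.costs[pollutant])
        except KeyError:
            raise KeyError(
                f"no damage-cost factor configured for pollutant {pollutant!r}"
            ) from None


def read_panel(
    path,
    schema: Mapping[str, str] | None = None,
    covariates: Sequence[str] = (),
    treatment_start: int = 2005,
) -> PanelDataset:
    """Read a long-format delimited text file into a validated panel.

    Parameters
    ----------
    path:
        CSV file with a header row, one row per unit-year.
    schema:
        Optional mapping from *file* column names to canonical names
        (``unit``, ``treated``, ``year``, ``outcome`` and covariate names), so
        inventory exports with arbitrary headers can be consumed unchanged.
    covariates:
        Canonical covariate column names expected after renaming.
    treatment_start:
        Adoption year.

    Raises
    ------
    PanelValidationError
        If the file violates any panel invariant (unbalanced, non-positive
        outcome, missing covariate cell, ...), naming the offending rows.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    keep = [UNIT, TREATED, YEAR, OUTCOME, *covariates]
    present = [c for c in keep if c in df.columns]
    return PanelDataset(df[present].copy(), tuple(covariates), int(treatment_start))


def write_panel(panel: PanelDataset, path) -> None:
    """Write the validated panel back to CSV (canonical column names)."""
    panel.data.to_csv(path, index=False)


def log_transform(panel: PanelDataset) -> PanelDataset:
    """Replace the outcome by its natural log, retaining levels alongside.

    The factor model is specified on log emissions, so all estimation happens
    on the transformed panel; the retained ``outcome_level`` column supports
    back-transformation of counterfactuals to tons.
    """
    if panel.is_log:
        return panel
    df = panel.data.copy()
    df[OUTCOME_LEVEL] = df[OUTCOME].astype(float)
    df[OUTCOME] = np.log(df[OUTCOME].astype(float))
    return PanelDataset(df, panel.covariates, panel.treatment_start, is_log=True)
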