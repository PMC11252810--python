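"""Run orchestration: configuration, manifests, and the staged pipeline.

A run is described by one declarative mapping (usually a YAML file) with
``simulate`` / ``data``, ``estimator``, ``bootstrap`` and ``report`` sections;
:func:`run_pipeline` executes simulate (optional) -> fit -> bootstrap ->
report and writes every stage artifact plus a :class:`RunManifest` into a run
directory.  Fits are deterministic given the data and settings (no seed), so
a manifest plus the input digests fully identifies a fit; stochastic stages
(simulation, bootstrap) record their seeds and reproduce identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cobenefits import build_report
from .gscm import estimate
from .inference import parametric_bootstrap
from .panel import CostConfig, LcpSeries, log_transform, read_panel, write_panel
from .simulate import economy_wide_series, emissions_like_preset, generate, synthetic_lcp_series

__all__ = ["RunManifest", "run_pipeline", "covariate_set_columns", "load_config"]

#: named covariate sets mirroring the specification variants
COVARIATE_SETS: dict[str, tuple[str, ...]] = {
    "none": (),
    "main": ("log_gdp", "log_gdp_sq"),
    "additional-policies": ("log_gdp", "log_gdp_sq", "carbon_price", "log_renewables"),
}


def covariate_set_columns(name_or_list) -> tuple[str, ...]:
    """Resolve a covariate-set name (none/main/additional-policies) or list."""
    if isinstance(name_or_list, str):
        try:
            return COVARIATE_SETS[name_or_list]
        except KeyError:
            raise ValueError(
                f"unknown covariate set {name_or_list!r}; "
                f"choose from {sorted(COVARIATE_SETS)} or give a column list"
            ) from None
    return tuple(name_or_list)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every run's outputs."""

    config_hash: str
    input_digests: dict
    covariate_set: list
    estimator: dict
    seeds: dict
    version: str
    created: str

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _make_manifest(config: Mapping, input_paths: Mapping[str, Path], covs, est, seeds) -> RunManifest:
    return RunManifest(
        config_hash=_config_hash(config),
        input_digests={k: _digest_file(p) for k, p in input_paths.items() if p and Path(p).exists()},
        covariate_set=list(covs),
        estimator=dict(est),
        seeds=dict(seeds),
        version=__version__,
        created=datetime.now(timezone.utc).isoformat(),
    )


def run_pipeline(config: Mapping, outdir, make_figures: bool = False) -> dict:
    """Execute simulate (optional) -> fit -> bootstrap -> report.

    Returns a dict with the in-memory stage objects (``panel``, ``fit``,
    ``result``, ``bands``, ``report``, ``manifest``) and writes CSV/JSON
    artifacts into ``outdir``.  Any stage failure is re-raised with the stage
    name prefixed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    input_paths: dict[str, Path] = {}

    def stage(name):
        class _Stage:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Stage()

    # ---- simulate or load ------------------------------------------------
    sp = None
    with stage("simulate/load"):
        if "simulate" in cfg:
            sim = cfg["simulate"]
            overrides = dict(sim.get("overrides", {}))
            if "seed" in sim:
                overrides["seed"] = int(sim["seed"])
            spec = emissions_like_preset(**overrides)
            sp = generate(spec)
            panel = sp.panel
            write_panel(panel, outdir / "panel.csv")
            truth = pd.concat(
                {
                    "tau": sp.truth["tau"],
                },
                axis=1,
            )
            truth.to_csv(outdir / "truth_tau.csv")
            sp.truth["y0_level"].to_csv(outdir / "truth_y0_level.csv")
            input_paths["panel"] = outdir / "panel.csv"
        else:
            data = cfg["data"]
            input_paths["panel"] = Path(data["panel"])
            panel = read_panel(
                data["panel"],
                schema=data.get("schema"),
                covariates=tuple(data.get("covariates", ())),
                treatment_start=int(data.get("treatment_start", 2005)),
            )
        panel = log_transform(panel)
        (outdir / "validation.json").write_text(
            json.dumps(panel.validation_report(), indent=2) + "\n"
        )

    # ---- fit -------------------------------------------------------------
    est_cfg = dict(cfg.get("estimator", {}))
    covs = covariate_set_columns(est_cfg.get("covariate_set", list(panel.covariates)))
    with stage("fit"):
        fit, result = estimate(
            panel,
            r=est_cfg.get("r"),
            candidates=tuple(est_cfg.get("candidates", (0, 1, 2, 3, 4, 5))),
            covariates=covs,
            additive_effects=bool(est_cfg.get("additive_effects", True)),
        )
        result.att_by_year.rename("att_log").to_frame().assign(
            att_pct=100 * (np.exp(result.att_by_year) - 1)
        ).to_csv(outdir / "att_by_year.csv", index_label="year")
        result.tau_hat.to_csv(outdir / "tau_by_unit_year.csv", index_label="year")
        result.y0_level.to_csv(outdir / "counterfactual_level.csv", index_label="year")

    # ---- bootstrap -------------------------------------------------------
    boot_cfg = dict(cfg.get("bootstrap", {}))
    with stage("bootstrap"):
        bands = parametric_bootstrap(
            panel,
            fit,
            result,
            n_reps=int(boot_cfg.get("n_reps", 1000)),
            level=float(boot_cfg.get("level", 0.95)),
            seed=int(boot_cfg.get("seed", 0)),
            resample=boot_cfg.get("resample", "block"),
        )
        pd.DataFrame(
            {
                "att_log": result.att_by_year,
                "ci_lower": bands.ci_lower,
                "ci_upper": bands.ci_upper,
            }
        ).to_csv(outdir / "bands.csv", index_label="year")
        bands.att_draws.to_csv(outdir / "draws.csv", index_label="rep")

    # ---- report ----------------------------------------------------------
    rep_cfg = dict(cfg.get("report", {}))
    with stage("report"):
        pollutant = rep_cfg.get("pollutant", "SO2")
        costs = CostConfig(
            rep_cfg.get("costs", {pollutant: 1.0}),
            currency=rep_cfg.get("currency", "EUR"),
            note=rep_cfg.get("cost_note", ""),
        )
        if "lcp" in rep_cfg:
            lcp = LcpSeries(pd.read_csv(rep_cfg["lcp"]))
            input_paths["lcp"] = Path(rep_cfg["lcp"])
        elif sp is not None:
            lcp_df = synthetic_lcp_series(sp, pollutant=pollutant)
            lcp_df.to_csv(outdir / "lcp_synthetic.csv", index=False)
            lcp = LcpSeries(lcp_df)
        else:
            lcp = None
        if "economy" in rep_cfg:
            eco_df = pd.read_csv(rep_cfg["economy"])
            economy = eco_df.set_index("year")["emissions"]
            input_paths["economy"] = Path(rep_cfg["economy"])
        elif sp is not None:
            economy = economy_wide_series(sp)
        else:
            economy = None
        window = tuple(rep_cfg["window"]) if "window" in rep_cfg else None
        report = build_report(
            pollutant,
            result,
            bands,
            costs,
            lcp=lcp,
            economy_series=economy,
            window=window,
            lcp_start_year=int(rep_cfg.get("lcp_start_year", 2008)),
            convention=rep_cfg.get("convention", "exponentiated"),
        )
        report.reductions_by_year.to_csv(outdir / "reductions_by_year.csv", index=False)

    est_settings = {
        "r": fit.r,
        "cross_validated": est_cfg.get("r") is None,
        "mspe_by_r": fit.mspe_by_r,
        "additive_effects": fit.additive_effects,
        "n_iterations": fit.n_iterations,
        "converged": fit.converged,
        "percent_convention": report.convention,
        "bootstrap_resample": bands.resample,
    }
    seeds = {
        "simulate": cfg.get("simulate", {}).get("seed"),
        "bootstrap": boot_cfg.get("seed", 0),
    }
    manifest = _make_manifest(cfg, input_paths, covs, est_settings, seeds)
    manifest.to_json(outdir / "manifest.json")
    report_payload = {"manifest_config_hash": manifest.config_hash, **report.to_dict()}
    (outdir / "report.json").write_text(json.dumps(report_payload, indent=2) + "\n")

    if make_figures:
        from .plotting import plot_paths

        plot_paths(result, bands, outdir / f"paths_{pollutant}.svg", pollutant=pollutant)

    return {
        "panel": panel,
        "fit": fit,
        "result": result,
        "bands": bands,
        "report": report,
        "manifest": manifest,
    }
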