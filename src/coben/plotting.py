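"""Figure-style outputs: emission paths and ATT bands."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gscm import CounterfactualResult
from .inference import BootstrapResult

__all__ = ["plot_paths"]


def plot_paths(
    result: CounterfactualResult,
    bands: BootstrapResult | None,
    path,
    pollutant: str = "",
) -> Path:
    """Two-panel figure: observed vs counterfactual paths, and the ATT band.

    Top: level-scale emissions averaged across treated units, observed (black)
    against the imputed counterfactual (orange), with a vertical marker at the
    adoption year.  Bottom: the estimated ATT in percent with the bootstrap
    interval shaded.  The output format follows the file suffix (svg/pdf/png).
    """
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(6.5, 6.5), sharex=True)
    years = result.observed_level.index.to_numpy()
    obs = result.observed_level.mean(axis=1)
    cf = result.y0_level.mean(axis=1)
    ax0.plot(years, obs, color="black", label="observed")
    ax0.plot(years, cf, color="tab:orange", label="counterfactual")
    ax0.axvline(result.treatment_start, color="black", lw=0.8)
    ax0.set_ylabel(f"{pollutant} emissions (tons/yr, mean of treated units)")
    ax0.legend(frameon=False)

    post = result.att_by_year.index.to_numpy()
    att_pct = 100 * (np.exp(result.att_by_year.to_numpy()) - 1)
    ax1.plot(post, att_pct, color="tab:blue", label="ATT")
    if bands is not None:
        lo = 100 * (np.exp(bands.ci_lower.to_numpy()) - 1)
        hi = 100 * (np.exp(bands.ci_upper.to_numpy()) - 1)
        ax1.fill_between(post, lo, hi, alpha=0.25, color="tab:blue",
                         label=f"{bands.level:.0%} CI")
    ax1.axhline(0.0, color="grey", lw=0.8)
    ax1.axvline(result.treatment_start, color="black", lw=0.8)
    ax1.set_xlabel("year")
    ax1.set_ylabel("ATT (%)")
    ax1.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
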