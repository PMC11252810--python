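import numpy as np
import pandas as pd
import pytest

from coben.panel import PanelDataset, log_transform
from coben.simulate import emissions_like_preset, generate


def make_panel_frame(
    n_treated=2,
    n_control=2,
    years=range(2000, 2006),
    treatment_start=2003,
    covariates=(),
    seed=0,
):
    """Small hand-rolled long panel with positive outcomes."""
    rng = np.random.default_rng(seed)
    rows = []
    units = [(f"t{i}", True) for i in range(n_treated)] + [
        (f"c{i}", False) for i in range(n_control)
    ]
    for unit, treated in units:
        for year in years:
            row = {
                "unit": unit,
                "treated": treated,
                "year": year,
                "outcome": float(np.exp(rng.normal(2.0, 0.3))),
            }
            for cov in covariates:
                row[cov] = float(rng.normal())
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def toy_frame():
    return make_panel_frame()


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact generated panel with a known flat effect, shared read-only."""
    spec = emissions_like_preset(
        seed=42, n_treated=6, n_control=10, tau_profile=-0.40
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_log_panel(small_synthetic):
    return log_transform(small_synthetic.panel)
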