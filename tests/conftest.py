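import numpy as np
import pandas as pd
import pytest

from rddmatch import SynthConfig, generate_panel


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete DGP for fast unit tests."""
    return SynthConfig(n_treated=30, n_control_pool=200, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


def make_series(y_by_month: dict[int, float], n_physicians: int = 3) -> pd.DataFrame:
    """Deterministic long series: every physician observes the same y(t)."""
    rows = []
    for i in range(n_physicians):
        for t, y in y_by_month.items():
            rows.append({"physician_id": f"p{i}", "month_index": t, "value": float(y)})
    return pd.DataFrame(rows)


def linear_series(intercept, slope, jump, cutoff, months=range(1, 12),
                  n_physicians=3):
    """Noiseless piecewise-linear outcome with an additive jump at the cutoff."""
    return make_series(
        {t: intercept + slope * (t - cutoff) + (jump if t >= cutoff else 0.0)
         for t in months},
        n_physicians,
    )
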