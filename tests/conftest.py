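import numpy as np
import pandas as pd
import pytest

from sedigrass import BayConfig, generate_bay, run_pipeline


@pytest.fixture(scope="session")
def small_config() -> BayConfig:
    """A fast bay: 3.2 x 6.4 km, 30 stations, 5.5 years of forcing."""
    return BayConfig(n_rows=32, n_cols=64, n_months=66, n_stations=30, seed=7)


@pytest.fixture(scope="session")
def small_grid(small_config):
    return generate_bay(small_config)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline under the default study conditions (13 water years)."""
    return run_pipeline(BayConfig(seed=0))


def make_daily(loads: dict[str, list[float]], start: str = "2000-07-01") -> pd.DataFrame:
    """Build a daily long-format TSS table from per-river load lists."""
    frames = []
    for river, values in loads.items():
        dates = pd.date_range(start, periods=len(values), freq="D")
        frames.append(pd.DataFrame({"date": dates, "river": river,
                                    "tss_tonnes": np.asarray(values, dtype=float)}))
    return pd.concat(frames, ignore_index=True)
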