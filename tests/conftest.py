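import numpy as np
import pandas as pd
import pytest

from biscuit_ema import TruthConfig, build_predictor_matrix, generate_participant


@pytest.fixture(scope="session")
def driver_config():
    """Three strong slider-item drivers, default study design."""
    return TruthConfig(
        item_effects={"item_01": 1.0, "item_05": -0.9, "item_12": 0.8},
        seed=7,
    )


@pytest.fixture(scope="session")
def driver_dataset(driver_config):
    return generate_participant(driver_config)


@pytest.fixture(scope="session")
def driver_matrix(driver_dataset):
    dataset, _ = driver_dataset
    return build_predictor_matrix(dataset)


def make_prompts(binges_by_day, start="2025-03-02", interval=2.5, first_clock=8.0):
    """Minimal prompt frame: binges_by_day is a list of per-day 0/1 lists."""
    rows = []
    t0 = pd.Timestamp(start)
    for d, day_binges in enumerate(binges_by_day):
        for s, b in enumerate(day_binges, start=1):
            rows.append(
                {
                    "timestamp": t0 + pd.Timedelta(days=d, hours=first_clock + (s - 1) * interval),
                    "day": d + 1,
                    "slot": s,
                    "binge": float(b),
                }
            )
    return pd.DataFrame(rows)
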