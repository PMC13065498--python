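import numpy as np
import pandas as pd
import pytest

from windforay import home_range as hr_mod
from windforay import segmentation as seg
from windforay import synthetic as syn


@pytest.fixture(scope="session")
def small_sim():
    """Three individuals over four months — enough structure for recovery."""
    cfg = syn.SimConfig(n_individuals=3, start_date="2021-03-01",
                        end_date="2021-06-30", seed=42)
    return syn.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def segmented_sim(small_sim):
    """Per-individual home ranges, excursion tracks and inside flags."""
    out = {}
    for ind, sub in small_sim.fixes.groupby("individual_id"):
        sub = sub.reset_index(drop=True)
        hr, poly = hr_mod.fit_home_range(sub)
        tracks, inside = seg.segment_individual(sub, poly)
        out[ind] = {"fixes": sub, "hr": hr, "poly": poly,
                    "tracks": tracks, "inside": inside}
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def simple_fixes():
    """Tiny hand-made fix table for I/O tests."""
    t = pd.date_range("2021-05-01 06:00", periods=6, freq="h", tz="UTC")
    return pd.DataFrame(
        {
            "individual_id": ["a"] * 3 + ["b"] * 3,
            "timestamp": list(t[:3]) + list(t[:3]),
            "x_km": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0],
            "y_km": [0.0, 0.5, 1.0, -1.0, -2.0, -3.0],
        }
    )
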