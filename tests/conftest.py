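import numpy as np
import pandas as pd
import pytest

import xenogrowth as xg


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tested_cohort():
    """Three-strain, two-mice-per-strain synthetic testing cohort."""
    return xg.generate_cohort(xg.default_design(seed=101))


@pytest.fixture(scope="session")
def tested_sizes(tested_cohort):
    return xg.measurements_to_sizes(tested_cohort)


@pytest.fixture(scope="session")
def volume_summary(tested_sizes):
    """Per-strain per-day (mean, se) volume summaries of the tested cohort."""
    frames = []
    for strain in ("nsg", "nsgs", "nude"):
        series = xg.GrowthSeries.from_sizes(tested_sizes, strain, "volume")
        frames.append(series.summarize().assign(strain=strain))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def caliper_frame():
    """Minimal valid caliper table with two mice, two days."""
    return pd.DataFrame(
        {
            "mouse_id": ["m1", "m1", "m2", "m2"],
            "strain": ["nsg"] * 4,
            "group": ["tested"] * 4,
            "day": [10, 13, 10, 13],
            "a_cm": [0.2, 0.3, 0.25, 0.35],
            "b_cm": [0.15, 0.25, 0.2, 0.3],
            "c_cm": [0.1, 0.2, 0.15, 0.25],
        }
    )
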