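import numpy as np
import pandas as pd
import pytest

from cartprofiler import datasets
from cartprofiler.io import EventTable


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_cohort():
    return datasets.default_cohort(events_per_sample=1000, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    pops = datasets.default_populations(n_populations=3, seed=11)
    return datasets.generate_event_tables(small_cohort, pops)


@pytest.fixture()
def bimodal_table():
    """Single-channel 60/40 mixture of two well-separated modes."""
    rng = np.random.default_rng(5)
    n = 20_000
    lo = rng.normal(1.0, 0.3, int(0.6 * n))
    hi = rng.normal(6.0, 0.3, n - int(0.6 * n))
    x = np.concatenate([lo, hi])
    rng.shuffle(x)
    return EventTable(values=pd.DataFrame({"CD8": x}), sample_meta={"donor": "d"})


@pytest.fixture(scope="session")
def killing_noise_free():
    params = datasets.KillingParams(
        product="P1", growth_rate=0.01, kill_rate=0.04, round_decay=0.9, noise_log_sd=0.0
    )
    return params, datasets.generate_killing_series(params, ["2:1", "1:1"])
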