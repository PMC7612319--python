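import numpy as np
import pandas as pd
import pytest

import voikit as vk


@pytest.fixture(scope="session")
def example_run():
    """One seeded R=5000 run of the PM2.5-stroke fixture, shared across tests.

    Returns (config, inputs, estimation outputs, decision outputs); the
    decision net benefits reuse the same draws (NB_policy = y - k).
    """
    cfg = vk.HealthModelConfig()
    inputs, y_est = vk.run_example(cfg, R=5000, seed=20, mode="estimation")
    y = y_est.values["cases_averted"].to_numpy()
    nb = vk.OutputDraws("decision", pd.DataFrame(
        {"status_quo": np.zeros(y.size), "policy": y - cfg.k}))
    return cfg, inputs, y_est, nb


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
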