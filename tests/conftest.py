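import numpy as np
import pytest

from gpfusion.synthdata import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_trial():
    """A 60-line, 200-marker, 2-year trial shared across tests."""
    cfg = SimulationConfig(J=60, p=200, h2=0.6, seed=11)
    calls, coded, features, trial = simulate_dataset(cfg)
    return {
        "config": cfg,
        "calls": calls,
        "coded": coded,
        "features": features,
        "records": trial.records,
        "ndvi": trial.ndvi,
        "truth": trial.truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
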