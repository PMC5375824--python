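import numpy as np
import pytest

from leafnir import Mode, plant_outliers, simulate_dataset
from leafnir.pipeline import PipelineConfig, preprocess_mode
from leafnir.synth import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_black_run():
    """One seeded default-condition run shared by the heavier tests.

    720 simulated leaves (black background), 10 planted gross outliers,
    screened and split 600/rest — the study's sample flow.
    """
    cfg = PipelineConfig(seed=1)
    sim = SimulationConfig(mode=Mode.BLACK_BACKGROUND, seed=123)
    raw = simulate_dataset(sim)
    contaminated, planted = plant_outliers(raw, 10, 3.0, np.random.default_rng(7))
    cal, val, record = preprocess_mode(contaminated, cfg, seed=5)
    return {
        "config": cfg,
        "raw": contaminated,
        "planted_ids": planted,
        "cal": cal,
        "val": val,
        "record": record,
    }


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free simulation config: deterministic closed-form spectra."""
    return SimulationConfig(
        noise_additive_sd=0.0, noise_multiplicative_sd=0.0, n_latent_sd=0.0,
        water_content_sd=0.0, structure_sd=0.0, smooth_drift_sd=0.0,
    )
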