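import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230724)


@pytest.fixture(scope="session")
def small_separated_dataset():
    """Well-separated synthetic dataset with full sensor coverage."""
    from sshmm import pipeline, simulate

    cfg = simulate.SimConfig(
        n_trips=6,
        fixes_per_trip=60,
        seed=1,
        sensor_coverage=1.0,
        coverage_mode="per_trip",
        gap_rate=0.0,
        wet_noise=0.0,
        conflict_rate=0.0,
        dive_detect_prob=1.0,
    )
    sim = simulate.simulate_dataset(cfg)
    prep = pipeline.prepare_dataset(sim.tracks, sim.sensors, sim.truth)
    return cfg, sim, prep
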