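import numpy as np
import pytest

from ripplemap.pipeline import RunConfig, run_pipeline
from ripplemap.synthetic import (
    AssemblySpec,
    SessionConfig,
    generate_assembly_spikes,
    make_default_session,
)


def poisson_train(rate_hz: float, duration_s: float, rng) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.random(n) * duration_s)


@pytest.fixture(scope="session")
def default_bundle():
    """The strong-effect planted session (seed 0)."""
    return make_default_session(seed=0)


@pytest.fixture(scope="session")
def default_result(default_bundle):
    """Full pipeline result on the default planted session."""
    return run_pipeline(default_bundle, RunConfig(seed=0))


@pytest.fixture(scope="session")
def planted_two_assemblies():
    """58-unit BLA population with two disjoint planted assemblies
    (gain 8, 0.5 events/s, 20 min), plus its ground truth."""
    cfg = SessionConfig(
        seed=7,
        n_bla=58,
        bla_rate_hz=5.0,
        epoch_durations={"post_sleep": 1200.0},
        assembly_specs=(
            AssemblySpec(members=(3, 7, 12), event_rate_hz=0.5, gain=8.0),
            AssemblySpec(members=(20, 21, 40, 41), event_rate_hz=0.5, gain=8.0),
        ),
    )
    spikes, truths = generate_assembly_spikes(cfg)
    return cfg, spikes, truths
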