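import numpy as np
import pytest

from osmotrace.conductance import PoreGeometry, SolutionConditions
from osmotrace.simulate import (
    COLLISION,
    TRANSLOCATION,
    EventPopulation,
    SimulationConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20151211)


@pytest.fixture
def pore():
    return PoreGeometry(diameter=4.4, effective_thickness=10.0)


@pytest.fixture
def solution():
    return SolutionConditions(conductivity=3.0, voltage_mV=300.0)


def make_config(
    populations=None,
    event_rate=20.0,
    duration=5.0,
    noise_sd=0.02,
    filter_cutoff=None,
    seed=7,
    sampling_rate=500e3,
):
    """Small simulation config used across detector/statistics tests."""
    if populations is None:
        populations = (
            EventPopulation(
                label=TRANSLOCATION,
                weight=1.0,
                blockade_mean=0.44,
                blockade_sd=0.03,
                log10_dwell_mean=-3.7,
                log10_dwell_sd=0.25,
            ),
        )
    return SimulationConfig(
        geometry=PoreGeometry(diameter=1.6, effective_thickness=3.0),
        solution=SolutionConditions(conductivity=3.0, voltage_mV=300.0),
        populations=populations,
        event_rate=event_rate,
        duration=duration,
        sampling_rate=sampling_rate,
        noise_sd=noise_sd,
        filter_cutoff=filter_cutoff,
        seed=seed,
    )


@pytest.fixture
def two_population_config():
    pops = (
        EventPopulation(COLLISION, 0.3, 0.44, 0.04, -3.7, 0.3),
        EventPopulation(TRANSLOCATION, 0.7, 0.63, 0.03, -3.7, 0.25),
    )
    return make_config(populations=pops)
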