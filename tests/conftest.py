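"""Shared fixtures: one attack scenario, its attack-free twin, and a model
calibrated on a time-compressed two-day-equivalent baseline recording."""

import dataclasses

import pytest

from ticguard.pipeline import CalibratedModel, calibrate
from ticguard.simulator import (
    ScenarioConfig,
    TicEpisode,
    simulate,
    simulate_calibration,
)

#: the study scenario: 15 min recording with one strong 5-min attack
ATTACK_START = 420.0
ATTACK_END = 720.0
SCENARIO_SEED = 1


@pytest.fixture(scope="session")
def attack_config() -> ScenarioConfig:
    return ScenarioConfig(
        duration_s=900.0,
        tic_episodes=(TicEpisode(start_s=ATTACK_START, duration_s=300.0),),
        seed=SCENARIO_SEED,
    )


@pytest.fixture(scope="session")
def twin_config(attack_config) -> ScenarioConfig:
    """Same scenario with the attack removed."""
    return dataclasses.replace(attack_config, tic_episodes=())


@pytest.fixture(scope="session")
def attack_sim(attack_config):
    return simulate(attack_config)


@pytest.fixture(scope="session")
def twin_sim(twin_config):
    return simulate(twin_config)


@pytest.fixture(scope="session")
def calibrated(attack_config) -> CalibratedModel:
    stream, tokens = simulate_calibration(attack_config, compress=288.0)
    return calibrate(stream, tokens)
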