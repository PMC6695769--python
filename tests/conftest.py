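"""Shared fixtures: one default synthetic campaign reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from vinespec.chemometrics import CalibrationDataset
from vinespec.pipeline import RunConfig, SimulatedCampaign, build_dataset, \
    simulate_campaign
from vinespec.preprocessing import apply_chain
from vinespec.synthetic import SimConfig, default_endmembers

CAMPAIGN_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig(seed=CAMPAIGN_SEED)


@pytest.fixture(scope="session")
def campaign(default_config) -> SimulatedCampaign:
    return simulate_campaign(default_config)


@pytest.fixture(scope="session")
def dataset(campaign, default_config) -> CalibrationDataset:
    ds, _ = build_dataset(campaign, default_config)
    return ds


@pytest.fixture(scope="session")
def treated_d1w15(dataset, default_config) -> np.ndarray:
    step = float(np.mean(np.diff(default_config.sim.wavelengths)))
    return apply_chain("D1W15", dataset.X, step=step)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def endmembers(sim_config):
    return default_endmembers(sim_config.wavelengths)
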