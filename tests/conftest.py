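"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import feedgp as fg

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> fg.SimulationConfig:
    """Down-scaled intercross: full structure, light marker panel."""
    return fg.SimulationConfig(n_markers=600, n_qtl=120, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> fg.SimulatedDataset:
    return fg.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def qc_traits(small_dataset):
    """Post-QC trait table with derived MBW/FCR/RFI."""
    traits_qc, _ = fg.filter_phenotypes(small_dataset.traits)
    derived, fit = fg.derive_traits(traits_qc)
    return derived, fit


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def tiny_cross_config(**overrides) -> fg.SimulationConfig:
    """Very small intercross for fast mixed-model tests."""
    base = dict(n_f0_males=3, n_f0_females=6, n_f1_males=2, n_f1_females=8,
                n_f2=30, n_markers=80, n_qtl=40, n_planted_outliers=0,
                missing_rate=0.0, fail_fraction=0.0, seed=21)
    base.update(overrides)
    return fg.SimulationConfig(**base)
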