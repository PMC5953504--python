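"""Shared fixtures: small rendered bundles and helper constructors."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from hsafm_cme.config import NoiseParams, SimulationConfig, preset_config
from hsafm_cme.generate import MovieBundle, generate_dataset
from hsafm_cme.studies import IN_FIELD_MOBILITY


def in_field_config(**overrides) -> SimulationConfig:
    """Untreated preset with in-field mobility (trackable rendered movies)."""
    kwargs = dict(n_frames=60, n_events=5, channels=("clathrin",),
                  mobility_cm2_s=dict(IN_FIELD_MOBILITY), seed=0)
    kwargs.update(overrides)
    return preset_config("untreated", **kwargs)


def single_event_config(motion: str, seed: int, **overrides) -> SimulationConfig:
    kwargs = dict(n_frames=56, n_events=1, grid_shape=(96, 96),
                  channels=(), tip_radius_nm=0.0, seed=seed)
    kwargs.update(overrides)
    cfg = in_field_config(**kwargs)
    mix = {"capping": 0.0, "two_step": 0.0, "reopen": 0.0}
    if motion != "plain":
        mix[motion] = 1.0
    return cfg.replace(mixture=dataclasses.replace(cfg.mixture, **mix))


def quiet_noise() -> NoiseParams:
    """Negligible-noise imaging: flat membrane, bright unsaturated spots."""
    return NoiseParams(roughness_nm=0.0, photon_scale=3.0e5,
                       background_photons=20.0, read_noise=0.0)


@pytest.fixture(scope="session")
def small_bundle() -> MovieBundle:
    """One 60-frame full-field movie with 5 CCP events and clathrin."""
    return generate_dataset(in_field_config())


@pytest.fixture(scope="session")
def analyzed_small_bundle(small_bundle):
    from hsafm_cme.pipeline import run_analyze

    return run_analyze(small_bundle)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
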