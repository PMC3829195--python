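"""Shared fixtures: scaled-down synthetic experiments generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import vsdcontext as v


@pytest.fixture(scope="session")
def small_cfg() -> v.SyntheticConfig:
    """Scaled-down default experiment configuration (32 x 64 grid)."""
    return v.SyntheticConfig.small(seed=11)


@pytest.fixture(scope="session")
def noiseless_cfg() -> v.SyntheticConfig:
    """Noise-free configuration for exactness checks (heartbeat kept on)."""
    return v.SyntheticConfig.small(seed=5, noise_sd=0.0, n_trials=2)


@pytest.fixture(scope="session")
def experiment(small_cfg):
    """One full synthetic experiment analysed end to end (noisy, 30 trials)."""
    return v.run_synthetic_experiment(small_cfg)


@pytest.fixture(scope="session")
def noiseless_experiment(noiseless_cfg):
    stacks, truth = v.generate_experiment(noiseless_cfg)
    ds = v.preprocess_experiment(stacks, ys=noiseless_cfg.ys, xs=noiseless_cfg.xs)
    return ds, truth, noiseless_cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def mini_cfg(seed: int, **overrides) -> v.SyntheticConfig:
    """Tiny experiment for replicated Monte-Carlo studies (time-course level)."""
    params = dict(
        ys=24, xs=48, spot_sigma_px=(2.0, 2.0), stim_ms=800.0,
        n_trials=6, mm_per_px=0.2, seed=seed,
    )
    params.update(overrides)
    return v.SyntheticConfig(**params)
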