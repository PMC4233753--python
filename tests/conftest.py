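"""Shared fixtures: small synthetic fixtures generated at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from posturemap import imagery, synthetic


@pytest.fixture(scope="session")
def static_stack():
    """Aligned stack + template from a short static-agent movie."""
    spec = synthetic.AgentSpec(heading=np.zeros(30), noise_sigma=0.01)
    movie, _ = synthetic.synth_movie(spec, T=30, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack = imagery.process_movie(
            movie, imagery.SegmentationParams(min_area=150)
        )
    return stack


@pytest.fixture(scope="session")
def cluster_spectra():
    """Three well-separated synthetic spectral clusters (normalized rows)."""
    rng = np.random.default_rng(7)

    def make(center, n, dim=30):
        base = np.full(dim, 0.01)
        base[center] = 1.0
        base /= base.sum()
        X = base + np.abs(rng.normal(0, 0.005, (n, dim)))
        return X / X.sum(axis=1, keepdims=True)

    n = 100
    X = np.vstack([make(c, n) for c in (3, 15, 27)])
    labels = np.repeat([0, 1, 2], n)
    return X, labels


@pytest.fixture(scope="session")
def state_series():
    """One individual's 6-state Markov limit-cycle series with labels."""
    spec = synthetic.default_state_model(n_states=6, n_modes=6, seed=0)
    series, labels = synthetic.synth_state_timeseries(spec, T=5000, seed=3)
    return spec, series, labels
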