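"""Shared fixtures: synthetic forward models and spike recordings.

Expensive objects (ICA decompositions, simulated recordings) are session
scoped; all randomness is seeded so the suite is reproducible.
"""
import warnings

import numpy as np
import pytest

from megspike import (PipelineConfig, ica_decompose, preprocess,
                      score_components, simulate_forward, simulate_recording)

warnings.filterwarnings("ignore", message=".*FastICA did not converge.*")


@pytest.fixture(scope="session")
def small_fwd():
    """60-sensor, 300-vertex hemispheric forward model."""
    return simulate_forward(60, 300, seed=1)


@pytest.fixture(scope="session")
def spike_recording(small_fwd):
    """5-minute recording with 2 planted spike sources at SNR 6."""
    rec, gt = simulate_recording(small_fwd, n_atoms=2, rate_per_min=4.0,
                                 duration_s=300, snr=6, seed=7)
    return rec, gt


@pytest.fixture(scope="session")
def preprocessed(spike_recording):
    rec, gt = spike_recording
    return preprocess(rec), gt


@pytest.fixture(scope="session")
def scored_components(preprocessed, small_fwd):
    rec, _ = preprocessed
    cs = ica_decompose(rec, n_components=20, seed=0)
    return score_components(cs, small_fwd, PipelineConfig())


@pytest.fixture(scope="session")
def music_fwd():
    """204-sensor, 500-vertex forward model for localization checks."""
    return simulate_forward(204, 500, seed=1)
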