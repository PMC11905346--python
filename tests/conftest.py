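"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

import perturbmap as pm


@pytest.fixture(scope="session")
def small_ac():
    """Small AC-like session with tones, preprocessed and influence-mapped.

    Deliberately modest (10 targets x 30 repeats) so module tests run fast;
    statistical-power checks live in the acceptance suite.
    """
    p = pm.ac_like_params(n_neurons=80, n_targets=10, n_control_targets=3,
                          n_repeats=30, som_fraction=0.15, n_tone_repeats=6,
                          seed=5)
    s = pm.generate_session(p)
    pm.preprocess_session(s, compute_events=True)
    pm.map_influence(s, n_shuffles=300, seed=1)
    return s


@pytest.fixture(scope="session")
def strong_session():
    """High-SNR session: large influence amplitudes so ground-truth
    structure (center/surround, sign consistency) is recoverable even at
    small trial counts."""
    p = pm.GroundTruthParams(
        n_neurons=100, som_fraction=0.12, n_targets=12, n_control_targets=2,
        n_repeats=80, center_amp=15.0, center_sigma=50.0, surround_amp=3.0,
        surround_sigma=150.0, noise_sd=0.03, seed=7)
    s = pm.generate_session(p)
    pm.preprocess_session(s)
    pm.map_influence(s, n_shuffles=400, seed=3)
    return s


@pytest.fixture(scope="session")
def null_mid():
    """Mid-size null session (no off-target effects) for calibration checks."""
    p = pm.GroundTruthParams(n_neurons=60, som_fraction=0.1, n_targets=20,
                             n_control_targets=0, n_repeats=50, seed=9)
    s = pm.generate_null_session(p)
    pm.preprocess_session(s)
    return s


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
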