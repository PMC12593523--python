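"""Shared fixtures: small synthetic cohorts and reusable signals."""

import numpy as np
import pytest

import cardiopyramid as cp


@pytest.fixture(scope="session")
def small_cohort():
    """20+20 subject cohort with the default (study-condition) generator."""
    cfg = cp.SynthConfig(n_positive=20, n_negative=20, seed=7)
    pairs, manifest = cp.generate_cohort(cfg)
    return cfg, pairs, manifest


@pytest.fixture(scope="session")
def clean_ecg_30s():
    """Clean 30-s, 70-bpm ECG with known R peaks (no corruption)."""
    cfg = cp.SynthConfig(seed=11, heart_rate_bpm=(70.0, 0.0), rr_jitter_frac=0.01)
    return cp.generate_ecg(cfg, subject_seed=0, label="negative", duration_s=30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
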