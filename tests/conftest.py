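"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from eegdecoder.channels import STANDARD_19
from eegdecoder.io import ArtifactAnnotations, RawRecording, TrialSet
from eegdecoder.preprocess import PipelineConfig, preprocess_cohort
from eegdecoder.synth import iter_cohort, small_cohort_spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def sine_recording():
    """60-s, 19-channel recording with a 10 Hz sinusoid on every channel."""
    fs = 256.0
    t = np.arange(int(60 * fs)) / fs
    data = np.tile(50.0 * np.sin(2 * np.pi * 10 * t), (19, 1))
    return RawRecording("sine", fs, list(STANDARD_19), data)


@pytest.fixture
def noise_recording(rng):
    fs = 256.0
    data = rng.standard_normal((19, int(300 * fs))) * 20.0
    return RawRecording("noise", fs, list(STANDARD_19), data)


@pytest.fixture
def simple_annotations():
    return ArtifactAnnotations([(10.0, 20.0), (50.0, 55.0)])


@pytest.fixture(scope="session")
def tiny_trialset(rng):
    """Three subjects x 4 trials of white noise (structure tests only)."""
    trials = rng.standard_normal((12, 19, 1280)).astype(np.float32)
    sids = np.repeat(["a", "b", "c"], 4)
    labels = np.repeat(["AD", "CJD", "CNTRL"], 4)
    return TrialSet(trials, sids, labels, 256.0)


@pytest.fixture(scope="session")
def small_cohort_trials():
    """Preprocessed small synthetic cohort (2 subjects/class, 10 trials each),
    shared across tests that exercise learning and evaluation."""
    spec = small_cohort_spec(n_subjects_per_class=2, duration_s=70, master_seed=2025)
    cfg = PipelineConfig(apply_ica=False, trials_per_subject_cap=10)
    return preprocess_cohort(
        ((rec, ann) for _, rec, ann in iter_cohort(spec)), cfg
    )
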