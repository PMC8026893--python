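"""Shared fixtures: scaled-down stimulus designs and noise-free oracles.

Unit tests use a reduced exp1 design (200 reference + 40 tail tones) so each
simulated subject takes a fraction of a second; the full 620-tone design is
exercised where trial counts themselves are under test.
"""

import numpy as np
import pandas as pd
import pytest

from nlrpipe.pipeline import RunConfig
from nlrpipe.preprocess import RoiEpochs
from nlrpipe.stimgen import StimulusConfig, generate_bimodal_exp2
from nlrpipe.synth_eeg import (
    GeneratingDistribution,
    NoiseConfig,
    PopulationParams,
    SubjectParams,
)


@pytest.fixture(scope="session")
def small_exp1_stim() -> StimulusConfig:
    """Reduced exp1 design: 200 reference + 4 x 10 tail tones (40 gaps of 4-6)."""
    return StimulusConfig(experiment="exp1", n_reference=200, n_per_tail=10)


@pytest.fixture(scope="session")
def small_exp1_config(small_exp1_stim) -> RunConfig:
    # a strong programmed effect keeps the tiny 2-subject fixture informative
    return RunConfig(
        experiment="exp1", n_subjects=2, seed=11, n_channels=12, stimulus=small_exp1_stim,
        population=PopulationParams(surprisal_gain_mean_uV=5.0),
    )


@pytest.fixture(scope="session")
def noise_free() -> NoiseConfig:
    return NoiseConfig.silent()


@pytest.fixture(scope="session")
def clean_subject() -> SubjectParams:
    return SubjectParams(subject_id="S00", artifact_rate=0.0)


@pytest.fixture(scope="session")
def narrow_dist() -> GeneratingDistribution:
    return GeneratingDistribution("normal", mean_hz=600.0, sd_hz=30.0)


@pytest.fixture(scope="session")
def exp2_sequence():
    """One full bimodal (pruned) sequence, shared across tests that only read it."""
    return generate_bimodal_exp2(StimulusConfig(experiment="exp2"), seed=101)


def make_roi_epochs(
    data_uv: np.ndarray,
    sfreq_hz: float = 100.0,
    t0_ms: float = -300.0,
    source_set: np.ndarray | None = None,
    frequency_hz: np.ndarray | None = None,
) -> RoiEpochs:
    """Hand-built RoiEpochs for oracle tests (all trials retained)."""
    n_trials, n_times = data_uv.shape
    times = t0_ms + np.arange(n_times) * 1000.0 / sfreq_hz
    events = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "sample": np.zeros(n_trials, dtype=int),
            "onset_s": np.arange(n_trials, dtype=float),
            "frequency_hz": np.full(n_trials, 600.0) if frequency_hz is None else frequency_hz,
            "source_set": np.full(n_trials, "reference", dtype=object)
            if source_set is None
            else source_set,
        }
    )
    return RoiEpochs(
        data_uv=data_uv,
        times_ms=times,
        sfreq_hz=sfreq_hz,
        events=events,
        n_channels_retained=np.full(n_trials, 11),
        retained=np.ones(n_trials, dtype=bool),
    )
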