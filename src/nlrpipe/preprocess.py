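"""Continuous recording -> ROI-averaged epochs.

Fixed stage order (any deviation must be explicit config):
band-pass filter -> segment -> baseline-correct -> resample -> average
reference -> per-channel range rejection -> ROI average.

Defaults follow the acquisition/analysis parameters of the design this
package simulates: 0.3-30 Hz zero-phase 4th-order Butterworth, epochs from
-300 to +1000 ms around tone onset, baseline over [-300, 0) ms, resampling
250 -> 100 Hz, average reference, rejection of channel-trial entries whose
amplitude range exceeds 100 uV, and averaging over the 11 fronto-central ROI
channels with at least 6 retained channels per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidConfigError, PipelineError
from .synth_eeg import ROI_CHANNEL_IDS, ContinuousRecording

logger = logging.getLogger(__name__)

#: preprocessing presets; ``robustness`` mirrors the 0.1-30 Hz / no-downsampling reanalysis
PRESETS = {
    "default": {"low_hz": 0.3, "high_hz": 30.0, "resample_hz": 100.0},
    "robustness": {"low_hz": 0.1, "high_hz": 30.0, "resample_hz": None},
}


@dataclass
class EpochsSet:
    """Trial x channel x time epochs (uV) with a channel-trial rejection mask."""

    data_uv: np.ndarray  # (n_trials, n_channels, n_times)
    times_ms: np.ndarray
    sfreq_hz: float
    channel_ids: tuple[str, ...]
    events: pd.DataFrame  # one row per retained epoch
    mask: np.ndarray  # (n_trials, n_channels) True = retained

    def __post_init__(self) -> None:
        if self.mask.shape != self.data_uv.shape[:2]:
            raise InvalidConfigError("mask shape must be (n_trials, n_channels)")

    @property
    def n_trials(self) -> int:
        return self.data_uv.shape[0]


@dataclass
class RoiEpochs:
    """Trial x time ROI-averaged epochs with per-trial retention bookkeeping."""

    data_uv: np.ndarray  # (n_trials, n_times); NaN where no channel survived
    times_ms: np.ndarray
    sfreq_hz: float
    events: pd.DataFrame
    n_channels_retained: np.ndarray  # per trial
    retained: np.ndarray  # per trial, True if >= min_channels survived

    @property
    def n_trials(self) -> int:
        return self.data_uv.shape[0]

    def sample_index(self, t_ms: float) -> int:
        """Index of the grid sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))


def bandpass_filter(
    recording: ContinuousRecording, low_hz: float = 0.3, high_hz: float = 30.0, order: int = 4
) -> ContinuousRecording:
    """Zero-phase (forward-backward) Butterworth band-pass, channel-wise."""
    nyq = recording.sfreq_hz / 2
    if not (0 < low_hz < high_hz < nyq):
        raise InvalidConfigError(f"invalid band {low_hz}-{high_hz} Hz at fs={recording.sfreq_hz}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.sfreq_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data_uv, axis=1)
    return ContinuousRecording(filtered, recording.sfreq_hz, recording.channel_ids, recording.events)


def segment(
    recording: ContinuousRecording, window_ms: tuple[float, float] = (-300.0, 1000.0)
) -> EpochsSet:
    """Cut one epoch per event; events too close to the record edges are dropped."""
    sfreq = recording.sfreq_hz
    pre = int(round(window_ms[0] / 1000.0 * sfreq))
    post = int(round(window_ms[1] / 1000.0 * sfreq))
    n_times = post - pre + 1
    times_ms = (np.arange(pre, post + 1) / sfreq) * 1000.0
    n_samples = recording.data_uv.shape[1]

    keep_rows, trials = [], []
    for row in recording.events.itertuples(index=False):
        start = int(row.sample) + pre
        if start < 0 or start + n_times > n_samples:
            logger.info("dropping trial %s: epoch window outside recording", row.trial)
            continue
        keep_rows.append(row)
        trials.append(recording.data_uv[:, start : start + n_times])
    if not trials:
        raise PipelineError("no extractable epochs")
    n_dropped = len(recording.events) - len(trials)
    if n_dropped:
        logger.info("segment: dropped %d/%d events at record edges", n_dropped, len(recording.events))
    data = np.stack(trials)  # (n_trials, n_channels, n_times)
    events = pd.DataFrame(keep_rows).reset_index(drop=True)
    mask = np.ones(data.shape[:2], dtype=bool)
    return EpochsSet(data, times_ms, sfreq, recording.channel_ids, events, mask)


def baseline_correct(
    epochs: EpochsSet, baseline_ms: tuple[float, float] = (-300.0, 0.0)
) -> EpochsSet:
    """Subtract the mean over the closed-open pre-stimulus interval [-300, 0) ms."""
    sel = (epochs.times_ms >= baseline_ms[0]) & (epochs.times_ms < baseline_ms[1])
    if not sel.any():
        raise InvalidConfigError("baseline interval not covered by epoch")
    corrected = epochs.data_uv - epochs.data_uv[:, :, sel].mean(axis=2, keepdims=True)
    return replace(epochs, data_uv=corrected)


def resample_epochs(epochs: EpochsSet, target_hz: float = 100.0) -> EpochsSet:
    """Anti-aliased polyphase resampling; the new grid is anchored at the epoch start."""
    if target_hz > epochs.sfreq_hz:
        raise InvalidConfigError("upsampling not supported")
    if target_hz == epochs.sfreq_hz:
        return epochs
    frac = Fraction(target_hz / epochs.sfreq_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data_uv, up, down, axis=2)
    n_times = data.shape[2]
    times_ms = epochs.times_ms[0] + np.arange(n_times) * 1000.0 / target_hz
    return replace(epochs, data_uv=data, times_ms=times_ms, sfreq_hz=float(target_hz))


def average_reference(epochs: EpochsSet) -> EpochsSet:
    """Re-reference every channel to the instantaneous mean over channels."""
    if epochs.data_uv.shape[1] < 2:
        raise InvalidConfigError("average reference needs >= 2 channels")
    data = epochs.data_uv - epochs.data_uv.mean(axis=1, keepdims=True)
    return replace(epochs, data_uv=data)


def reject_high_range(epochs: EpochsSet, threshold_uv: float = 100.0) -> EpochsSet:
    """Mask channel-trial entries whose amplitude range (max - min) exceeds the threshold.

    Rejection is per channel within trial ("exceeding" is strict: a range of
    exactly ``threshold_uv`` is retained).
    """
    if threshold_uv <= 0:
        raise InvalidConfigError("threshold must be positive")
    ranges = epochs.data_uv.max(axis=2) - epochs.data_uv.min(axis=2)
    mask = epochs.mask & (ranges <= threshold_uv)
    n_rej = int((~mask & epochs.mask).sum())
    if n_rej:
        logger.info("reject_high_range: masked %d channel-trial entries", n_rej)
    return replace(epochs, mask=mask)


def rejection_log(epochs: EpochsSet, threshold_uv: float = 100.0) -> pd.DataFrame:
    """Long-format rejection log: trial, channel, range_uv, masked."""
    ranges = epochs.data_uv.max(axis=2) - epochs.data_uv.min(axis=2)
    trials = np.repeat(epochs.events["trial"].to_numpy(), epochs.data_uv.shape[1])
    chans = np.tile(np.array(epochs.channel_ids), epochs.n_trials)
    return pd.DataFrame(
        {
            "trial": trials,
            "channel": chans,
            "range_uv": ranges.ravel(),
            "masked": ~epochs.mask.ravel(),
        }
    )


def roi_average(
    epochs: EpochsSet,
    roi_channel_ids: tuple[str, ...] = ROI_CHANNEL_IDS,
    min_channels: int = 6,
) -> RoiEpochs:
    """Average unmasked ROI channels per trial; flag trials with too few channels.

    A trial whose retained ROI-channel count falls below ``min_channels`` is
    flagged not-retained (its mean, if any channels survive, is still
    computed for inspection but excluded downstream).
    """
    idx = []
    for cid in roi_channel_ids:
        if cid not in epochs.channel_ids:
            raise InvalidConfigError(f"ROI channel {cid!r} missing from epochs")
        idx.append(epochs.channel_ids.index(cid))
    idx = np.array(idx)
    sub = epochs.data_uv[:, idx, :]
    sub_mask = epochs.mask[:, idx]  # (n_trials, n_roi)
    n_retained = sub_mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        weights = sub_mask[:, :, None].astype(float)
        sums = (sub * weights).sum(axis=1)
        data = np.where(n_retained[:, None] > 0, sums / np.maximum(n_retained, 1)[:, None], np.nan)
    retained = n_retained >= min_channels
    n_excluded = int((~retained).sum())
    if n_excluded:
        logger.info("roi_average: %d trials excluded (<%d ROI channels)", n_excluded, min_channels)
    return RoiEpochs(
        data_uv=data,
        times_ms=epochs.times_ms,
        sfreq_hz=epochs.sfreq_hz,
        events=epochs.events,
        n_channels_retained=n_retained,
        retained=retained,
    )


def preprocess_recording(
    recording: ContinuousRecording,
    preset: str = "default",
    window_ms: tuple[float, float] = (-300.0, 1000.0),
    reject_uv: float = 100.0,
    roi_channel_ids: tuple[str, ...] = ROI_CHANNEL_IDS,
    min_channels: int = 6,
) -> RoiEpochs:
    """Run the full fixed-order preprocessing chain on one recording."""
    if preset not in PRESETS:
        raise InvalidConfigError(f"unknown preset {preset!r}")
    p = PRESETS[preset]
    rec = bandpass_filter(recording, p["low_hz"], p["high_hz"])
    epochs = segment(rec, window_ms)
    epochs = baseline_correct(epochs)
    if p["resample_hz"] is not None:
        epochs = resample_epochs(epochs, p["resample_hz"])
    epochs = average_reference(epochs)
    epochs = reject_high_range(epochs, reject_uv)
    return roi_average(epochs, roi_channel_ids, min_channels)
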