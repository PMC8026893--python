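"""Averaged mismatch response (MMR), N1/P2 peak snapping, and participant QC.

The MMR is the difference wave between the averaged ERP of deviant trials
(tail tones, or tail-interval tones in the bimodal design) and frequent
trials (reference or mode-interval tones).  Its most prominent negative (N1)
and positive (P2) peaks gate the single-trial extraction: peak finding is
fully automated here (search windows + local-extremum snapping), with an
SNR rule standing in for visual no-clear-components exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, PipelineError
from .preprocess import RoiEpochs


@dataclass
class ERPWaveform:
    """An averaged ROI waveform on the epoch time grid."""

    times_ms: np.ndarray
    amplitude_uv: np.ndarray
    n_trials: int


@dataclass
class MMRPeaks:
    """N1/P2 peak latencies and amplitudes found on the averaged MMR."""

    t_n1_ms: float
    t_p2_ms: float
    amp_n1_uv: float
    amp_p2_uv: float
    snr: float
    qc_pass: bool
    reason: str = ""


@dataclass
class QCDecision:
    include: bool
    reason: str


def average_erp(roi: RoiEpochs, selection: np.ndarray) -> ERPWaveform:
    """Pointwise mean over the retained trials in ``selection`` (boolean mask)."""
    sel = np.asarray(selection, dtype=bool) & roi.retained
    if not sel.any():
        raise PipelineError("empty trial selection for ERP")
    return ERPWaveform(roi.times_ms, roi.data_uv[sel].mean(axis=0), int(sel.sum()))


def compute_mmr(deviant: ERPWaveform, standard: ERPWaveform) -> ERPWaveform:
    """Deviant minus standard ERP (identical time grids required)."""
    if deviant.times_ms.shape != standard.times_ms.shape or not np.allclose(
        deviant.times_ms, standard.times_ms
    ):
        raise InvalidConfigError("ERP time grids differ")
    return ERPWaveform(
        deviant.times_ms,
        deviant.amplitude_uv - standard.amplitude_uv,
        min(deviant.n_trials, standard.n_trials),
    )


def _local_extrema(y: np.ndarray, kind: str) -> np.ndarray:
    """Indices of interior local minima/maxima; plateau edges snap to the earliest sample."""
    if kind == "min":
        return np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])) + 1
    return np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1


def find_mmr_peaks(
    mmr: ERPWaveform,
    n1_window_ms: tuple[float, float] = (80.0, 200.0),
    p2_window_ms: tuple[float, float] | None = None,
    baseline_ms: tuple[float, float] = (-300.0, 0.0),
    p2_gap_ms: float = 20.0,
    p2_max_ms: float = 300.0,
) -> MMRPeaks:
    """Snap N1 to the deepest local minimum in its window, then P2 to the highest
    local maximum between ``t_N1 + p2_gap_ms`` and ``p2_max_ms``.

    SNR is the peak-to-peak MMR amplitude over the baseline-interval SD.
    If either window contains no interior local extremum, ``qc_pass`` is
    False with the reason recorded.
    """
    t, y = mmr.times_ms, mmr.amplitude_uv
    base = (t >= baseline_ms[0]) & (t < baseline_ms[1])
    noise_sd = float(np.std(y[base])) if base.any() else np.nan

    n1_sel = (t >= n1_window_ms[0]) & (t <= n1_window_ms[1])
    minima = _local_extrema(y, "min")
    minima = minima[n1_sel[minima]]
    if minima.size == 0:
        return MMRPeaks(np.nan, np.nan, np.nan, np.nan, np.nan, False, "no N1 local minimum")
    i_n1 = minima[np.argmin(y[minima])]

    if p2_window_ms is None:
        p2_window_ms = (t[i_n1] + p2_gap_ms, p2_max_ms)
    p2_sel = (t >= p2_window_ms[0]) & (t <= p2_window_ms[1])
    maxima = _local_extrema(y, "max")
    maxima = maxima[p2_sel[maxima]]
    if maxima.size == 0:
        return MMRPeaks(float(t[i_n1]), np.nan, float(y[i_n1]), np.nan, np.nan, False, "no P2 local maximum")
    i_p2 = maxima[np.argmax(y[maxima])]

    amp_n1, amp_p2 = float(y[i_n1]), float(y[i_p2])
    snr = (amp_p2 - amp_n1) / noise_sd if noise_sd > 0 else np.inf
    return MMRPeaks(float(t[i_n1]), float(t[i_p2]), amp_n1, amp_p2, float(snr), True)


def qc_participant(peaks: MMRPeaks, snr_threshold: float = 2.0) -> QCDecision:
    """Include a participant iff peaks were found and SNR >= threshold (boundary inclusive)."""
    if not peaks.qc_pass:
        return QCDecision(False, f"no clear MMR components ({peaks.reason})")
    if not peaks.snr >= snr_threshold:
        return QCDecision(False, f"snr {peaks.snr:.2f} below threshold {snr_threshold}")
    return QCDecision(True, "ok")
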