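"""Tone-sequence generation for the auditory statistical-learning designs.

Two designs are supported:

* **exp1** -- 500 reference tones drawn from a normal distribution (narrow,
  SD 30 Hz, or broad, SD 60 Hz truncated at +/-100 Hz from the mean), with
  four 30-tone "tail" sets at +/-200 and +/-400 Hz from the reference mean
  (SD 10 Hz) interleaved so that 4-6 reference tones separate consecutive
  tail tones and every disjoint block of four tail tones contains each tail
  set exactly once.
* **exp2** -- 500 tones with bimodal pitch, obtained by drawing 50,000 tones
  from each of N(500, 40) and N(700, 40) Hz, shuffling, and iteratively
  removing tones whose frequency jump to the next tone exceeds 80% of the
  current maximum jump; the first 500 survivors are presented.

All tones are 100 ms pure sines with a random 800-1,100 ms offset-to-onset
inter-stimulus interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.stats import gaussian_kde

from .errors import InvalidConfigError, PipelineError

TAIL_LABELS = {-400: "tail_m400", -200: "tail_m200", 200: "tail_p200", 400: "tail_p400"}

#: the four between-subject reference-set variants, cycled round-robin
EXP1_CONDITIONS = (
    {"ref_mean_hz": 600.0, "ref_sd_hz": 30.0, "truncation_hz": None},
    {"ref_mean_hz": 700.0, "ref_sd_hz": 30.0, "truncation_hz": None},
    {"ref_mean_hz": 600.0, "ref_sd_hz": 60.0, "truncation_hz": 100.0},
    {"ref_mean_hz": 700.0, "ref_sd_hz": 60.0, "truncation_hz": 100.0},
)


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of one stimulus sequence.

    Defaults are the study conditions; ``experiment`` selects which fields
    are used.  For ``exp1``, ``n_reference + 4 * n_per_tail`` tones are
    presented (620 by default); for ``exp2``, ``n_output`` tones.
    """

    experiment: str = "exp1"
    ref_mean_hz: float = 600.0
    ref_sd_hz: float = 30.0
    truncation_hz: float | None = None  # +/-100 Hz when ref_sd_hz == 60
    n_reference: int = 500
    tail_offsets_hz: tuple[float, ...] = (-400.0, -200.0, 200.0, 400.0)
    tail_sd_hz: float = 10.0
    n_per_tail: int = 30
    gap_range: tuple[int, int] = (4, 6)
    tone_duration_ms: float = 100.0
    isi_range_ms: tuple[float, float] = (800.0, 1100.0)
    # exp2 (bimodal) parameters
    mode_means_hz: tuple[float, float] = (500.0, 700.0)
    mode_sd_hz: float = 40.0
    n_per_mode: int = 50_000
    prune_fraction: float = 0.8
    n_iterations: int = 1000
    n_output: int = 500
    prune_reading: str = "consecutive"  # or "pairwise"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise InvalidConfigError(f"unknown experiment {self.experiment!r}")
        if self.ref_sd_hz <= 0 or self.tail_sd_hz <= 0 or self.mode_sd_hz <= 0:
            raise InvalidConfigError("standard deviations must be positive")
        if not (0 < self.prune_fraction < 1):
            raise InvalidConfigError("prune_fraction must be in (0, 1)")
        lo, hi = self.gap_range
        if lo > hi or lo < 0:
            raise InvalidConfigError(f"invalid gap_range {self.gap_range}")
        if self.n_per_mode < self.n_output:
            raise InvalidConfigError("n_per_mode must be >= n_output")
        if self.prune_reading not in ("consecutive", "pairwise"):
            raise InvalidConfigError(f"unknown prune_reading {self.prune_reading!r}")

    def with_condition(self, index: int) -> "StimulusConfig":
        """Return a copy set to the ``index``-th (mod 4) exp1 reference variant."""
        return replace(self, **EXP1_CONDITIONS[index % len(EXP1_CONDITIONS)])


@dataclass
class ToneSequence:
    """An ordered, timed sequence of pure-tone events."""

    frequency_hz: np.ndarray
    onset_s: np.ndarray
    duration_ms: np.ndarray
    source_set: np.ndarray  # str labels

    def __post_init__(self) -> None:
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.duration_ms = np.asarray(self.duration_ms, dtype=float)
        self.source_set = np.asarray(self.source_set, dtype=object)
        n = len(self.frequency_hz)
        if not (len(self.onset_s) == len(self.duration_ms) == len(self.source_set) == n):
            raise InvalidConfigError("sequence fields must have equal length")
        if n and np.any(np.diff(self.onset_s) <= 0):
            raise InvalidConfigError("onsets must be strictly increasing")
        if n and np.any(self.frequency_hz <= 0):
            raise InvalidConfigError("frequencies must be positive")

    def __len__(self) -> int:
        return len(self.frequency_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "onset_s": self.onset_s,
                "frequency_hz": self.frequency_hz,
                "duration_ms": self.duration_ms,
                "source_set": self.source_set.astype(str),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ToneSequence":
        df = pd.read_csv(path, sep="\t")
        return cls(
            frequency_hz=df["frequency_hz"].to_numpy(),
            onset_s=df["onset_s"].to_numpy(),
            duration_ms=df["duration_ms"].to_numpy(),
            source_set=df["source_set"].to_numpy(dtype=object),
        )


@dataclass(frozen=True)
class DistributionSummary:
    """Descriptive summary of a frequency set (KDE-based mode structure)."""

    min_hz: float
    max_hz: float
    empirical_sd_hz: float
    mode_locations_hz: tuple[float, ...]
    center_minimum_hz: float | None = None


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_reference_set(
    mean_hz: float,
    sd_hz: float,
    n: int,
    truncation_hz: float | None = None,
    seed=None,
) -> np.ndarray:
    """Draw ``n`` reference-tone frequencies from N(mean, sd).

    If ``truncation_hz`` is given, rejection sampling keeps only draws within
    ``mean +/- truncation_hz`` (the broad, SD-60 sets are truncated at
    +/-100 Hz so that they cannot overlap the tail sets).
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    if sd_hz <= 0:
        raise InvalidConfigError("sd must be positive")
    if truncation_hz is not None and truncation_hz <= 0:
        raise InvalidConfigError("truncation_hz must be positive")
    rng = _rng(seed)
    if truncation_hz is None:
        return rng.normal(mean_hz, sd_hz, n)
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mean_hz, sd_hz, max(2 * (n - out.size), 16))
        keep = np.abs(draw - mean_hz) <= truncation_hz
        out = np.concatenate([out, draw[keep]])
    return out[:n]


def sample_tail_sets(
    ref_mean_hz: float,
    offsets_hz=(-400.0, -200.0, 200.0, 400.0),
    tail_sd_hz: float = 10.0,
    n_per_set: int = 30,
    seed=None,
    ref_halfwidth_hz: float | None = None,
) -> pd.DataFrame:
    """Draw the four equally frequent tail sets.

    Returns a frame with columns ``frequency_hz`` and ``source_set``
    (``n_per_set`` rows per offset).  If ``ref_halfwidth_hz`` is given and a
    tail set's +/-3 SD range intrudes into the reference range, a warning is
    issued: the design's categorical-separation assumption is violated.
    """
    offsets = tuple(float(o) for o in offsets_hz)
    if len(set(offsets)) != len(offsets):
        raise InvalidConfigError("tail offsets must be distinct")
    if n_per_set < 0:
        raise InvalidConfigError("n_per_set must be >= 0")
    rng = _rng(seed)
    rows = []
    for off in offsets:
        label = TAIL_LABELS.get(int(off), f"tail_{'m' if off < 0 else 'p'}{abs(int(off))}")
        if ref_halfwidth_hz is not None and abs(off) - 3 * tail_sd_hz < ref_halfwidth_hz:
            warnings.warn(
                f"tail set at {off:+.0f} Hz (+/-3 SD) overlaps the reference range "
                f"(+/-{ref_halfwidth_hz:.0f} Hz); tail tones are no longer "
                "categorically separated",
                stacklevel=2,
            )
        freqs = rng.normal(ref_mean_hz + off, tail_sd_hz, n_per_set)
        rows.append(pd.DataFrame({"frequency_hz": freqs, "source_set": label}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["frequency_hz", "source_set"]
    )


def _gap_composition(total: int, n_gaps: int, gap_range: tuple[int, int], rng) -> np.ndarray:
    """Random integer composition of ``total`` into ``n_gaps`` parts within gap_range.

    Starts every gap at the minimum and spreads the remaining tones one at a
    time over gaps with spare capacity (balanced-swap construction).
    """
    lo, hi = gap_range
    if not (n_gaps * lo <= total <= n_gaps * hi):
        raise InvalidConfigError(
            f"cannot split {total} reference tones into {n_gaps} gaps of {lo}-{hi}"
        )
    gaps = np.full(n_gaps, lo, dtype=int)
    for _ in range(total - n_gaps * lo):
        capacity = np.flatnonzero(gaps < hi)
        gaps[capacity[rng.integers(len(capacity))]] += 1
    return gaps


def interleave_exp1(
    reference: np.ndarray,
    tails: pd.DataFrame,
    gap_range: tuple[int, int] = (4, 6),
    seed=None,
    tone_duration_ms: float = 100.0,
    isi_range_ms: tuple[float, float] = (800.0, 1100.0),
) -> ToneSequence:
    """Interleave tail tones into the reference stream.

    Tail tones are presented in disjoint blocks of four, each block a random
    permutation of the four tail sets, with 4-6 reference tones before every
    tail tone; the 120 gaps are a random composition summing to all 500
    reference tones (each gap, including the one before the first tail tone,
    lies within ``gap_range``).
    """
    rng = _rng(seed)
    reference = np.asarray(reference, dtype=float)
    labels = tails["source_set"].unique()
    n_sets = len(labels)
    per_set = {lab: tails.loc[tails.source_set == lab, "frequency_hz"].to_numpy() for lab in labels}
    counts = {lab: len(v) for lab, v in per_set.items()}
    if len(set(counts.values())) != 1:
        raise InvalidConfigError("tail sets must be equally sized")
    n_blocks = next(iter(counts.values()))
    n_tail = n_sets * n_blocks

    # block-randomized tail order: each block of n_sets covers every label once
    consumed = {lab: 0 for lab in labels}
    tail_order: list[tuple[float, str]] = []
    for _ in range(n_blocks):
        for lab in rng.permutation(labels):
            tail_order.append((per_set[lab][consumed[lab]], lab))
            consumed[lab] += 1

    gaps = _gap_composition(len(reference), n_tail, gap_range, rng)
    ref_order = rng.permutation(reference)

    freqs: list[float] = []
    labs: list[str] = []
    ref_pos = 0
    for gap, (tail_freq, tail_lab) in zip(gaps, tail_order):
        freqs.extend(ref_order[ref_pos : ref_pos + gap])
        labs.extend(["reference"] * gap)
        ref_pos += gap
        freqs.append(tail_freq)
        labs.append(tail_lab)
    return assign_timing(
        np.array(freqs), np.array(labs, dtype=object), tone_duration_ms, isi_range_ms, rng
    )


def prune_large_jumps(
    frequencies: np.ndarray,
    prune_fraction: float = 0.8,
    n_iterations: int = 1000,
    reading: str = "consecutive",
) -> np.ndarray:
    """Iteratively remove tones that precede an oversized frequency jump.

    On each iteration the maximum jump is recomputed -- under the default
    ``consecutive`` reading, the largest absolute difference between
    neighbouring tones; under ``pairwise``, the overall range (max - min) --
    and every tone whose absolute difference to its successor exceeds
    ``prune_fraction`` times that maximum is removed.
    """
    x = np.asarray(frequencies, dtype=float)
    for _ in range(n_iterations):
        if x.size < 2:
            break
        diffs = np.abs(np.diff(x))
        max_diff = diffs.max() if reading == "consecutive" else x.max() - x.min()
        if max_diff <= 0:
            break
        keep = np.ones(x.size, dtype=bool)
        keep[:-1] = diffs <= prune_fraction * max_diff
        if keep.all():
            break
        x = x[keep]
    return x


def generate_bimodal_exp2(config: StimulusConfig, seed=None) -> ToneSequence:
    """Generate the bimodal (exp2) sequence via the iterative pruning procedure."""
    rng = _rng(config.seed if seed is None else seed)
    draws = np.concatenate(
        [rng.normal(m, config.mode_sd_hz, config.n_per_mode) for m in config.mode_means_hz]
    )
    rng.shuffle(draws)
    survivors = prune_large_jumps(
        draws, config.prune_fraction, config.n_iterations, config.prune_reading
    )
    if survivors.size < config.n_output:
        raise PipelineError(
            f"pruning left {survivors.size} tones, fewer than n_output={config.n_output}"
        )
    freqs = survivors[: config.n_output]
    labels = np.full(config.n_output, "bimodal", dtype=object)
    return assign_timing(freqs, labels, config.tone_duration_ms, config.isi_range_ms, rng)


def assign_timing(
    frequencies: np.ndarray,
    labels: np.ndarray,
    tone_duration_ms: float = 100.0,
    isi_range_ms: tuple[float, float] = (800.0, 1100.0),
    seed=None,
) -> ToneSequence:
    """Assign onsets: onset[i+1] = onset[i] + duration + ISI_i, ISI ~ U(isi_range)."""
    lo, hi = isi_range_ms
    if lo > hi or lo < 0:
        raise InvalidConfigError(f"invalid isi_range_ms {isi_range_ms}")
    rng = _rng(seed)
    n = len(frequencies)
    if n == 0:
        return ToneSequence(np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=object))
    isi_s = rng.uniform(lo, hi, max(n - 1, 0)) / 1000.0
    onsets = np.concatenate([[0.0], np.cumsum(tone_duration_ms / 1000.0 + isi_s)])
    return ToneSequence(
        frequency_hz=np.asarray(frequencies, dtype=float),
        onset_s=onsets,
        duration_ms=np.full(n, tone_duration_ms, dtype=float),
        source_set=np.asarray(labels, dtype=object),
    )


def generate_exp1(config: StimulusConfig, seed=None) -> ToneSequence:
    """Generate a full exp1 sequence (reference + interleaved tail sets)."""
    rng = _rng(config.seed if seed is None else seed)
    ref = sample_reference_set(
        config.ref_mean_hz, config.ref_sd_hz, config.n_reference, config.truncation_hz, rng
    )
    halfwidth = config.truncation_hz if config.truncation_hz is not None else 3 * config.ref_sd_hz
    tails = sample_tail_sets(
        config.ref_mean_hz,
        config.tail_offsets_hz,
        config.tail_sd_hz,
        config.n_per_tail,
        rng,
        ref_halfwidth_hz=halfwidth,
    )
    return interleave_exp1(
        ref, tails, config.gap_range, rng, config.tone_duration_ms, config.isi_range_ms
    )


def generate_sequence(config: StimulusConfig, seed=None) -> ToneSequence:
    """Dispatch on ``config.experiment``."""
    if config.experiment == "exp1":
        return generate_exp1(config, seed)
    return generate_bimodal_exp2(config, seed)


def summarize_distribution(
    frequencies: np.ndarray,
    bandwidth_rule: str = "silverman",
    grid_step_hz: float = 1.0,
    min_rel_height: float = 0.1,
) -> DistributionSummary:
    """Summarize a frequency set: range, SD, KDE modes, and the between-mode minimum.

    Modes are local maxima of a Gaussian KDE evaluated on a ``grid_step_hz``
    grid over [min, max]; maxima below ``min_rel_height`` times the global
    density maximum are discarded as ripple.  When exactly two modes are
    found, the density minimum between them is reported.
    """
    x = np.asarray(frequencies, dtype=float)
    if x.size < 10:
        raise InvalidConfigError("need at least 10 frequencies to summarize")
    kde = gaussian_kde(x, bw_method=bandwidth_rule)
    grid = np.arange(np.floor(x.min()), np.ceil(x.max()) + grid_step_hz, grid_step_hz)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1  # ties: earliest grid point wins
    interior = interior[dens[interior] >= min_rel_height * dens.max()]
    # endpoints can be modes if density is monotone toward them
    modes = [grid[i] for i in interior]
    if dens.size >= 2 and dens[0] > dens[1] and dens[0] >= min_rel_height * dens.max():
        modes.insert(0, grid[0])
    if dens.size >= 2 and dens[-1] > dens[-2] and dens[-1] >= min_rel_height * dens.max():
        modes.append(grid[-1])
    modes = sorted(modes)
    center_min = None
    if len(modes) == 2:
        i0 = int(round((modes[0] - grid[0]) / grid_step_hz))
        i1 = int(round((modes[1] - grid[0]) / grid_step_hz))
        center_min = float(grid[i0 + np.argmin(dens[i0 : i1 + 1])])
    return DistributionSummary(
        min_hz=float(x.min()),
        max_hz=float(x.max()),
        empirical_sd_hz=float(np.std(x, ddof=1)),
        mode_locations_hz=tuple(float(m) for m in modes),
        center_minimum_hz=center_min,
    )


def render_audio(
    sequence: ToneSequence, sample_rate_hz: int = 44_100, ramp_ms: float = 5.0
) -> np.ndarray:
    """Render the sequence as a mono waveform (pure sines, cosine on/off ramps)."""
    if len(sequence) and sample_rate_hz < 2 * sequence.frequency_hz.max():
        raise InvalidConfigError(
            f"sample rate {sample_rate_hz} Hz below Nyquist for "
            f"{sequence.frequency_hz.max():.0f} Hz"
        )
    if len(sequence) == 0:
        return np.zeros(0)
    total_s = sequence.onset_s[-1] + sequence.duration_ms[-1] / 1000.0 + 0.1
    wave = np.zeros(int(np.ceil(total_s * sample_rate_hz)))
    for freq, onset, dur_ms in zip(sequence.frequency_hz, sequence.onset_s, sequence.duration_ms):
        n = int(round(dur_ms / 1000.0 * sample_rate_hz))
        t = np.arange(n) / sample_rate_hz
        tone = np.sin(2 * np.pi * freq * t)
        n_ramp = int(round(ramp_ms / 1000.0 * sample_rate_hz))
        if n_ramp > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            tone[:n_ramp] *= ramp
            tone[-n_ramp:] *= ramp[::-1]
        start = int(round(onset * sample_rate_hz))
        wave[start : start + n] += tone
    return wave


def write_wav(path, wave: np.ndarray, sample_rate_hz: int = 44_100) -> None:
    """Write a waveform as 16-bit PCM WAV (amplitude normalized to 0.9 FS)."""
    peak = np.abs(wave).max() or 1.0
    pcm = np.round(wave / peak * 0.9 * 32767).astype(np.int16)
    wavfile.write(path, sample_rate_hz, pcm)
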