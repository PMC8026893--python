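"""Single-trial Neural Likelihood Response extraction and derived quantities.

The NLR of a trial is the amplitude difference V(t_P2) - V(t_N1) of that
trial's own ROI trace, read at the peak latencies identified on the averaged
mismatch response.  Downstream transforms: frequency z-scores against the
subject's delivered reference tones, per-subject negative normalization, the
fixed 13-center z-binning used for the curve fits, and the five-interval
(tails / modes / center-minimum) trial selection for the bimodal design.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, PipelineError
from .mmr import MMRPeaks
from .preprocess import RoiEpochs
from .stimgen import DistributionSummary, summarize_distribution

logger = logging.getLogger(__name__)

#: the 13 z-bin centers capturing all tail sets and splitting the reference set
DEFAULT_BIN_CENTERS = (
    -13.63, -8.375, -6.75, -4.125, -2.0, -1.0, 0.0, 1.0, 2.0, 4.24, 6.75, 8.5, 13.75,
)

INTERVAL_LABELS = ("left_tail", "left_mode", "center_min", "right_mode", "right_tail")
INTERVAL_RANK = {lab: r for lab, r in zip(INTERVAL_LABELS, (-2, -1, 0, 1, 2))}


def build_trial_table(roi: RoiEpochs, subject_id: str) -> pd.DataFrame:
    """Per-trial records joining stimulus metadata with EEG retention status."""
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial_index": roi.events["trial"].to_numpy(),
            "frequency_hz": roi.events["frequency_hz"].to_numpy(),
            "source_set": roi.events["source_set"].to_numpy(),
            "retained": roi.retained,
        }
    )


def extract_trial_nlr(
    roi: RoiEpochs, peaks: MMRPeaks, table: pd.DataFrame, include: bool = True
) -> pd.DataFrame:
    """Add ``nlr_raw``: V(t_P2) - V(t_N1) read at the nearest grid samples.

    If the participant was excluded (``include=False`` or peaks not found),
    an empty table is returned and the exclusion logged.
    """
    if not include or not peaks.qc_pass:
        logger.info("subject %s excluded: no NLR extracted", table["subject_id"].iloc[0] if len(table) else "?")
        return table.iloc[0:0].assign(nlr_raw=pd.Series(dtype=float))
    i_n1 = roi.sample_index(peaks.t_n1_ms)
    i_p2 = roi.sample_index(peaks.t_p2_ms)
    out = table.copy()
    out["nlr_raw"] = roi.data_uv[:, i_p2] - roi.data_uv[:, i_n1]
    return out


def compute_zscores(table: pd.DataFrame, reference_set: str = "reference") -> pd.DataFrame:
    """z-score all frequencies against the subject's delivered reference tones.

    The mean/SD are empirical, computed from all delivered reference-set
    trials (EEG retention does not change what the ear heard).
    """
    out = []
    for _, sub in table.groupby("subject_id", sort=False):
        ref = sub.loc[sub.source_set == reference_set, "frequency_hz"]
        if len(ref) < 2:
            raise InvalidConfigError("need >= 2 reference trials for z-scoring")
        sd = ref.std(ddof=1)
        if sd == 0:
            raise InvalidConfigError("zero reference SD")
        sub = sub.copy()
        sub["z"] = (sub["frequency_hz"] - ref.mean()) / sd
        sub["abs_z"] = sub["z"].abs()
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def negative_normalize(table: pd.DataFrame, mode: str = "zscore") -> pd.DataFrame:
    """Per-subject negative normalization of the raw NLR.

    ``zscore`` (default): nlr_negnorm = -(nlr_raw - mean) / sd over the
    subject's retained trials, so a bell over frequency means larger
    responses to less likely tones.  Alternatives: ``negate-only`` and
    ``minmax`` (negated min-max to [-1, 0]).
    """
    if mode not in ("zscore", "negate-only", "minmax"):
        raise InvalidConfigError(f"unknown normalization mode {mode!r}")
    out = []
    for _, sub in table.groupby("subject_id", sort=False):
        sub = sub.copy()
        vals = sub.loc[sub.retained, "nlr_raw"]
        if len(vals) < 2:
            raise InvalidConfigError("need >= 2 retained trials to normalize")
        if mode == "zscore":
            sd = vals.std(ddof=1)
            if sd == 0:
                raise InvalidConfigError("zero within-subject NLR variance")
            sub["nlr_negnorm"] = -(sub["nlr_raw"] - vals.mean()) / sd
        elif mode == "negate-only":
            sub["nlr_negnorm"] = -sub["nlr_raw"]
        else:
            span = vals.max() - vals.min()
            if span == 0:
                raise InvalidConfigError("zero within-subject NLR range")
            sub["nlr_negnorm"] = -(sub["nlr_raw"] - vals.min()) / span
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def bin_by_z(
    table: pd.DataFrame,
    centers: tuple[float, ...] = DEFAULT_BIN_CENTERS,
    halfwidth: float = 0.5,
    value_col: str = "nlr_negnorm",
) -> pd.DataFrame:
    """Assign retained trials to the nearest z-bin center within ``halfwidth``
    and return per-subject bin means.

    Trials with no center within ``halfwidth`` are left unbinned and drop out
    of the curve fits.  Returns columns subject, bin_center, n, mean value.
    """
    centers = np.asarray(sorted(centers), dtype=float)
    if np.any(np.diff(centers) < 2 * halfwidth):
        raise InvalidConfigError("bin centers closer than 2 * halfwidth overlap")
    rows = []
    for subject, sub in table.groupby("subject_id", sort=False):
        sub = sub[sub.retained]
        z = sub["z"].to_numpy()
        dist = np.abs(z[:, None] - centers[None, :])
        nearest = np.argmin(dist, axis=1)
        within = dist[np.arange(len(z)), nearest] <= halfwidth
        for j, center in enumerate(centers):
            sel = within & (nearest == j)
            if sel.any():
                rows.append(
                    {
                        "subject_id": subject,
                        "bin_center": center,
                        "n": int(sel.sum()),
                        "mean_negnorm": float(sub[value_col].to_numpy()[sel].mean()),
                    }
                )
    return pd.DataFrame(rows)


def interval_anchors(
    frequencies: np.ndarray, summary: DistributionSummary | None = None
) -> dict[str, float]:
    """The five anchor frequencies of the bimodal design.

    Tails are the delivered min/max; the two modes and the center minimum
    come from the KDE summary of the delivered tones.
    """
    if summary is None:
        summary = summarize_distribution(frequencies)
    if len(summary.mode_locations_hz) != 2 or summary.center_minimum_hz is None:
        raise PipelineError(
            f"cannot resolve interval anchors: {len(summary.mode_locations_hz)} KDE modes found"
        )
    anchors = {
        "left_tail": summary.min_hz,
        "left_mode": summary.mode_locations_hz[0],
        "center_min": summary.center_minimum_hz,
        "right_mode": summary.mode_locations_hz[1],
        "right_tail": summary.max_hz,
    }
    if len(set(anchors.values())) != 5:
        raise PipelineError("degenerate interval anchors (not all distinct)")
    return anchors


def select_intervals_exp2(
    table: pd.DataFrame, k: int = 50, summary: DistributionSummary | None = None
) -> pd.DataFrame:
    """Label, per subject, the k trials closest to each of the five anchors.

    Assignment is globally greedy on |frequency - anchor| so the intervals
    are disjoint and each receives exactly ``k`` distinct trials (nearest
    anchor wins; later candidates backfill intervals that are not yet full).
    """
    out = []
    for subject, sub in table.groupby("subject_id", sort=False):
        freqs = sub["frequency_hz"].to_numpy()
        if len(freqs) < 5 * k:
            raise InvalidConfigError(f"need >= {5 * k} trials, got {len(freqs)}")
        anchors = interval_anchors(freqs, summary)
        labels = np.full(len(freqs), None, dtype=object)
        cands = [
            (abs(freqs[i] - a), i, lab)
            for i in range(len(freqs))
            for lab, a in anchors.items()
        ]
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        fill = {lab: 0 for lab in anchors}
        assigned = 0
        for d, i, lab in cands:
            if labels[i] is None and fill[lab] < k:
                labels[i] = lab
                fill[lab] += 1
                assigned += 1
                if assigned == 5 * k:
                    break
        sub = sub.copy()
        sub["interval_label"] = labels
        sub["interval_rank"] = [INTERVAL_RANK.get(l) if l else None for l in labels]
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def interval_means(table: pd.DataFrame, value_col: str = "nlr_negnorm") -> pd.DataFrame:
    """Per-subject mean response in each of the five intervals (retained trials)."""
    sub = table[table.retained & table.interval_label.notna()]
    g = (
        sub.groupby(["subject_id", "interval_label"], sort=False)[value_col]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_negnorm", "size": "n"})
    )
    g["interval_rank"] = g["interval_label"].map(INTERVAL_RANK)
    return g.sort_values(["subject_id", "interval_rank"]).reset_index(drop=True)
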