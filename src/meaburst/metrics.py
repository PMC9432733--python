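"""Network activity metrics, normalizations and temporal descriptors.

The panel computed per active channel and per protocol phase:

* MBR — mean bursting rate (bursts/min)
* IBI — mean inter-burst interval, measured end-to-next-start (s)
* BD — mean burst duration (s)
* IBSR — intra-burst spike rate: in-burst spikes / in-burst time (spikes/s)
* MSR — out-of-burst spiking rate: spikes outside burst intervals divided
  by the time outside bursts (spikes/s)

Treatment effects are expressed as the fractional variation
``R = M_exposure / M_baseline`` at the pooled-MEA and per-channel level,
cross-channel synchrony as the coefficient of variation of burst-level
metric values, and the spatial footprint of an effect as the normalized
root-mean-square error of per-channel R values around the MEA-level R.

Spike attribution to burst intervals uses closed intervals
``[start, end]`` so the defining last spike of a burst is in-burst and
in-burst + out-of-burst spike counts conserve the total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExperimentPhase, SpikeTrainSet

__all__ = [
    "METRICS",
    "PipelineError",
    "TimeCourse",
    "active_channel_filter",
    "compute_panel",
    "pooled_panel",
    "normalize",
    "pooled_ratio",
    "cv_sync",
    "norm_rmse",
    "time_course",
    "initial_inhibitory_rate",
    "postinhibitory_rebound",
]

METRICS = ["MBR", "IBI", "BD", "IBSR", "MSR"]


class PipelineError(RuntimeError):
    pass


def _in_burst_mask(times: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask of spikes lying inside any [start, end] burst interval."""
    if times.size == 0 or starts.size == 0:
        return np.zeros(times.size, dtype=bool)
    idx = np.searchsorted(starts, times, side="right") - 1
    mask = idx >= 0
    mask[mask] = times[mask] <= ends[idx[mask]]
    return mask


def active_channel_filter(
    trains: SpikeTrainSet,
    burst_table: pd.DataFrame,
    min_rate: float = 0.02,
    min_bursts: int = 2,
) -> list[int]:
    """Channels showing both spiking and bursting activity at baseline.

    A channel is active iff its baseline firing rate is at least
    ``min_rate`` spikes/s and it has at least ``min_bursts`` baseline
    bursts.  Raises :class:`PipelineError` when no channel qualifies.
    """
    t0, t1 = trains.phase_window(ExperimentPhase.BASELINE)
    dur = t1 - t0
    active = []
    for ch in trains.channels:
        t = trains.times[ch]
        n_spk = int(np.sum((t >= t0) & (t < t1)))
        b = burst_table[burst_table["channel"] == ch]
        n_bursts = int(np.sum((b["start_s"] >= t0) & (b["start_s"] < t1)))
        if n_spk / dur >= min_rate and n_bursts >= min_bursts:
            active.append(ch)
    if not active:
        raise PipelineError("no active channel (spiking and bursting) at baseline")
    return active


def compute_panel(
    trains: SpikeTrainSet,
    burst_table: pd.DataFrame,
    phase: ExperimentPhase,
    channels: list[int] | None = None,
) -> pd.DataFrame:
    """Per-channel metric panel for one phase.

    Channels without bursts in the phase get NaN for burst metrics (and
    are excluded from that metric's pooling); IBI needs at least two
    bursts.  Returns a DataFrame indexed by channel with METRICS columns.
    """
    t0, t1 = trains.phase_window(phase)
    window = t1 - t0
    channels = list(channels) if channels is not None else trains.channels
    rows = {}
    for ch in channels:
        t = trains.times[ch]
        t = t[(t >= t0) & (t < t1)]
        b = burst_table[(burst_table["channel"] == ch)
                        & (burst_table["start_s"] >= t0)
                        & (burst_table["start_s"] < t1)].sort_values("start_s")
        starts = b["start_s"].to_numpy()
        ends = np.minimum(b["end_s"].to_numpy(), t1 - 1e-12)
        n_bursts = starts.size
        mbr = n_bursts / (window / 60.0)
        ibi = float(np.mean(starts[1:] - ends[:-1])) if n_bursts >= 2 else np.nan
        bd = float(np.mean(ends - starts)) if n_bursts else np.nan
        mask = _in_burst_mask(t, starts, ends)
        burst_time = float(np.sum(ends - starts))
        ibsr = float(np.sum(mask)) / burst_time if burst_time > 0 else np.nan
        out_time = window - burst_time
        msr = float(np.sum(~mask)) / out_time if out_time > 0 else np.nan
        rows[ch] = [mbr, ibi, bd, ibsr, msr]
    panel = pd.DataFrame.from_dict(rows, orient="index", columns=METRICS)
    panel.index.name = "channel"
    return panel


def pooled_panel(panel: pd.DataFrame) -> pd.Series:
    """MEA-level panel: unweighted mean over channels, NaNs excluded."""
    return panel.mean(axis=0, skipna=True)


def normalize(panel_exposure: pd.DataFrame, panel_baseline: pd.DataFrame) -> pd.DataFrame:
    """Per-channel fractional variation R = M_exposure / M_baseline.

    Channels with a zero or undefined baseline value are flagged NaN and
    thereby excluded from any pooling of R.
    """
    base = panel_baseline.replace(0.0, np.nan)
    return panel_exposure / base


def pooled_ratio(panel_exposure: pd.DataFrame, panel_baseline: pd.DataFrame) -> pd.Series:
    """MEA-level R: ratio of pooled exposure to pooled baseline panels."""
    base = pooled_panel(panel_baseline).replace(0.0, np.nan)
    return pooled_panel(panel_exposure) / base


def cv_sync(
    burst_table: pd.DataFrame,
    trains: SpikeTrainSet,
    phase: ExperimentPhase,
    metric: str,
    channels: list[int] | None = None,
) -> float:
    """Cross-channel synchrony CV (%) of a burst metric in one phase.

    ``100 x mean over channels of the within-channel sd of the burst-level
    metric values, divided by the pooled mean of those values``.  Lower CV
    means tighter cross-channel synchronization.  Metric is one of
    ``IBI``, ``BD``, ``IBSR``; burst-level values are inter-burst gaps,
    durations and per-burst spike rates respectively.
    """
    if metric not in ("IBI", "BD", "IBSR"):
        raise ValueError("cv_sync is defined for IBI, BD and IBSR")
    t0, t1 = trains.phase_window(phase)
    channels = list(channels) if channels is not None else trains.channels
    sds, pooled_values = [], []
    for ch in channels:
        b = burst_table[(burst_table["channel"] == ch)
                        & (burst_table["start_s"] >= t0)
                        & (burst_table["start_s"] < t1)].sort_values("start_s")
        starts = b["start_s"].to_numpy()
        ends = b["end_s"].to_numpy()
        if metric == "IBI":
            vals = starts[1:] - ends[:-1]
        elif metric == "BD":
            vals = ends - starts
        else:
            durs = ends - starts
            vals = b["n_spikes"].to_numpy() / np.where(durs > 0, durs, np.nan)
            vals = vals[np.isfinite(vals)]
        if vals.size >= 2:
            sds.append(float(np.std(vals, ddof=1)))
            pooled_values.append(vals)
    if not sds:
        return np.nan
    pooled_mean = float(np.mean(np.concatenate(pooled_values)))
    if pooled_mean == 0:
        return np.nan
    return 100.0 * float(np.mean(sds)) / pooled_mean


def norm_rmse(channel_values, mea_value: float | None = None) -> float:
    """Normalized RMS deviation of channel-level values from the MEA value.

    ``sqrt(sum_k (Y - y_k)^2 / K) / Y`` — 0 iff every channel equals the
    mean; 0.5 means the mean inter-channel deviation is 50 % of the mean.
    NaN channels are excluded; a zero or undefined MEA value yields NaN.
    """
    y = np.asarray(channel_values, dtype=float)
    y = y[np.isfinite(y)]
    if y.size == 0:
        return np.nan
    Y = float(np.mean(y)) if mea_value is None else float(mea_value)
    if not np.isfinite(Y) or Y == 0:
        return np.nan
    return float(np.sqrt(np.mean((Y - y) ** 2)) / Y)


@dataclass
class TimeCourse:
    """Binned, baseline-normalized rate series over the whole record."""

    bin_edges: np.ndarray          # s, tiling [0, duration]
    rate: np.ndarray               # events/s per bin
    normalized: np.ndarray         # rate / mean baseline rate
    phase_boundaries: tuple[float, float]
    bin_width: float

    def phase_bins(self, phase: ExperimentPhase) -> np.ndarray:
        """Indices of bins lying entirely inside a phase."""
        t1, t2 = self.phase_boundaries
        lo, hi = {
            ExperimentPhase.BASELINE: (0.0, t1),
            ExperimentPhase.EXPOSURE: (t1, t2),
            ExperimentPhase.POST: (t2, self.bin_edges[-1]),
        }[ExperimentPhase(phase)]
        left = self.bin_edges[:-1]
        right = self.bin_edges[1:]
        return np.flatnonzero((left >= lo - 1e-9) & (right <= hi + 1e-9))


def time_course(
    event_times: np.ndarray,
    duration: float,
    phase_boundaries: tuple[float, float],
    bin_width: float = 60.0,
) -> TimeCourse:
    """Event rate over time, normalized to the baseline-phase mean.

    ``event_times`` may be pooled spike times (spiking-rate course) or
    pooled burst onsets (bursting-rate course); 60 s bins give the
    minute-resolution course, 10 s bins the sliding-window trace.
    """
    if duration <= bin_width:
        raise ValueError("record must be longer than one bin")
    n_bins = int(np.ceil(duration / bin_width - 1e-9))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    edges[-1] = max(edges[-1], duration)
    counts, _ = np.histogram(np.asarray(event_times, dtype=float), bins=edges)
    rate = counts / np.diff(edges)
    tc = TimeCourse(edges, rate, rate.copy(), tuple(phase_boundaries), bin_width)
    base = tc.phase_bins(ExperimentPhase.BASELINE)
    base_mean = float(np.mean(rate[base])) if base.size else np.nan
    tc.normalized = rate / base_mean if base_mean and np.isfinite(base_mean) else np.full_like(rate, np.nan)
    return tc


def initial_inhibitory_rate(tc: TimeCourse, n_bins: int = 5) -> float:
    """Initial slope of the normalized course during exposure (fraction/min).

    Ordinary least squares through the first ``n_bins`` exposure bins;
    negative values indicate inhibition.  Requires minute bins for the
    stated per-minute units, but any bin width is converted.
    """
    idx = tc.phase_bins(ExperimentPhase.EXPOSURE)
    if idx.size < n_bins:
        raise ValueError(f"need at least {n_bins} exposure bins")
    idx = idx[:n_bins]
    x = np.arange(n_bins) * (tc.bin_width / 60.0)  # minutes
    y = tc.normalized[idx]
    return float(np.polyfit(x, y, 1)[0])


def postinhibitory_rebound(tc: TimeCourse, n_post: int = 2, n_exposure: int = 5) -> float:
    """Post-inhibitory rebound ratio.

    Maximum of the first ``n_post`` post-exposure bins over the mean of
    the last ``n_exposure`` exposure bins of the normalized course; 1
    means no rate change at washout, values well above the sham level
    indicate rebound excitation.  NaN when the late-exposure mean is 0.
    """
    post = tc.phase_bins(ExperimentPhase.POST)
    exp = tc.phase_bins(ExperimentPhase.EXPOSURE)
    if post.size < n_post or exp.size < n_exposure:
        raise ValueError("not enough post/exposure bins")
    denom = float(np.mean(tc.normalized[exp[-n_exposure:]]))
    if denom == 0 or not np.isfinite(denom):
        return np.nan
    return float(np.max(tc.normalized[post[:n_post]])) / denom
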