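"""Core data model and file formats shared by every analysis stage.

A recording session follows a three-phase protocol (baseline / exposure /
post-exposure).  Raw multichannel voltage lives in :class:`Recording`
(HDF5 on disk, int16 + scale factor), event-level data in
:class:`SpikeTrainSet` (CSV on disk) and detected or ground-truth bursts
in a plain pandas ``DataFrame`` with the :data:`BURST_COLUMNS` schema.

Conventions: all times are seconds, all indices 0-based, analysis windows
are half-open ``[start, end)``.  The one deliberate exception is spike
attribution to burst intervals, which uses closed intervals so that a
burst's defining last spike counts as in-burst (see :mod:`meaburst.metrics`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ExperimentPhase",
    "Recording",
    "SpikeTrainSet",
    "BURST_COLUMNS",
    "FormatError",
    "ValidationError",
    "validate_burst_table",
    "read_recording",
    "write_recording",
    "read_spike_csv",
    "write_spike_csv",
    "read_burst_csv",
    "write_burst_csv",
]

BURST_COLUMNS = ["channel", "start_s", "end_s", "n_spikes", "network_flag"]


class FormatError(ValueError):
    """A file is missing required structure or metadata."""


class ValidationError(ValueError):
    """In-memory data violates a model invariant."""


class ExperimentPhase(str, enum.Enum):
    """The three contiguous recording phases of the exposure protocol."""

    BASELINE = "baseline"
    EXPOSURE = "exposure"
    POST = "post"


@dataclass
class Recording:
    """Multichannel extracellular voltage with protocol annotations.

    Parameters
    ----------
    voltages
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sampling_rate
        Samples per second per channel (the study digitized at 10 kHz).
    phase_boundaries
        ``(t_baseline_end, t_exposure_end)`` in seconds; the record spans
        ``[0, n_samples / sampling_rate)``.
    channel_ids
        Integer channel labels; defaults to ``0..n_channels-1``.
    """

    voltages: np.ndarray
    sampling_rate: float
    phase_boundaries: tuple[float, float]
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 2:
            raise ValidationError("voltages must be 2-D (channels x samples)")
        if not self.channel_ids:
            self.channel_ids = list(range(self.voltages.shape[0]))
        if len(self.channel_ids) != self.voltages.shape[0]:
            raise ValidationError("channel_ids length mismatch")
        t1, t2 = self.phase_boundaries
        if not (0.0 < t1 < t2 < self.duration + 1e-9):
            raise ValidationError(
                "phase boundaries must be strictly increasing and inside the record"
            )

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def duration(self) -> float:
        return self.voltages.shape[1] / self.sampling_rate

    def phase_window(self, phase: ExperimentPhase) -> tuple[float, float]:
        """Half-open ``[t0, t1)`` window of a phase in seconds."""
        t1, t2 = self.phase_boundaries
        return {
            ExperimentPhase.BASELINE: (0.0, t1),
            ExperimentPhase.EXPOSURE: (t1, t2),
            ExperimentPhase.POST: (t2, self.duration),
        }[ExperimentPhase(phase)]


@dataclass
class SpikeTrainSet:
    """Per-channel sorted spike times, optionally with waveform snippets.

    ``times`` maps channel id to a strictly increasing float array of spike
    times (s).  ``snippets`` maps channel id to an ``(n_spikes, 40)`` array
    of microvolt waveforms aligned on the trough (0.8 ms pre / 3.2 ms post
    at 10 kHz); ``labels`` maps channel id to per-spike integer cluster
    labels (-1 = unsorted).
    """

    times: dict[int, np.ndarray]
    duration: float
    phase_boundaries: tuple[float, float] | None = None
    snippets: dict[int, np.ndarray] = field(default_factory=dict)
    labels: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, t in self.times.items():
            t = np.asarray(t, dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                raise ValidationError(f"channel {ch}: spike times not strictly increasing")
            if t.size and (t[0] < 0 or t[-1] >= self.duration + 1e-9):
                raise ValidationError(f"channel {ch}: spike times outside the record")
            self.times[ch] = t
        for ch, s in self.snippets.items():
            if np.asarray(s).ndim != 2 or np.asarray(s).shape[1] != 40:
                raise ValidationError("snippets must have exactly 40 samples")

    @property
    def channels(self) -> list[int]:
        return sorted(self.times)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.times.values()))

    def phase_window(self, phase: ExperimentPhase) -> tuple[float, float]:
        if self.phase_boundaries is None:
            raise ValidationError("spike train set carries no phase boundaries")
        t1, t2 = self.phase_boundaries
        return {
            ExperimentPhase.BASELINE: (0.0, t1),
            ExperimentPhase.EXPOSURE: (t1, t2),
            ExperimentPhase.POST: (t2, self.duration),
        }[ExperimentPhase(phase)]


def validate_burst_table(table: pd.DataFrame, min_spikes: int = 1) -> pd.DataFrame:
    """Check the burst-table schema and its invariants; returns the table.

    Raises :class:`ValidationError` on negative durations, undersized
    bursts, or overlapping intervals within a channel.
    """
    missing = [c for c in BURST_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"burst table missing columns: {missing}")
    if len(table) == 0:
        return table
    if (table["end_s"] <= table["start_s"]).any():
        raise ValidationError("burst end must exceed start")
    if (table["n_spikes"] < min_spikes).any():
        raise ValidationError(f"bursts must contain >= {min_spikes} spikes")
    for _, grp in table.groupby("channel"):
        g = grp.sort_values("start_s")
        if (g["start_s"].to_numpy()[1:] < g["end_s"].to_numpy()[:-1]).any():
            raise ValidationError("bursts overlap within a channel")
    return table


# ---------------------------------------------------------------------------
# HDF5 recordings
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path, scale_uv_per_lsb: float | None = None) -> None:
    """Write a recording as HDF5: one int16 dataset per channel.

    Voltages are quantized with a per-file microvolt-per-LSB scale factor
    (default: chosen so the largest absolute sample maps near full range).
    """
    if scale_uv_per_lsb is None:
        vmax = float(np.max(np.abs(recording.voltages))) if recording.voltages.size else 0.0
        scale_uv_per_lsb = max(vmax / 32000.0, 1e-6)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate_hz"] = float(recording.sampling_rate)
        f.attrs["phase_boundaries_s"] = np.asarray(recording.phase_boundaries, dtype=float)
        f.attrs["scale_uv_per_lsb"] = float(scale_uv_per_lsb)
        grp = f.create_group("channels")
        for cid, row in zip(recording.channel_ids, recording.voltages):
            q = np.clip(np.round(row / scale_uv_per_lsb), -32768, 32767).astype(np.int16)
            grp.create_dataset(f"ch{cid:03d}", data=q)


def read_recording(path) -> Recording:
    """Read an HDF5 recording written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        for key in ("sampling_rate_hz", "phase_boundaries_s", "scale_uv_per_lsb"):
            if key not in f.attrs:
                raise FormatError(f"recording file missing attribute '{key}'")
        fs = float(f.attrs["sampling_rate_hz"])
        bounds = tuple(np.asarray(f.attrs["phase_boundaries_s"], dtype=float))
        scale = float(f.attrs["scale_uv_per_lsb"])
        if "channels" not in f:
            raise FormatError("recording file missing 'channels' group")
        names = sorted(f["channels"])
        ids = [int(name[2:]) for name in names]
        volts = np.stack([f["channels"][name][...].astype(float) * scale for name in names])
    return Recording(volts, fs, (bounds[0], bounds[1]), channel_ids=ids)


# ---------------------------------------------------------------------------
# CSV spike trains and burst tables
# ---------------------------------------------------------------------------

def write_spike_csv(trains: SpikeTrainSet, path) -> None:
    """Write spike times as CSV with columns ``channel,time_s`` (0.1 ms precision)."""
    rows = [
        pd.DataFrame({"channel": ch, "time_s": trains.times[ch]})
        for ch in trains.channels
        if trains.times[ch].size
    ]
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["channel", "time_s"])
    )
    df.to_csv(path, index=False, float_format="%.4f")


def read_spike_csv(path, duration: float | None = None,
                   phase_boundaries: tuple[float, float] | None = None) -> SpikeTrainSet:
    """Read a ``channel,time_s`` CSV back into a :class:`SpikeTrainSet`."""
    df = pd.read_csv(path)
    for col in ("channel", "time_s"):
        if col not in df.columns:
            raise FormatError(f"spike CSV missing column '{col}'")
    times = {
        int(ch): grp["time_s"].to_numpy(dtype=float)
        for ch, grp in df.groupby("channel")
    }
    for ch, t in times.items():
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError(f"channel {ch}: unsorted or duplicate spike times")
    if duration is None:
        duration = float(df["time_s"].max()) + 1e-4 if len(df) else 0.0
    return SpikeTrainSet(times, duration=duration, phase_boundaries=phase_boundaries)


def write_burst_csv(table: pd.DataFrame, path) -> None:
    table[BURST_COLUMNS].to_csv(path, index=False, float_format="%.4f")


def read_burst_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_burst_table(df)
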