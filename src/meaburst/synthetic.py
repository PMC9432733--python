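"""Synthetic MEA activity generator.

Emulates the statistical structure of spontaneous activity in mature
cortical cultures on a 60-channel MEA under a baseline / exposure /
post-exposure protocol, so that every downstream stage (spike detection,
burst detection, metric panel, waveform analysis, dose-response, group
statistics) can be exercised and validated without recorded data.

The activity model is doubly stochastic: network-wide burst events are
drawn from a gamma-renewal point process (shape ``burst_regularity``
controls the regularity of collective bursting; mature cultures burst
fairly regularly), each event recruits each channel with probability
``burst_participation`` with a small Gaussian onset jitter, channels add
isolated (single-channel) bursts so that network bursts make up roughly
60-80 % of all bursts, burst spikes are a flat-rate Poisson over a
log-normal burst duration, and tonic out-of-burst spiking is a Poisson
background.  Treatments are expressed as :class:`EffectPreset`
multipliers applied during the exposure phase with an exponential onset
transition, an exponential post-exposure recovery and, for the
muscimol-like preset, a short multiplicative rebound of network bursting
after washout.

All randomness flows from one integer seed; per-channel substreams are
derived deterministically from ``(seed, channel)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SpikeTrainSet, validate_burst_table

__all__ = [
    "ProtocolSpec",
    "NetworkActivityModel",
    "EffectPreset",
    "WaveformTemplate",
    "WaveformTemplateBank",
    "ProtocolError",
    "builtin_presets",
    "generate_spike_trains",
    "render_raw_recording",
    "burst_rate_multiplier",
    "background_rate_multiplier",
    "agonist_dose_panel",
    "sar_dose_panel",
    "MU_DOSES_UM",
    "MU_DOSE_REPLICATES",
    "SAR_DOSES_WKG",
    "SAR_DOSE_REPLICATES",
    "MU_IC50_UM",
    "SAR_HALF_EFFECT_WKG",
]


class ProtocolError(ValueError):
    """Invalid protocol, model or preset parameters."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Recording protocol: 30 min baseline, 15 min exposure, 45 min post,
    60 channels digitized at 10 kHz."""

    baseline_duration: float = 1800.0
    exposure_duration: float = 900.0
    post_duration: float = 2700.0
    n_channels: int = 60
    sampling_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if min(self.baseline_duration, self.exposure_duration, self.post_duration) <= 0:
            raise ProtocolError("all phase durations must be positive")
        if self.n_channels < 1:
            raise ProtocolError("need at least one channel")
        if self.sampling_rate <= 0:
            raise ProtocolError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.baseline_duration + self.exposure_duration + self.post_duration

    @property
    def phase_boundaries(self) -> tuple[float, float]:
        return (
            self.baseline_duration,
            self.baseline_duration + self.exposure_duration,
        )


@dataclass(frozen=True)
class NetworkActivityModel:
    """Parameters of spontaneous network activity at baseline.

    Defaults describe a mature, network-burst-dominated culture:
    ~12 network bursts/min recruiting 80 % of channels, isolated bursts
    making up 30 % of each channel's bursts (network bursts thus 60-80 %
    of the total), ~80 spikes/s inside bursts of ~0.3 s, and ~2 spikes/s
    of tonic background activity.
    """

    network_burst_rate: float = 12.0          # events / min
    burst_participation: float = 0.8          # probability per channel
    intra_burst_rate: float = 80.0            # spikes / s within a burst
    burst_duration_mean: float = 0.3          # s
    burst_duration_cv: float = 0.3
    isolated_burst_fraction: float = 0.3      # fraction of a channel's bursts
    background_rate: float = 2.0              # spikes / s outside bursts
    channel_rate_heterogeneity: float = 0.2   # CV of per-channel rate multipliers
    burst_regularity: float = 4.0             # gamma shape of the event process
    onset_jitter_sd: float = 0.020            # s, cross-channel burst-onset jitter

    def __post_init__(self) -> None:
        if not (0.0 < self.burst_participation <= 1.0):
            raise ProtocolError("burst_participation must be in (0, 1]")
        if not (0.0 <= self.isolated_burst_fraction < 1.0):
            raise ProtocolError("isolated_burst_fraction must be in [0, 1)")
        for name in ("network_burst_rate", "intra_burst_rate", "burst_duration_mean",
                     "background_rate", "burst_regularity"):
            if getattr(self, name) < 0:
                raise ProtocolError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EffectPreset:
    """Mechanistic description of one treatment's effect during exposure.

    All ``*_scale`` fields multiply the corresponding baseline model
    parameter while the exposure is on, with an exponential transition of
    time constant ``onset_time_constant`` at exposure onset and an
    exponential return to baseline with ``recovery_time_constant`` after
    exposure ends.  ``jitter_scale`` desynchronizes collective bursting:
    it scales the cross-channel burst-onset jitter and divides the
    gamma-renewal regularity of the network event process by its square,
    so a jitter_scale of 2 turns regular bursting Poisson-irregular.
    ``rebound`` adds a multiplicative boost of ``rebound_magnitude`` to
    the (recovering) network burst rate for ``rebound_duration`` seconds
    after exposure offset.
    """

    name: str
    burst_rate_scale: float = 1.0
    background_rate_scale: float = 1.0
    burst_duration_scale: float = 1.0
    intra_burst_rate_scale: float = 1.0
    jitter_scale: float = 1.0
    rebound: bool = False
    rebound_magnitude: float = 1.0
    rebound_duration: float = 60.0
    ap_halfwidth_scale: float = 1.0
    onset_time_constant: float = 30.0
    recovery_time_constant: float = 300.0

    def __post_init__(self) -> None:
        for name in ("burst_rate_scale", "background_rate_scale", "burst_duration_scale",
                     "intra_burst_rate_scale", "jitter_scale", "rebound_magnitude",
                     "ap_halfwidth_scale"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be positive")
        if self.rebound_duration > 120.0:
            raise ProtocolError("rebound_duration must be <= 120 s")


def builtin_presets() -> dict[str, EffectPreset]:
    """The three study arms as generator presets.

    The RF-like and muscimol-like multipliers are calibration defaults
    chosen in closed form so that the *measured* pipeline output (after
    burst detection and the exposure/baseline normalization, including
    the 30 s onset transition) reproduces the study-scale effect sizes:
    ~35 % / ~57 % MBR reduction and ~14 % / ~58 % out-of-burst MSR
    reduction for RF-like / muscimol-like arms.  Muscimol-like adds a
    post-washout rebound of network bursting and a stronger
    desynchronization; both active arms narrow the AP waveform to 93 %
    of its baseline width.
    """
    return {
        "sham": EffectPreset(name="sham"),
        "rf": EffectPreset(
            name="rf",
            burst_rate_scale=0.64,
            background_rate_scale=0.855,
            burst_duration_scale=0.85,
            intra_burst_rate_scale=1.0,
            jitter_scale=1.1,
            rebound=False,
            ap_halfwidth_scale=0.93,
        ),
        "mu": EffectPreset(
            name="mu",
            burst_rate_scale=0.41,
            background_rate_scale=0.40,
            burst_duration_scale=0.70,
            intra_burst_rate_scale=1.1,
            jitter_scale=2.0,
            rebound=True,
            rebound_magnitude=2.0,
            rebound_duration=60.0,
            ap_halfwidth_scale=0.93,
        ),
    }


# ---------------------------------------------------------------------------
# Time-varying rate profiles
# ---------------------------------------------------------------------------

def _scale_profile(t: np.ndarray, protocol: ProtocolSpec, preset: EffectPreset,
                   scale: float, rebound: bool) -> np.ndarray:
    """Multiplier m(t) for one scaled rate: exponential transition into the
    scaled regime at exposure onset, exponential recovery after offset,
    optional rebound boost right after offset."""
    t = np.asarray(t, dtype=float)
    t1, t2 = protocol.phase_boundaries
    tau_on = preset.onset_time_constant
    tau_off = preset.recovery_time_constant
    m = np.ones_like(t)
    in_exp = (t >= t1) & (t < t2)
    m[in_exp] = scale + (1.0 - scale) * np.exp(-(t[in_exp] - t1) / tau_on)
    # level actually reached at the end of exposure
    m_end = scale + (1.0 - scale) * np.exp(-(t2 - t1) / tau_on)
    in_post = t >= t2
    m[in_post] = 1.0 + (m_end - 1.0) * np.exp(-(t[in_post] - t2) / tau_off)
    if rebound and preset.rebound and preset.rebound_magnitude != 1.0:
        boost = in_post & (t < t2 + preset.rebound_duration)
        m[boost] *= preset.rebound_magnitude
    return m


def burst_rate_multiplier(t, protocol: ProtocolSpec, preset: EffectPreset) -> np.ndarray:
    """Multiplier on the burst event rate (network and isolated) at time t."""
    return _scale_profile(t, protocol, preset, preset.burst_rate_scale, rebound=True)


def background_rate_multiplier(t, protocol: ProtocolSpec, preset: EffectPreset) -> np.ndarray:
    """Multiplier on the tonic out-of-burst spike rate at time t (no rebound:
    washout rebound is a property of collective bursting only)."""
    return _scale_profile(t, protocol, preset, preset.background_rate_scale, rebound=False)


def _instant_scale(t: np.ndarray, protocol: ProtocolSpec, preset: EffectPreset,
                   scale: float) -> np.ndarray:
    """Per-event multiplier (durations, intra-burst rate): scaled while the
    exposure is on, with the same onset transition, back to 1 afterwards."""
    return _scale_profile(t, protocol, preset, scale, rebound=False)


# ---------------------------------------------------------------------------
# Point-process sampling via time rescaling
# ---------------------------------------------------------------------------

_GRID_DT = 0.25  # s; resolution of the cumulative-rate grid


def _cumulative_rate(t0: float, t1: float, rate_fn) -> tuple[np.ndarray, np.ndarray]:
    n = max(int(np.ceil((t1 - t0) / _GRID_DT)), 2)
    grid = np.linspace(t0, t1, n + 1)
    rates = np.asarray(rate_fn(grid), dtype=float)
    cum = np.concatenate([[0.0], np.cumsum((rates[1:] + rates[:-1]) / 2.0 * np.diff(grid))])
    return grid, cum


def _sample_renewal(rng: np.random.Generator, t0: float, t1: float, rate_fn,
                    shape: float) -> np.ndarray:
    """Sample an inhomogeneous renewal process on [t0, t1) by time rescaling.

    In operational time (integrated rate) the process is a renewal process
    with gamma inter-event intervals of the given shape and unit mean;
    shape 1 recovers an inhomogeneous Poisson process.
    """
    grid, cum = _cumulative_rate(t0, t1, rate_fn)
    total = cum[-1]
    if total <= 0:
        return np.empty(0)
    n_max = int(total + 10.0 * np.sqrt(total / max(shape, 0.25)) + 20)
    isis = rng.gamma(shape, 1.0 / shape, size=n_max)
    # random start phase so the first event is not anchored at t0
    ops = np.cumsum(isis) - rng.uniform(0.0, isis[0] + 1e-12)
    ops = ops[(ops > 0) & (ops < total)]
    while isis.size and ops.size and np.cumsum(isis)[-1] < total:  # pragma: no cover
        extra = rng.gamma(shape, 1.0 / shape, size=n_max)
        isis = np.concatenate([isis, extra])
        ops = np.cumsum(isis) - isis[0] / 2.0
        ops = ops[(ops > 0) & (ops < total)]
    return np.interp(ops, cum, grid)


def _sample_poisson(rng: np.random.Generator, t0: float, t1: float, rate_fn) -> np.ndarray:
    """Inhomogeneous Poisson sample on [t0, t1) via the rescaling theorem."""
    grid, cum = _cumulative_rate(t0, t1, rate_fn)
    total = cum[-1]
    if total <= 0:
        return np.empty(0)
    n = rng.poisson(total)
    ops = np.sort(rng.uniform(0.0, total, size=n))
    return np.interp(ops, cum, grid)


# ---------------------------------------------------------------------------
# Spike-train generation
# ---------------------------------------------------------------------------

def _network_event_times(protocol: ProtocolSpec, model: NetworkActivityModel,
                         preset: EffectPreset, rng: np.random.Generator) -> np.ndarray:
    """Network burst event times over the whole record; the renewal shape is
    reduced (more irregular) during exposure for desynchronizing presets."""
    lam0 = model.network_burst_rate / 60.0
    t1, t2 = protocol.phase_boundaries
    windows = [(0.0, t1, model.burst_regularity),
               (t1, t2, model.burst_regularity / preset.jitter_scale ** 2),
               (t2, protocol.duration, model.burst_regularity)]
    parts = []
    for w0, w1, shape in windows:
        rate_fn = lambda t: lam0 * burst_rate_multiplier(t, protocol, preset)
        parts.append(_sample_renewal(rng, w0, w1, rate_fn, max(shape, 0.25)))
    return np.concatenate(parts)


def generate_spike_trains(
    protocol: ProtocolSpec,
    model: NetworkActivityModel,
    preset: EffectPreset,
    seed: int,
) -> tuple[SpikeTrainSet, pd.DataFrame]:
    """Generate per-channel spike trains plus the ground-truth burst table.

    Returns
    -------
    trains : SpikeTrainSet
        Sorted spike times per channel with the protocol's phase boundaries.
    truth : pandas.DataFrame
        Ground-truth bursts (``channel, start_s, end_s, n_spikes,
        network_flag``); overlapping generated bursts are merged per channel.
    """
    if protocol.n_channels < 1 or protocol.duration <= 0:
        raise ProtocolError("protocol must have channels and positive duration")
    T = protocol.duration
    t1, t2 = protocol.phase_boundaries
    net_rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    events = _network_event_times(protocol, model, preset, net_rng)

    lam_net_ch = model.network_burst_rate / 60.0 * model.burst_participation
    f_iso = model.isolated_burst_fraction
    lam_iso = lam_net_ch * f_iso / (1.0 - f_iso) if f_iso > 0 else 0.0

    het_sigma = np.sqrt(np.log1p(model.channel_rate_heterogeneity ** 2))
    times: dict[int, np.ndarray] = {}
    truth_rows: list[pd.DataFrame] = []
    for ch in range(protocol.n_channels):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), ch + 1]))
        het = float(np.exp(rng.normal(-het_sigma ** 2 / 2.0, het_sigma)))

        recruited = events[rng.random(events.size) < model.burst_participation]
        in_exp = (recruited >= t1) & (recruited < t2)
        jit_sd = np.where(in_exp, model.onset_jitter_sd * preset.jitter_scale,
                          model.onset_jitter_sd)
        onsets_net = np.clip(recruited + rng.normal(0.0, 1.0, recruited.size) * jit_sd,
                             0.0, T - 1e-6)
        onsets_iso = _sample_poisson(
            rng, 0.0, T,
            lambda t: lam_iso * burst_rate_multiplier(t, protocol, preset))
        onsets = np.concatenate([onsets_net, onsets_iso])
        flags = np.concatenate([np.ones(onsets_net.size, bool), np.zeros(onsets_iso.size, bool)])
        order = np.argsort(onsets, kind="stable")
        onsets, flags = onsets[order], flags[order]

        dur_scale = _instant_scale(onsets, protocol, preset, preset.burst_duration_scale)
        cv = model.burst_duration_cv
        sig = np.sqrt(np.log1p(cv ** 2))
        durs = (model.burst_duration_mean * dur_scale
                * np.exp(rng.normal(-sig ** 2 / 2.0, sig, onsets.size)))
        rate_scale = _instant_scale(onsets, protocol, preset, preset.intra_burst_rate_scale)
        counts = rng.poisson(model.intra_burst_rate * het * rate_scale * durs)

        keep = counts >= 1
        onsets, durs, counts, flags = onsets[keep], durs[keep], counts[keep], flags[keep]
        ends = np.minimum(onsets + durs, T - 1e-6)

        n_burst_spikes = int(counts.sum())
        burst_spikes = (np.repeat(onsets, counts)
                        + rng.uniform(0.0, 1.0, n_burst_spikes) * np.repeat(ends - onsets, counts))
        bg = _sample_poisson(
            rng, 0.0, T,
            lambda t: model.background_rate * het
            * background_rate_multiplier(t, protocol, preset))
        all_spikes = np.unique(np.concatenate([burst_spikes, bg]))
        all_spikes = all_spikes[(all_spikes >= 0) & (all_spikes < T)]
        times[ch] = all_spikes

        truth_rows.append(_merged_truth(ch, onsets, ends, counts, flags))

    truth = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(columns=["channel", "start_s", "end_s", "n_spikes", "network_flag"])
    )
    trains = SpikeTrainSet(times, duration=T, phase_boundaries=(t1, t2))
    return trains, validate_burst_table(truth)


def _merged_truth(ch: int, starts: np.ndarray, ends: np.ndarray,
                  counts: np.ndarray, flags: np.ndarray) -> pd.DataFrame:
    """Merge overlapping generated bursts so truth intervals never overlap."""
    if starts.size == 0:
        return pd.DataFrame(columns=["channel", "start_s", "end_s", "n_spikes", "network_flag"])
    m_start, m_end, m_count, m_flag = [starts[0]], [ends[0]], [int(counts[0])], [bool(flags[0])]
    for i in range(1, starts.size):
        if starts[i] < m_end[-1]:
            m_end[-1] = max(m_end[-1], ends[i])
            m_count[-1] += int(counts[i])
            m_flag[-1] = m_flag[-1] or bool(flags[i])
        else:
            m_start.append(starts[i]); m_end.append(ends[i])
            m_count.append(int(counts[i])); m_flag.append(bool(flags[i]))
    return pd.DataFrame({
        "channel": ch, "start_s": m_start, "end_s": m_end,
        "n_spikes": m_count, "network_flag": m_flag,
    })


# ---------------------------------------------------------------------------
# Waveform-level rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformTemplate:
    """Biphasic extracellular AP template: a negative (inverted) Gaussian
    trough followed by a slower positive after-wave."""

    trough_amplitude: float          # μV, magnitude of the negative trough
    trough_fwhm_ms: float = 0.35     # full width at half maximum of the trough
    peak_amplitude: float = 15.0     # μV, positive after-wave
    abundance: float = 1.0           # relative fraction of the channel's spikes
    class_hint: str = "MAJ"

    def render(self, sampling_rate: float, width_scale: float = 1.0,
               n_samples: int = 40, trough_index: int = 8) -> np.ndarray:
        """Sampled waveform with the trough at ``trough_index``; width_scale
        stretches both lobes in time, amplitudes unchanged."""
        if n_samples / sampling_rate > 0.004 + 1e-12:
            raise ProtocolError("template longer than 4 ms is incompatible with the snippet window")
        t = (np.arange(n_samples) - trough_index) / sampling_rate * 1e3  # ms
        sd = self.trough_fwhm_ms / 2.3548200450309493 * width_scale
        wave = -self.trough_amplitude * np.exp(-0.5 * (t / sd) ** 2)
        sd_p = 2.0 * sd
        wave += self.peak_amplitude * np.exp(-0.5 * ((t - 0.8 * width_scale) / sd_p) ** 2)
        return wave


@dataclass
class WaveformTemplateBank:
    """Per-channel AP templates plus the channel noise level (μV)."""

    templates: dict[int, list[WaveformTemplate]]
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        for ch, tmpls in self.templates.items():
            total = sum(t.abundance for t in tmpls)
            if not np.isclose(total, 1.0):
                raise ProtocolError(f"channel {ch}: template abundances must sum to 1")

    @classmethod
    def default(cls, channels, noise_sd: float = 3.0) -> "WaveformTemplateBank":
        """Two detectable units per channel: a dominant (MAJ-like) and a
        smaller auxiliary template, both well above 5x the noise floor."""
        tmpls = {
            int(ch): [
                WaveformTemplate(60.0, 0.35, 18.0, abundance=0.7, class_hint="MAJ"),
                WaveformTemplate(35.0, 0.30, 10.0, abundance=0.3, class_hint="AUX"),
            ]
            for ch in channels
        }
        return cls(tmpls, noise_sd=noise_sd)


def render_raw_recording(
    trains: SpikeTrainSet,
    bank: WaveformTemplateBank,
    protocol: ProtocolSpec,
    preset: EffectPreset,
    seed: int,
):
    """Render event-level spike trains into raw multichannel voltage.

    Gaussian noise at ``bank.noise_sd`` plus, at every spike time, one
    template drawn by abundance.  For spikes inside the exposure phase the
    template width is multiplied by ``preset.ap_halfwidth_scale`` with
    amplitudes unchanged.  Returns the ground-truth template index per
    spike alongside the recording (for sorter validation).
    """
    from .io import Recording  # local import to avoid cycle at module load

    fs = protocol.sampling_rate
    n_samples = int(round(trains.duration * fs))
    t1, t2 = protocol.phase_boundaries
    channels = trains.channels
    volts = np.empty((len(channels), n_samples))
    truth_labels: dict[int, np.ndarray] = {}
    for row, ch in enumerate(channels):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7000 + ch]))
        sig = rng.normal(0.0, bank.noise_sd, n_samples) if bank.noise_sd > 0 else np.zeros(n_samples)
        tmpls = bank.templates.get(ch, [])
        spike_t = trains.times[ch]
        if tmpls and spike_t.size:
            if any(t.trough_fwhm_ms * 4 > 4.0 for t in tmpls):
                raise ProtocolError("template longer than 4 ms")
            base_waves = [t.render(fs) for t in tmpls]
            exp_waves = [t.render(fs, width_scale=preset.ap_halfwidth_scale) for t in tmpls]
            probs = np.array([t.abundance for t in tmpls])
            choice = rng.choice(len(tmpls), size=spike_t.size, p=probs)
            truth_labels[ch] = choice
            centers = np.round(spike_t * fs).astype(int)
            for idx, c in zip(choice, centers):
                wave = exp_waves[idx] if t1 <= c / fs < t2 else base_waves[idx]
                lo, hi = c - 8, c - 8 + wave.size
                wlo, whi = max(0, -lo), wave.size - max(0, hi - n_samples)
                lo, hi = max(lo, 0), min(hi, n_samples)
                if lo < hi:
                    sig[lo:hi] += wave[wlo:whi]
        else:
            truth_labels[ch] = np.empty(0, dtype=int)
        volts[row] = sig
    rec = Recording(volts, fs, (t1, t2), channel_ids=list(channels))
    return rec, truth_labels


# ---------------------------------------------------------------------------
# Dose-response panels
# ---------------------------------------------------------------------------

# Agonist (muscimol-like) panel: concentrations in μM and per-dose replicate
# counts of the study's 14-recording concentration series.
MU_DOSES_UM = (1e-4, 0.1, 0.2, 0.25, 0.3, 0.4, 0.5, 1.0)
MU_DOSE_REPLICATES = (2, 3, 1, 2, 1, 1, 2, 2)
MU_IC50_UM = 0.25
_MU_HILL = 1.5

# RF panel: SAR levels in W/kg and per-dose replicate counts.
SAR_DOSES_WKG = (0.0, 5.5, 11.0, 20.35, 23.1, 25.3, 28.6, 30.6)
SAR_DOSE_REPLICATES = (21, 2, 3, 2, 3, 3, 5, 3)
SAR_HALF_EFFECT_WKG = 28.6
_SAR_HILL = 8.0


def _logistic_response(dose: np.ndarray, d50: float, hill: float) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    return 1.0 / (1.0 + (dose / d50) ** hill)


def agonist_dose_panel(seed: int, doses=MU_DOSES_UM, replicates=MU_DOSE_REPLICATES,
                       ic50: float = MU_IC50_UM, hill: float = _MU_HILL,
                       noise_sd: float = 0.05) -> pd.DataFrame:
    """Normalized-MBR values for an agonist concentration series.

    The underlying dose model is a descending logistic with full
    suppression at saturating dose; replicate values get multiplicative
    log-normal noise of the given sd.  Returns columns
    ``dose, r_mbr, replicate``.
    """
    return _dose_panel(seed, doses, replicates, ic50, hill, noise_sd)


def sar_dose_panel(seed: int, doses=SAR_DOSES_WKG, replicates=SAR_DOSE_REPLICATES,
                   half_effect: float = SAR_HALF_EFFECT_WKG, hill: float = _SAR_HILL,
                   noise_sd: float = 0.05) -> pd.DataFrame:
    """Normalized-MBR values for an RF SAR series: inhibition only appears
    above ~25 W/kg (steep logistic), halving MBR at ``half_effect``."""
    return _dose_panel(seed, doses, replicates, half_effect, hill, noise_sd)


def _dose_panel(seed, doses, replicates, d50, hill, noise_sd) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4242]))
    rows = []
    for dose, n in zip(doses, replicates):
        mean = float(_logistic_response(np.array([dose]), d50, hill)[0])
        vals = mean * np.exp(rng.normal(0.0, noise_sd, size=int(n)))
        rows.extend((float(dose), float(v), i) for i, v in enumerate(vals))
    return pd.DataFrame(rows, columns=["dose", "r_mbr", "replicate"])
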