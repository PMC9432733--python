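"""End-to-end orchestration: generate -> detect -> bursts -> metrics ->
waveforms -> group statistics, reproducible from a config + seed.

The event-level path (spike times only) drives the metric panel and the
group comparison across simulated cultures; the waveform-level path
renders short raw segments (default 8 channels, 5 min per phase) and
runs detection, sorting and AP-feature extraction on them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts as _bursts
from . import detection as _detection
from . import metrics as _metrics
from . import stats as _stats
from . import synthetic as _synthetic
from . import waveforms as _waveforms
from .io import ExperimentPhase, SpikeTrainSet

__all__ = [
    "RunConfig",
    "CultureResult",
    "simulate_culture",
    "simulate_arm",
    "waveform_culture",
    "run_experiment",
    "parse_config_file",
]

_DEFAULT_ARMS = {"sham": 12, "rf": 15, "mu": 8}


@dataclass
class RunConfig:
    """Everything a run needs; serializable, so config + seed reproduce it."""

    seed: int = 1
    out: str = "run_out"
    mode: str = "events"                       # events | waveforms
    arms: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_ARMS))
    protocol: _synthetic.ProtocolSpec = field(default_factory=_synthetic.ProtocolSpec)
    model: _synthetic.NetworkActivityModel = field(
        default_factory=_synthetic.NetworkActivityModel)
    burst_params: _bursts.BurstParams = field(default_factory=_bursts.BurstParams)
    alpha: float = 0.05

    def flat(self) -> dict[str, str]:
        out = {"seed": str(self.seed), "mode": self.mode,
               "arms": ",".join(f"{k}:{v}" for k, v in self.arms.items())}
        for prefix, obj in (("protocol", self.protocol), ("model", self.model),
                            ("burst", self.burst_params)):
            for f in dataclasses.fields(obj):
                out[f"{prefix}.{f.name}"] = str(getattr(obj, f.name))
        return out

    def hash(self) -> str:
        payload = "\n".join(f"{k}={v}" for k, v in sorted(self.flat().items()))
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def parse_config_file(path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a :class:`RunConfig`.

    Recognized keys: ``seed``, ``out``, ``mode``, ``arms`` (e.g.
    ``sham:12,rf:15,mu:8``) and dotted overrides ``protocol.<field>``,
    ``model.<field>``, ``burst.<field>``.
    """
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line is not 'key = value': {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        kv[key] = val
    cfg = RunConfig()
    overrides: dict[str, dict] = {"protocol": {}, "model": {}, "burst": {}}
    for key, val in kv.items():
        if key == "seed":
            cfg.seed = int(val)
        elif key == "out":
            cfg.out = val
        elif key == "mode":
            cfg.mode = val
        elif key == "arms":
            cfg.arms = {
                part.split(":")[0].strip(): int(part.split(":")[1])
                for part in val.split(",") if part.strip()
            }
        elif "." in key:
            prefix, name = key.split(".", 1)
            if prefix not in overrides:
                raise ValueError(f"unknown config section '{prefix}'")
            overrides[prefix][name] = val
        else:
            raise ValueError(f"unknown config key '{key}'")

    def _coerce(cls, kwargs):
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        out = {}
        for name, val in kwargs.items():
            if name not in types:
                raise ValueError(f"unknown field '{name}' for {cls.__name__}")
            out[name] = type(getattr(cls(), name))(val) if not isinstance(val, str) else \
                _parse_scalar(val, getattr(cls(), name))
        return out

    if overrides["protocol"]:
        cfg.protocol = dataclasses.replace(
            cfg.protocol, **_coerce(_synthetic.ProtocolSpec, overrides["protocol"]))
    if overrides["model"]:
        cfg.model = dataclasses.replace(
            cfg.model, **_coerce(_synthetic.NetworkActivityModel, overrides["model"]))
    if overrides["burst"]:
        cfg.burst_params = dataclasses.replace(
            cfg.burst_params, **_coerce(_bursts.BurstParams, overrides["burst"]))
    return cfg


def _parse_scalar(val: str, default):
    if isinstance(default, bool):
        return val.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(val)
    if isinstance(default, float):
        return float(val)
    return val


# ---------------------------------------------------------------------------
# Event-level analysis of one simulated culture
# ---------------------------------------------------------------------------

@dataclass
class CultureResult:
    """Event-level analysis output of one culture."""

    preset_name: str
    seed: int
    trains: SpikeTrainSet
    burst_table: pd.DataFrame
    active_channels: list[int]
    panels: dict[ExperimentPhase, pd.DataFrame]
    pooled_r: pd.Series                       # Eq-1 R per metric (MEA level)
    channel_r: pd.DataFrame                   # per-channel R per metric
    br_course: _metrics.TimeCourse
    sr_course: _metrics.TimeCourse
    summary: dict[str, float]


def analyze_trains(trains: SpikeTrainSet, preset_name: str = "", seed: int = 0,
                   burst_params: _bursts.BurstParams | None = None) -> CultureResult:
    """Burst detection + metric panel + normalizations for one spike-train set."""
    burst_params = burst_params or _bursts.BurstParams()
    table = _bursts.detect_bursts_trainset(trains, burst_params)
    active = _metrics.active_channel_filter(trains, table)
    table = _bursts.label_network_bursts(table, active, burst_params)
    panels = {
        phase: _metrics.compute_panel(trains, table, phase, channels=active)
        for phase in ExperimentPhase
    }
    pooled_r = _metrics.pooled_ratio(panels[ExperimentPhase.EXPOSURE],
                                     panels[ExperimentPhase.BASELINE])
    channel_r = _metrics.normalize(panels[ExperimentPhase.EXPOSURE],
                                   panels[ExperimentPhase.BASELINE])

    onsets = np.sort(np.concatenate([
        table[table["channel"] == ch]["start_s"].to_numpy() for ch in active]))
    spikes = np.sort(np.concatenate([trains.times[ch] for ch in active]))
    bounds = trains.phase_boundaries
    br_course = _metrics.time_course(onsets, trains.duration, bounds, bin_width=60.0)
    sr_course = _metrics.time_course(spikes, trains.duration, bounds, bin_width=60.0)

    summary: dict[str, float] = {"preset": preset_name, "seed": seed,
                                 "n_active": len(active)}
    for m in _metrics.METRICS:
        summary[f"R_{m}"] = float(pooled_r[m])
    summary["norm_rmse_MBR"] = _metrics.norm_rmse(channel_r["MBR"].to_numpy())
    summary["norm_rmse_MSR"] = _metrics.norm_rmse(channel_r["MSR"].to_numpy())
    for m in ("IBI", "BD", "IBSR"):
        cv_base = _metrics.cv_sync(table, trains, ExperimentPhase.BASELINE, m, active)
        cv_exp = _metrics.cv_sync(table, trains, ExperimentPhase.EXPOSURE, m, active)
        summary[f"cv_{m}_baseline"] = cv_base
        summary[f"cv_{m}_exposure"] = cv_exp
        summary[f"R_cv_{m}"] = cv_exp / cv_base if cv_base else np.nan
    summary["iir_br"] = _metrics.initial_inhibitory_rate(br_course)
    summary["iir_sr"] = _metrics.initial_inhibitory_rate(sr_course)
    summary["pir_br"] = _metrics.postinhibitory_rebound(br_course)
    summary["pir_sr"] = _metrics.postinhibitory_rebound(sr_course)
    return CultureResult(preset_name, seed, trains, table, active, panels,
                         pooled_r, channel_r, br_course, sr_course, summary)


def simulate_culture(
    preset: _synthetic.EffectPreset | str,
    seed: int,
    protocol: _synthetic.ProtocolSpec | None = None,
    model: _synthetic.NetworkActivityModel | None = None,
    burst_params: _bursts.BurstParams | None = None,
) -> CultureResult:
    """Generate one culture under a preset and run the event-level pipeline."""
    if isinstance(preset, str):
        preset = _synthetic.builtin_presets()[preset]
    protocol = protocol or _synthetic.ProtocolSpec()
    model = model or _synthetic.NetworkActivityModel()
    trains, _ = _synthetic.generate_spike_trains(protocol, model, preset, seed)
    return analyze_trains(trains, preset.name, seed, burst_params)


def simulate_arm(
    preset: _synthetic.EffectPreset | str,
    n_cultures: int,
    seed: int,
    arm_index: int = 0,
    protocol: _synthetic.ProtocolSpec | None = None,
    model: _synthetic.NetworkActivityModel | None = None,
    burst_params: _bursts.BurstParams | None = None,
) -> pd.DataFrame:
    """Simulate and analyze ``n_cultures`` cultures of one treatment arm.

    Per-culture seeds are derived deterministically from
    ``(seed, arm_index, culture_index)`` and stay below 2**31.
    """
    rows = []
    for i in range(n_cultures):
        culture_seed = int(
            np.random.SeedSequence([int(seed), arm_index, i]).generate_state(1)[0]
            % (2 ** 31)
        )
        res = simulate_culture(preset, culture_seed, protocol, model, burst_params)
        rows.append(res.summary)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Waveform-level analysis of one culture
# ---------------------------------------------------------------------------

def waveform_culture(
    preset: _synthetic.EffectPreset | str,
    seed: int,
    n_channels: int = 8,
    phase_duration: float = 300.0,
    model: _synthetic.NetworkActivityModel | None = None,
    noise_sd: float = 3.0,
) -> dict:
    """Render a short waveform-level segment and measure AP-shape changes.

    Baseline and exposure segments of ``phase_duration`` seconds are
    merged into one rendered record (so units are sorted across both
    phases), spikes are detected at 5 sigma with 40-sample snippets,
    sorted per channel, classified MAJ/AUX/MIN, and the exposure/baseline
    feature ratios of MAJ+AUX units are averaged into the MEA-level
    waveform change.
    """
    if isinstance(preset, str):
        preset = _synthetic.builtin_presets()[preset]
    model = model or _synthetic.NetworkActivityModel()
    protocol = _synthetic.ProtocolSpec(
        baseline_duration=phase_duration, exposure_duration=phase_duration,
        post_duration=1.0, n_channels=n_channels)
    trains, _ = _synthetic.generate_spike_trains(protocol, model, preset, seed)
    bank = _synthetic.WaveformTemplateBank.default(trains.channels, noise_sd=noise_sd)
    rec, _ = _synthetic.render_raw_recording(trains, bank, protocol, preset, seed)
    detected = _detection.detect_recording(rec, with_snippets=True)

    t1, _ = protocol.phase_boundaries
    unit_rows = []
    ratios = []
    for ch in detected.channels:
        snips = detected.snippets.get(ch, np.empty((0, 40)))
        times = detected.times[ch]
        labels = _waveforms.sort_spikes(snips, seed=seed)
        classes = _waveforms.classify_clusters(labels)
        feats_base: dict[int, _waveforms.WaveformFeatures] = {}
        feats_exp: dict[int, _waveforms.WaveformFeatures] = {}
        for unit in classes:
            sel = labels == unit
            for phase_sel, store in ((times < t1, feats_base), (times >= t1, feats_exp)):
                pick = sel & phase_sel
                if np.sum(pick) >= 5:
                    try:
                        store[unit] = _waveforms.waveform_features(
                            snips[pick].mean(axis=0), rec.sampling_rate)
                    except _waveforms.FeatureError:
                        pass
        per_unit, _mea = _waveforms.feature_change(feats_exp, feats_base, classes)
        for unit, ratio in per_unit.items():
            unit_rows.append({"channel": ch, "unit": unit, "class": classes[unit],
                              "n_spikes": int(np.sum(labels == unit)),
                              **{f"ratio_{n}": float(v)
                                 for n, v in zip(_waveforms.FEATURE_NAMES, ratio)}})
            ratios.append(ratio)
    mea_ratio = (np.nanmean(np.stack(ratios), axis=0)
                 if ratios else np.full(len(_waveforms.FEATURE_NAMES), np.nan))
    return {
        "preset": preset.name,
        "units": pd.DataFrame(unit_rows),
        "mea_ratio": {n: float(v) for n, v in zip(_waveforms.FEATURE_NAMES, mea_ratio)},
    }


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def run_experiment(config: RunConfig) -> Path:
    """Run all arms, write tidy CSV/JSON outputs and a summary report.

    Outputs under ``config.out``: per-culture summaries including
    normalized metrics, synchrony CVs, initial inhibitory rates and
    rebound ratios (``cultures.csv``), and group statistics with compact
    letters (``group_stats.json``).  Every file carries the config hash.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    presets = _synthetic.builtin_presets()

    frames = []
    for arm_index, (name, n) in enumerate(config.arms.items()):
        if name not in presets:
            raise ValueError(f"unknown preset '{name}'")
        df = simulate_arm(presets[name], n, config.seed, arm_index,
                          config.protocol, config.model, config.burst_params)
        frames.append(df)
    cultures = pd.concat(frames, ignore_index=True)
    _write_csv(cultures, out / "cultures.csv", cfg_hash)

    report: dict = {"config_hash": cfg_hash, "arms": config.arms,
                    "seed": config.seed, "comparisons": {}}
    for metric in ("R_MBR", "R_MSR", "R_IBI", "R_BD", "R_IBSR", "pir_br", "iir_br"):
        groups = {
            name: cultures.loc[cultures["preset"] == name, metric].dropna().to_numpy()
            for name in config.arms
        }
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            continue
        cmp_res = _stats.compare_groups(groups, alpha=config.alpha)
        report["comparisons"][metric] = {
            "H": cmp_res.h, "p": cmp_res.p, "epsilon_squared": cmp_res.eps_squared,
            "letters": cmp_res.letters,
            "medians": {k: float(np.median(v)) for k, v in groups.items()},
            "pairwise_p": {f"{a}|{b}": float(cmp_res.pairwise.loc[a, b])
                           for a in cmp_res.pairwise.index
                           for b in cmp_res.pairwise.columns if a < b},
        }
    if config.mode == "waveforms":
        report["waveforms"] = {
            name: waveform_culture(presets[name], config.seed + arm_index)["mea_ratio"]
            for arm_index, name in enumerate(config.arms)
        }
    (out / "group_stats.json").write_text(json.dumps(report, indent=2, default=float))
    return out


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)
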