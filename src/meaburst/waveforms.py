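"""Spike sorting and action-potential waveform analysis.

Snippets (40 samples, trough-aligned) are sorted per channel by
projecting onto the first three principal components and fitting
Gaussian mixtures with 1-4 components selected by BIC; spikes beyond a
Mahalanobis outlier bound from every component stay unsorted (label -1).
Clusters are ranked by spike count into a major (MAJ) unit, auxiliary
(AUX) units holding at least 15 % of the channel's sorted spikes, and
minor (MIN) units.

Waveform features follow the inverted extracellular convention (the AP
appears as a negative trough): the *rising edge* is the fast downstroke
into the trough (the depolarization equivalent), measured as the
maximum-magnitude slope on the pre-trough segment; the *falling edge* is
the trough-to-peak recovery slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = [
    "WaveformFeatures",
    "sort_spikes",
    "classify_clusters",
    "waveform_features",
    "feature_change",
    "phase_plot",
    "FeatureError",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ["peak", "anti_peak", "fwhm_ms", "max_rising_slope", "max_falling_slope"]

_N_PCS = 3
_OUTLIER_MULTIPLIER = 1.5  # times the 0.99 chi-square quantile on squared distance
_MIN_SNIPPETS = 20
_AUX_FRACTION = 0.15


class FeatureError(ValueError):
    """Snippet lacks the structure (e.g. a trough) a feature needs."""


@dataclass(frozen=True)
class WaveformFeatures:
    """Shape descriptors of a mean AP snippet (inverted extracellular wave)."""

    peak: float               # μV, positive after-wave extremum above baseline
    anti_peak: float          # μV, trough magnitude below baseline
    fwhm_ms: float            # ms, full width at half maximum of the trough
    max_rising_slope: float   # μV/ms, fastest descent into the trough
    max_falling_slope: float  # μV/ms, fastest trough-to-peak recovery

    def as_array(self) -> np.ndarray:
        return np.array([self.peak, self.anti_peak, self.fwhm_ms,
                         self.max_rising_slope, self.max_falling_slope])


def sort_spikes(snippets: np.ndarray, seed: int = 0, max_components: int = 4) -> np.ndarray:
    """Cluster one channel's snippets; returns per-spike labels (-1 = unsorted).

    Fewer than 20 snippets: the channel is skipped (all labels -1).
    Model selection minimizes BIC over 1..4 full-covariance Gaussian
    mixtures on the first three principal components; spikes whose
    squared Mahalanobis distance to their best component exceeds
    1.5x the 0.99 chi-square quantile (3 d.o.f.) are left unsorted.
    Deterministic for a given seed.
    """
    snippets = np.asarray(snippets, dtype=float)
    n = snippets.shape[0]
    if n < _MIN_SNIPPETS:
        return -np.ones(n, dtype=int)
    n_pcs = min(_N_PCS, snippets.shape[1], n)
    proj = PCA(n_components=n_pcs, random_state=0).fit_transform(snippets)
    best, best_bic = None, np.inf
    for k in range(1, max_components + 1):
        if n < 2 * k:
            break
        try:
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 n_init=1, random_state=int(seed), reg_covar=1e-4)
            gm.fit(proj)
            bic = gm.bic(proj)
        except Exception:
            continue
        if np.isfinite(bic) and bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    if best is None:  # degenerate covariance everywhere: one cluster
        return np.zeros(n, dtype=int)
    labels = best.predict(proj)
    # Mahalanobis outlier bound against the assigned component
    bound = _OUTLIER_MULTIPLIER * chi2.ppf(0.99, df=n_pcs)
    prec = best.precisions_
    for k in range(best.n_components):
        sel = labels == k
        if not np.any(sel):
            continue
        d = proj[sel] - best.means_[k]
        sq = np.einsum("ij,jk,ik->i", d, prec[k], d)
        out = np.flatnonzero(sel)[sq > bound]
        labels[out] = -1
    return labels


def classify_clusters(labels: np.ndarray) -> dict[int, str]:
    """Rank sorted clusters into MAJ / AUX / MIN by spike count.

    The largest cluster (ties broken toward the lower cluster index) is
    MAJ; remaining clusters holding at least 15 % of the channel's sorted
    spikes are AUX; the rest are MIN.  Unsorted spikes (-1) are ignored.
    """
    labels = np.asarray(labels)
    sorted_lbl = labels[labels >= 0]
    if sorted_lbl.size == 0:
        return {}
    ids, counts = np.unique(sorted_lbl, return_counts=True)
    order = np.lexsort((ids, -counts))  # by count desc, then index asc
    total = counts.sum()
    classes: dict[int, str] = {}
    for rank, j in enumerate(order):
        if rank == 0:
            classes[int(ids[j])] = "MAJ"
        elif counts[j] / total >= _AUX_FRACTION:
            classes[int(ids[j])] = "AUX"
        else:
            classes[int(ids[j])] = "MIN"
    return classes


def waveform_features(snippet: np.ndarray, sampling_rate: float = 10_000.0) -> WaveformFeatures:
    """Shape features of a (mean) 40-sample snippet.

    Baseline is the mean of the first four samples.  FWHM crossings of
    the half-trough level are located by linear interpolation between
    adjacent samples.
    """
    w = np.asarray(snippet, dtype=float)
    if w.ndim != 1:
        raise FeatureError("waveform_features expects a single snippet")
    dt_ms = 1e3 / sampling_rate
    baseline = float(np.mean(w[:4]))
    i_min = int(np.argmin(w))
    anti_peak = baseline - float(w[i_min])
    if anti_peak <= 0:
        raise FeatureError("snippet has no trough below baseline")
    after = w[i_min:]
    peak = float(np.max(after)) - baseline
    half = baseline - anti_peak / 2.0

    def _cross(i0: int, i1: int) -> float:
        # linear interpolation of the crossing of `half` between samples
        y0, y1 = w[i0], w[i1]
        return i0 + (half - y0) / (y1 - y0) if y1 != y0 else float(i0)

    left = i_min
    while left > 0 and w[left] < half:
        left -= 1
    right = i_min
    while right < w.size - 1 and w[right] < half:
        right += 1
    if w[left] < half or w[right] < half:
        raise FeatureError("trough does not recross its half-maximum level")
    t_left = _cross(left, left + 1)
    t_right = _cross(right - 1, right)
    fwhm_ms = (t_right - t_left) * dt_ms

    diffs = np.diff(w) / dt_ms
    pre = diffs[:i_min]
    rising = float(np.max(np.abs(pre))) if pre.size else np.nan
    i_peak = i_min + int(np.argmax(after))
    seg = diffs[i_min:max(i_peak, i_min + 1)]
    falling = float(np.max(seg)) if seg.size else np.nan
    return WaveformFeatures(peak, anti_peak, fwhm_ms, rising, falling)


def feature_change(
    features_exposure: dict[int, WaveformFeatures],
    features_baseline: dict[int, WaveformFeatures],
    classes: dict[int, str],
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Exposure/baseline feature ratios for MAJ and AUX units.

    Units present in only one phase are excluded.  Returns the per-unit
    ratio arrays (ordered as :data:`FEATURE_NAMES`) and their unweighted
    mean — the MEA-level waveform change.
    """
    per_unit: dict[int, np.ndarray] = {}
    for unit, cls in classes.items():
        if cls not in ("MAJ", "AUX"):
            continue
        if unit not in features_exposure or unit not in features_baseline:
            continue
        base = features_baseline[unit].as_array()
        expo = features_exposure[unit].as_array()
        with np.errstate(divide="ignore", invalid="ignore"):
            per_unit[unit] = np.where(base != 0, expo / base, np.nan)
    if per_unit:
        mea = np.nanmean(np.stack(list(per_unit.values())), axis=0)
    else:
        mea = np.full(len(FEATURE_NAMES), np.nan)
    return per_unit, mea


def phase_plot(snippet: np.ndarray, sampling_rate: float = 10_000.0) -> tuple[np.ndarray, np.ndarray]:
    """Voltage vs dV/dt trajectory of a snippet (central differences).

    A narrower AP of equal amplitude traces a taller loop (larger
    |dV/dt| extrema) in this plane.
    """
    w = np.asarray(snippet, dtype=float)
    dt_ms = 1e3 / sampling_rate
    dv = np.gradient(w, dt_ms)
    return w, dv
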