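"""Spike cutouts, cluster-averaged waveforms, shape features and classes.

Each detected spike yields a 3 ms cutout (1 ms before to 2 ms after the
peak).  Cutouts are clustered by waveform similarity (divisive k-means
on energy-normalised cutouts, splits accepted by silhouette), cluster
members are averaged, and five features are measured on each averaged
waveform:

* spike amplitude (signed, baseline to peak, microvolts),
* first-peak-to-trough ratio (|first pre-peak of opposite sign| / |peak|),
* amplitude slope ((peak - first peak) / (t_peak - t_first), uV/ms),
* peak-to-peak time (first peak to second peak, ms),
* spike duration (peak to second peak, ms),

with the baseline defined as the mean of the first and last samples of
the window.  A decision tree then assigns one of five shape classes:
positive spiking (PS) when the amplitude is positive; otherwise
compound (CS) for >= 2 distinct troughs, triphasic (TS) for prominent
positive phases on both sides of the trough, fast spiking (FS) for
short spike duration, regular spiking (RS) otherwise.  All negative-
branch criteria are ratios or durations, so classification is invariant
to uniform amplitude scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .recording import RawRecording
from .spikes import SpikeTrain

__all__ = [
    "SpikeCutout",
    "WaveformFeatures",
    "extract_cutouts",
    "cluster_cutouts",
    "average_waveform",
    "compute_features",
    "classify_waveform",
    "waveform_prevalence",
    "waveform_pipeline",
]


@dataclass
class SpikeCutout:
    """One spike's voltage snippet: 1 ms before to 2 ms after the peak."""

    samples: np.ndarray
    sampling_rate: float
    channel_id: str = ""
    spike_time: float = 0.0
    pre_ms: float = 1.0

    @property
    def peak_index(self) -> int:
        return int(round(self.pre_ms * self.sampling_rate / 1000.0))

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the spike peak."""
        return (np.arange(self.samples.size) - self.peak_index) \
            / self.sampling_rate * 1000.0


@dataclass
class WaveformFeatures:
    """The five shape features of one averaged waveform, plus baseline."""

    spike_amplitude: float          # signed, baseline-to-peak, uV
    first_peak_trough_ratio: float  # dimensionless, absolute
    amplitude_slope: float          # uV/ms
    peak_to_peak_time: float        # ms, 1st peak to 2nd peak
    spike_duration: float           # ms, spike peak to 2nd peak
    baseline: float                 # uV
    second_peak_missing: bool = False
    n_negative_peaks: int = 1       # distinct prominent troughs
    pre_positive_ratio: float = 0.0   # pre-peak positive phase / |amplitude|
    post_positive_ratio: float = 0.0  # post-peak positive phase / |amplitude|


def extract_cutouts(filtered: RawRecording, spikes: SpikeTrain,
                    pre_ms: float = 1.0, post_ms: float = 2.0
                    ) -> tuple[list[SpikeCutout], int]:
    """Cutouts for every spike whose full window fits the recording.

    Returns ``(cutouts, n_boundary_skipped)``; spikes too close to an
    edge are skipped (padding would distort the first/last-sample
    baseline).
    """
    rate = filtered.sampling_rate
    n_pre = int(round(pre_ms * rate / 1000.0))
    n_post = int(round(post_ms * rate / 1000.0))
    cutouts, skipped = [], 0
    for ch, (cid, times) in enumerate(zip(filtered.channel_ids, spikes.times)):
        for t in times:
            idx = int(round((t - filtered.t0) * rate))
            if idx - n_pre < 0 or idx + n_post >= filtered.n_samples:
                skipped += 1
                continue
            cutouts.append(SpikeCutout(
                samples=filtered.data[ch, idx - n_pre: idx + n_post + 1].copy(),
                sampling_rate=rate, channel_id=cid, spike_time=float(t),
                pre_ms=pre_ms))
    return cutouts, skipped


def cluster_cutouts(cutouts: list[SpikeCutout], max_clusters: int = 6,
                    seed: int = 0, split_threshold: float = 0.2) -> np.ndarray:
    """Group cutouts by waveform similarity; returns a label per cutout.

    Divisive k-means on energy-normalised cutouts: starting from one
    cluster, each cluster is tentatively bisected (seeded 2-means) and
    the split is kept when its silhouette score reaches
    ``split_threshold``; splitting recurses until no cluster splits
    cleanly or ``max_clusters`` is reached.  Recursive bisection finds
    fine-grained shape classes that a single flat silhouette
    maximization misses when one gross contrast (e.g. positive- versus
    negative-going waveforms) dominates the global score.  Deterministic
    under ``seed``.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    if not cutouts:
        return np.array([], dtype=int)
    X = np.stack([c.samples for c in cutouts])
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / np.where(norms > 0, norms, 1.0)
    n = Xn.shape[0]
    labels = np.zeros(n, dtype=int)
    if n < 4 or np.allclose(Xn, Xn[0], atol=1e-10):
        return labels

    n_clusters = 1
    queue = [0]
    next_label = 1
    while queue and n_clusters < max_clusters:
        c = queue.pop(0)
        idx = np.flatnonzero(labels == c)
        if idx.size < 4 or np.allclose(Xn[idx], Xn[idx[0]], atol=1e-10):
            continue
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        sub = km.fit_predict(Xn[idx])
        if len(np.unique(sub)) < 2 or min(np.bincount(sub)) < 2:
            continue
        if silhouette_score(Xn[idx], sub) < split_threshold:
            continue
        labels[idx[sub == 1]] = next_label
        queue.extend([c, next_label])
        next_label += 1
        n_clusters += 1
    # compact label range
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def average_waveform(cutouts: list[SpikeCutout]) -> SpikeCutout:
    """Pointwise mean of a non-empty cluster of cutouts."""
    if not cutouts:
        raise ValueError("empty cluster")
    rates = {c.sampling_rate for c in cutouts}
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates: {sorted(rates)}")
    return SpikeCutout(
        samples=np.mean([c.samples for c in cutouts], axis=0),
        sampling_rate=cutouts[0].sampling_rate,
        channel_id=cutouts[0].channel_id,
        spike_time=cutouts[0].spike_time,
        pre_ms=cutouts[0].pre_ms)


def compute_features(avg: SpikeCutout, prominence_frac: float = 0.05,
                     cs_prominence: float = 0.3, cs_min_sep_ms: float = 0.3
                     ) -> WaveformFeatures:
    """Measure the five waveform features on an averaged cutout.

    Landmarks: the spike peak is the cutout's extremum at the 1 ms
    offset; the 1st peak is the opposite-sign extremum in the pre-peak
    window; the 2nd peak is the first opposite-sign local extremum
    after the peak with prominence >= ``prominence_frac`` of the main
    amplitude.  A missing 2nd peak sets the duration to the window end
    and flags the result.
    """
    y = avg.samples
    if np.ptp(y) == 0:
        raise ValueError("flat waveform; features undefined")
    t_ms = avg.times_ms
    i_peak = avg.peak_index
    baseline = (y[0] + y[-1]) / 2.0
    amplitude = y[i_peak] - baseline
    sign = np.sign(amplitude) if amplitude != 0 else -1.0

    # 1st peak: opposite-sign extremum before the spike peak
    pre = y[:i_peak] - baseline
    if pre.size:
        i_first = int(np.argmax(-sign * pre))
        first_amp = pre[i_first]
    else:
        i_first, first_amp = 0, 0.0
    ratio = abs(first_amp / amplitude) if amplitude != 0 else np.inf
    dt_first = t_ms[i_peak] - t_ms[i_first]
    slope = (amplitude - first_amp) / dt_first if dt_first > 0 else np.nan

    # 2nd peak: first opposite-sign local extremum after the spike peak
    # ("opposite sign" = beyond baseline by the prominence fraction)
    post = y[i_peak:] - baseline
    idx, _ = find_peaks(-sign * post, height=prominence_frac * abs(amplitude),
                        prominence=prominence_frac * abs(amplitude))
    if idx.size:
        i_second = i_peak + int(idx[0])
        missing = False
    else:
        i_second = y.size - 1
        missing = True
    duration = t_ms[i_second] - t_ms[i_peak]
    peak_to_peak = t_ms[i_second] - t_ms[i_first]

    # counts and phase prominences used by the decision tree; troughs are
    # extrema of the main-peak sign exceeding the compound-spike prominence
    centred = y - baseline
    troughs, _ = find_peaks(
        sign * centred, height=cs_prominence * abs(amplitude),
        prominence=cs_prominence * abs(amplitude),
        distance=max(1, int(round(cs_min_sep_ms * avg.sampling_rate / 1000.0))))
    pre_pos = float(np.max(-sign * pre) / abs(amplitude)) if pre.size else 0.0
    post_peaks = -sign * post
    post_pos = float(np.max(post_peaks[1:]) / abs(amplitude)) \
        if post_peaks.size > 1 else 0.0

    return WaveformFeatures(
        spike_amplitude=float(amplitude),
        first_peak_trough_ratio=float(ratio),
        amplitude_slope=float(slope),
        peak_to_peak_time=float(peak_to_peak),
        spike_duration=float(duration),
        baseline=float(baseline),
        second_peak_missing=missing,
        n_negative_peaks=int(troughs.size),
        pre_positive_ratio=max(0.0, pre_pos),
        post_positive_ratio=max(0.0, post_pos))


def classify_waveform(f: WaveformFeatures,
                      config: AnalysisConfig | None = None) -> str:
    """Assign one of RS / FS / TS / CS / PS to a feature set.

    PS if the spike amplitude is positive.  Negative spikes: CS for
    >= 2 distinct prominent troughs; else TS when both the pre- and
    post-peak positive phases exceed the triphasic prominence ratio;
    else FS when the spike duration is below ``fs_max_duration_ms``;
    else RS.  Precedence CS -> TS -> FS -> RS.
    """
    config = config or AnalysisConfig()
    if f.spike_amplitude > 0:
        return "PS"
    if f.n_negative_peaks >= 2:
        return "CS"
    if (f.pre_positive_ratio >= config.triphasic_ratio
            and f.post_positive_ratio >= config.triphasic_ratio):
        return "TS"
    if f.spike_duration < config.fs_max_duration_ms:
        return "FS"
    return "RS"


def waveform_prevalence(classes: list[str] | np.ndarray) -> pd.DataFrame:
    """Percentage of averaged waveforms per class; percentages sum to 100."""
    if len(classes) == 0:
        warnings.warn("no classified waveforms; empty prevalence table")
        return pd.DataFrame(columns=["class", "count", "percent"])
    s = pd.Series(list(classes)).value_counts()
    return pd.DataFrame({
        "class": s.index, "count": s.to_numpy(),
        "percent": 100.0 * s.to_numpy() / s.sum()})


def waveform_pipeline(filtered: RawRecording, spikes: SpikeTrain,
                      config: AnalysisConfig | None = None) -> dict:
    """Cutouts -> per-channel clustering -> averaging -> features -> classes.

    Clustering is per channel (one electrode records few units), so
    averaged waveforms retain their source channel.  Returns a dict
    with the cutout list, a features table and the prevalence table.
    """
    config = config or AnalysisConfig()
    cutouts, skipped = extract_cutouts(filtered, spikes,
                                       config.cutout_pre_ms, config.cutout_post_ms)
    rows = []
    by_channel: dict[str, list[SpikeCutout]] = {}
    for c in cutouts:
        by_channel.setdefault(c.channel_id, []).append(c)
    for cid, ch_cuts in by_channel.items():
        labels = cluster_cutouts(ch_cuts, config.max_clusters, config.seed)
        for lab in np.unique(labels):
            members = [c for c, l in zip(ch_cuts, labels) if l == lab]
            avg = average_waveform(members)
            try:
                f = compute_features(avg, cs_prominence=config.cs_prominence,
                                     cs_min_sep_ms=config.cs_min_sep_ms)
            except ValueError:
                continue
            rows.append({
                "channel": cid, "cluster": int(lab), "n_spikes": len(members),
                "class": classify_waveform(f, config),
                "spike_amplitude_uV": f.spike_amplitude,
                "first_peak_trough_ratio": f.first_peak_trough_ratio,
                "amplitude_slope_uV_per_ms": f.amplitude_slope,
                "peak_to_peak_time_ms": f.peak_to_peak_time,
                "spike_duration_ms": f.spike_duration,
                "baseline_uV": f.baseline,
                "second_peak_missing": f.second_peak_missing})
    features = pd.DataFrame(rows)
    prevalence = waveform_prevalence(features["class"].tolist()
                                     if len(features) else [])
    return {"cutouts": cutouts, "n_boundary_skipped": skipped,
            "features": features, "prevalence": prevalence}
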