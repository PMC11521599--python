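"""Threshold spike detection, CMA burst detection and activity metrics.

Spikes are detected on the spike-band-filtered signal wherever the
absolute voltage exceeds ``k`` standard deviations of the channel
(default ``k = 5``, both polarities); each contiguous supra-threshold
excursion yields one spike timed at its extremum, and a dead time
(default 1 ms) suppresses double counting of multiphasic waveforms.

Bursts are found with the network-wide cumulative-moving-average (CMA)
method: all channels' inter-spike intervals (ISIs) are pooled into one
histogram, the cumulative moving average of the histogram is computed,
and the burst ISI threshold is the bin at which the CMA curve has
decayed to ``alpha1 x max(CMA)`` past its peak, where ``alpha1`` is
selected from the skewness of the CMA distribution (skewness < 1 ->
1.0, 1-4 -> 0.7, 4-9 -> 0.5, > 9 -> 0.3).  The threshold is shared by
all channels; bursts are then delimited per channel as runs of >=
``min_spikes`` spikes whose successive ISIs all stay at or below the
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .recording import RawRecording

__all__ = [
    "DegenerateSignalError",
    "SpikeTrain",
    "BurstSet",
    "ActivityMetrics",
    "detect_spikes",
    "cma_burst_detect",
    "activity_metrics",
    "spike_pipeline",
]

# skewness -> alpha1 map of the CMA burst detector (configurable defaults)
CMA_ALPHA_MAP: tuple[tuple[float, float], ...] = (
    (1.0, 1.0), (4.0, 0.7), (9.0, 0.5), (np.inf, 0.3))


class DegenerateSignalError(ValueError):
    """Raised when a channel is constant (sigma = 0) and cannot be thresholded."""


@dataclass
class SpikeTrain:
    """Per-channel spike times, polarities and peak amplitudes."""

    channel_ids: list[str]
    times: list[np.ndarray]        # seconds, sorted, per channel
    polarities: list[np.ndarray]   # +1 / -1 per spike
    amplitudes: list[np.ndarray]   # signed peak voltage, microvolts
    sigma: np.ndarray              # detection sigma per channel
    threshold_k: float = 5.0

    @property
    def n_channels(self) -> int:
        return len(self.times)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.times))

    def pooled_isis(self) -> np.ndarray:
        """All channels' inter-spike intervals pooled, in milliseconds."""
        isis = [np.diff(t) * 1000.0 for t in self.times if t.size >= 2]
        return np.concatenate(isis) if isis else np.array([])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, t, pol, amp in zip(self.channel_ids, self.times,
                                    self.polarities, self.amplitudes):
            for j in range(t.size):
                rows.append((cid, t[j], int(pol[j]), amp[j]))
        return pd.DataFrame(rows, columns=["channel", "time_s", "polarity", "amp_uV"])


@dataclass
class BurstSet:
    """Per-channel burst intervals plus the CMA diagnostics that produced them."""

    channel_ids: list[str]
    bursts: list[list[tuple[float, float, int]]]  # (start s, end s, n_spikes)
    isi_threshold_ms: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_bursts(self) -> int:
        return int(sum(len(b) for b in self.bursts))

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, s, e, n) for cid, bs in zip(self.channel_ids, self.bursts)
                for (s, e, n) in bs]
        return pd.DataFrame(rows, columns=["channel", "start_s", "end_s", "n_spikes"])


@dataclass
class ActivityMetrics:
    """Spike/burst activity summary, per channel and network-pooled."""

    per_channel: pd.DataFrame   # channel, sr_hz, br_hz, mean_bd_ms, pct_in_bursts
    network: dict               # pooled values over all channels
    isis_ms: list[np.ndarray]   # per channel
    ibis_ms: list[np.ndarray]   # per channel
    bds_ms: list[np.ndarray]    # per channel, one entry per burst


def detect_spikes(filtered: RawRecording, k: float = 5.0,
                  dead_time_ms: float = 1.0) -> SpikeTrain:
    """Detect positive and negative threshold crossings on a filtered recording.

    ``sigma`` is the plain standard deviation of each channel of the
    supplied (already spike-band-filtered, already windowed) matrix.
    Each contiguous excursion beyond ``+/- k sigma`` contributes one
    spike at the sample of largest absolute voltage; spikes closer than
    ``dead_time_ms`` are merged keeping the larger-amplitude one.
    """
    rate = filtered.sampling_rate
    dead = dead_time_ms / 1000.0
    sigma = filtered.data.std(axis=1)
    if np.any(sigma == 0):
        bad = [filtered.channel_ids[i] for i in np.flatnonzero(sigma == 0)]
        raise DegenerateSignalError(f"constant channel(s): {bad}")

    times, pols, amps = [], [], []
    for ch in range(filtered.n_channels):
        x = filtered.data[ch]
        thr = k * sigma[ch]
        above = np.abs(x) >= thr
        # contiguous excursion bounds
        d = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, above.size]
        peak_idx = np.array(
            [s + np.argmax(np.abs(x[s:e])) for s, e in zip(starts, ends)], dtype=int)
        peak_amp = x[peak_idx] if peak_idx.size else np.array([])

        # dead-time merge: greedy scan keeping the larger |amplitude|
        keep_i, keep_a = [], []
        for i, a in zip(peak_idx, peak_amp):
            if keep_i and (i - keep_i[-1]) / rate < dead:
                if abs(a) > abs(keep_a[-1]):
                    keep_i[-1], keep_a[-1] = i, a
            else:
                keep_i.append(int(i))
                keep_a.append(float(a))
        keep_i = np.asarray(keep_i, dtype=int)
        keep_a = np.asarray(keep_a)
        times.append(filtered.t0 + keep_i / rate)
        pols.append(np.sign(keep_a).astype(int))
        amps.append(keep_a)

    return SpikeTrain(channel_ids=list(filtered.channel_ids), times=times,
                      polarities=pols, amplitudes=amps, sigma=sigma, threshold_k=k)


def _select_alpha1(skewness: float,
                   alpha_map: tuple[tuple[float, float], ...] = CMA_ALPHA_MAP) -> float:
    for upper, alpha in alpha_map:
        if skewness < upper:
            return alpha
    return alpha_map[-1][1]


def cma_burst_detect(spikes: SpikeTrain, bin_ms: float = 5.0,
                     max_isi_ms: float = 1000.0, min_spikes: int = 3,
                     alpha_map: tuple[tuple[float, float], ...] = CMA_ALPHA_MAP,
                     ) -> BurstSet:
    """Network-wide CMA burst detection.

    Pools ISIs across channels, histograms them (``bin_ms`` bins, capped
    at ``max_isi_ms``), computes the cumulative moving average of the
    histogram, and sets the burst ISI threshold at the first bin past
    the CMA peak where the curve falls to ``alpha1 x max(CMA)``.  If the
    occupied part of the histogram is a single bin (e.g. a perfectly
    regular train) no threshold is defined and the burst set is empty.
    """
    isis = spikes.pooled_isis()
    empty = BurstSet(channel_ids=list(spikes.channel_ids),
                     bursts=[[] for _ in spikes.times],
                     isi_threshold_ms=np.nan)
    if isis.size < 2:
        warnings.warn("fewer than 2 network-wide ISIs; no bursts detected")
        return empty

    edges = np.arange(0.0, max_isi_ms + bin_ms, bin_ms)
    hist, _ = np.histogram(np.minimum(isis, max_isi_ms - 1e-9), bins=edges)
    if np.count_nonzero(hist) < 2 or isis.max() - isis.min() < bin_ms:
        # single-bin ISI histogram (e.g. a perfectly regular train): no
        # time-scale separation, by convention no bursts (docs/methods.md)
        warnings.warn("single-bin ISI histogram; no bursts detected")
        empty.diagnostics = {"histogram": hist, "edges": edges}
        return empty

    cma = np.cumsum(hist) / np.arange(1, hist.size + 1)
    skew = float(stats.skew(cma))
    alpha1 = _select_alpha1(skew, alpha_map)
    i_max = int(np.argmax(cma))
    target = alpha1 * cma[i_max]
    below = np.flatnonzero(cma[i_max:] <= target)
    i_thr = i_max + int(below[0]) if below.size else hist.size - 1
    isi_threshold_ms = edges[i_thr + 1]  # upper edge of the threshold bin

    thr_s = isi_threshold_ms / 1000.0
    bursts: list[list[tuple[float, float, int]]] = []
    for t in spikes.times:
        ch_bursts = []
        if t.size >= min_spikes:
            gaps_ok = np.diff(t) <= thr_s
            i = 0
            while i < gaps_ok.size:
                if gaps_ok[i]:
                    j = i
                    while j < gaps_ok.size and gaps_ok[j]:
                        j += 1
                    n_in = j - i + 1
                    if n_in >= min_spikes:
                        ch_bursts.append((float(t[i]), float(t[j]), n_in))
                    i = j
                else:
                    i += 1
        bursts.append(ch_bursts)

    return BurstSet(
        channel_ids=list(spikes.channel_ids), bursts=bursts,
        isi_threshold_ms=float(isi_threshold_ms),
        diagnostics={"histogram": hist, "edges": edges, "cma": cma,
                     "skewness": skew, "alpha1": alpha1, "cma_peak_bin": i_max})


def activity_metrics(spikes: SpikeTrain, bursts: BurstSet,
                     window_s: float) -> ActivityMetrics:
    """Spike rate, burst rate, burst duration, %-in-burst, ISIs and IBIs.

    Rates are normalized by the analysis-window length; burst durations
    and intervals are in milliseconds.  Percent-in-burst counts spikes
    whose time falls inside any of their channel's burst intervals.
    """
    rows, isis, ibis, bds = [], [], [], []
    tot_spikes = tot_burst_spikes = tot_bursts = 0
    for cid, t, bs in zip(spikes.channel_ids, spikes.times, bursts.bursts):
        ch_isi = np.diff(t) * 1000.0
        ch_bd = np.array([(e - s) * 1000.0 for s, e, _ in bs])
        ch_ibi = np.array([(bs[i + 1][0] - bs[i][1]) * 1000.0
                           for i in range(len(bs) - 1)])
        in_burst = 0
        if bs and t.size:
            for s, e, _ in bs:
                in_burst += int(np.count_nonzero((t >= s) & (t <= e)))
        pct = 100.0 * in_burst / t.size if t.size else 0.0
        rows.append((cid, t.size / window_s, len(bs) / window_s,
                     float(ch_bd.mean()) if ch_bd.size else np.nan, pct))
        isis.append(ch_isi)
        ibis.append(ch_ibi)
        bds.append(ch_bd)
        tot_spikes += t.size
        tot_burst_spikes += in_burst
        tot_bursts += len(bs)

    per_channel = pd.DataFrame(
        rows, columns=["channel", "sr_hz", "br_hz", "mean_bd_ms", "pct_in_bursts"])
    all_bds = np.concatenate(bds) if bds else np.array([])
    all_isis = np.concatenate(isis) if isis else np.array([])
    all_ibis = np.concatenate(ibis) if ibis else np.array([])
    network = {
        "sr_hz": tot_spikes / window_s,
        "br_hz": tot_bursts / window_s,
        "mean_bd_ms": float(all_bds.mean()) if all_bds.size else np.nan,
        "pct_in_bursts": (100.0 * tot_burst_spikes / tot_spikes
                          if tot_spikes else 0.0),
        "mean_isi_ms": float(all_isis.mean()) if all_isis.size else np.nan,
        "mean_ibi_ms": float(all_ibis.mean()) if all_ibis.size else np.nan,
        "n_spikes": tot_spikes,
        "n_bursts": tot_bursts,
    }
    return ActivityMetrics(per_channel=per_channel, network=network,
                           isis_ms=isis, ibis_ms=ibis, bds_ms=bds)


def spike_pipeline(rec: RawRecording, config: AnalysisConfig | None = None
                   ) -> tuple[SpikeTrain, BurstSet, ActivityMetrics]:
    """Slice the analysis window, filter, detect spikes/bursts, summarize."""
    from .preprocess import bandpass_spike
    from .recording import slice_window

    config = config or AnalysisConfig()
    start, end = config.analysis_window_s
    end = min(end, rec.t0 + rec.duration)
    win = slice_window(rec, start, end)
    filt = bandpass_spike(win, config)
    st = detect_spikes(filt, k=config.spike_threshold_k,
                       dead_time_ms=config.spike_dead_time_ms)
    bs = cma_burst_detect(st, bin_ms=config.cma_bin_ms,
                          max_isi_ms=config.cma_max_isi_ms,
                          min_spikes=config.burst_min_spikes)
    am = activity_metrics(st, bs, end - start)
    return st, bs, am
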