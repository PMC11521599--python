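"""Synthetic multi-channel MEA recordings with ground truth.

Emulates 60-channel, 25 kHz extracellular recordings from cultured
networks.  Spiking on each channel is a homogeneous Poisson background
plus a burst process (Poisson or periodic-with-jitter onsets, a fixed
number of spikes per burst at a fixed intra-burst interval), and each
spike is rendered by adding a class-stereotyped waveform template into
Gaussian noise.  Three condition presets (``patterned``,
``intermediate``, ``irregular``) order the cultures from strongly
rhythmic, stereotyped activity to sparse, irregular activity, standing
in for pure neuronal cultures versus co-cultures with increasing
astrocyte fractions.

Templates are sums of Gaussian-windowed phases — closed-form, compact
and class-controllable — spanning 1 ms before to 2 ms after the main
peak.  A linear ramp between the first and last samples is subtracted so
that the window edges are exactly zero and the extremum equals the
requested peak amplitude exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import substream_rng
from .recording import RawRecording

__all__ = [
    "WAVEFORM_CLASSES",
    "GeneratorParams",
    "GroundTruth",
    "make_waveform_template",
    "generate_spike_times",
    "render_recording",
    "preset",
]

WAVEFORM_CLASSES = ("RS", "FS", "TS", "CS", "PS")

# phase tables: (offset ms from main peak, amplitude relative to main, sigma ms)
_TEMPLATE_PHASES: dict[str, list[tuple[float, float, float]]] = {
    # regular spiking: wide trough, late repolarization hump
    "RS": [(0.0, -1.0, 0.20), (-0.40, 0.10, 0.12), (0.80, 0.25, 0.22)],
    # fast spiking: narrow trough, early repolarization hump
    "FS": [(0.0, -1.0, 0.10), (-0.25, 0.08, 0.08), (0.30, 0.25, 0.10)],
    # triphasic: prominent positive phases before and after the trough
    "TS": [(0.0, -1.0, 0.15), (-0.40, 0.40, 0.14), (0.60, 0.40, 0.18)],
    # compound: two distinct troughs
    "CS": [(0.0, -1.0, 0.12), (0.60, -0.55, 0.14), (-0.30, 0.08, 0.10)],
    # positive spiking: dominant positive peak
    "PS": [(0.0, 1.0, 0.20), (0.55, -0.10, 0.18)],
}


def make_waveform_template(
    waveform_class: str,
    peak_amplitude: float,
    duration_params: list[tuple[float, float, float]] | None = None,
    sampling_rate: float = 25000.0,
    pre_ms: float = 1.0,
    post_ms: float = 2.0,
) -> np.ndarray:
    """Render a stereotyped spike template.

    Parameters
    ----------
    waveform_class
        One of ``RS, FS, TS, CS, PS``.
    peak_amplitude
        Signed extremum of the template in microvolts (negative for
        RS/FS/TS/CS, positive for PS).
    duration_params
        Optional override of the phase table: a list of
        ``(offset_ms, relative_amplitude, sigma_ms)`` tuples; the first
        entry is the main peak.
    """
    if waveform_class not in _TEMPLATE_PHASES:
        raise ValueError(f"unknown waveform class {waveform_class!r}; "
                         f"expected one of {WAVEFORM_CLASSES}")
    phases = duration_params if duration_params is not None else _TEMPLATE_PHASES[
        waveform_class]
    for off, _, sig in phases:
        if not (-pre_ms < off < post_ms):
            raise ValueError(f"phase offset {off} ms outside ({-pre_ms}, {post_ms}) ms")
        if sig <= 0:
            raise ValueError("phase width must be positive")
    n_pre = int(round(pre_ms * sampling_rate / 1000.0))
    n_post = int(round(post_ms * sampling_rate / 1000.0))
    t_ms = (np.arange(n_pre + n_post + 1) - n_pre) / sampling_rate * 1000.0
    wave = np.zeros_like(t_ms)
    for off, amp, sig in phases:
        wave += amp * np.exp(-0.5 * ((t_ms - off) / sig) ** 2)
    # pin window edges to exactly zero so the cutout baseline is zero
    wave -= wave[0] + (wave[-1] - wave[0]) * (t_ms - t_ms[0]) / (t_ms[-1] - t_ms[0])
    wave[0] = wave[-1] = 0.0
    extreme = wave.min() if peak_amplitude < 0 else wave.max()
    if extreme == 0:
        raise ValueError("degenerate template (no extremum of requested sign)")
    return wave * (peak_amplitude / extreme)


def generate_spike_times(
    rate: float,
    burst_params: tuple[float, int, float],
    duration: float,
    refractory_ms: float = 2.0,
    seed: int | np.random.Generator = 0,
    burst_timing: str = "poisson",
    burst_onset_jitter_s: float = 0.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Generate one channel's spike train with burst intervals.

    Parameters
    ----------
    rate
        Tonic (background) Poisson rate, Hz.
    burst_params
        ``(burst_rate_hz, spikes_per_burst, intra_burst_isi_ms)``.
        Burst onsets are Poisson (``burst_timing="poisson"``) or periodic
        with period ``1/burst_rate`` plus Gaussian jitter
        (``burst_timing="periodic"``).
    refractory_ms
        Absolute refractory period; later spike of a violating pair is
        dropped.

    Returns
    -------
    times, bursts
        Sorted spike times (s) and ``(start, end)`` burst intervals
        covering the retained burst spikes.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    burst_rate, spikes_per_burst, intra_isi_ms = burst_params

    tonic = np.array([])
    if rate > 0:
        n = rng.poisson(rate * duration)
        tonic = np.sort(rng.uniform(0.0, duration, n))

    onsets: np.ndarray = np.array([])
    if burst_rate > 0 and spikes_per_burst > 0:
        if burst_timing == "periodic":
            period = 1.0 / burst_rate
            starts = np.arange(rng.uniform(0, period), duration, period)
            if burst_onset_jitter_s > 0:
                starts = starts + rng.normal(0, burst_onset_jitter_s, starts.size)
            onsets = np.sort(starts[(starts >= 0) & (starts < duration)])
        elif burst_timing == "poisson":
            gaps = rng.exponential(1.0 / burst_rate, int(burst_rate * duration * 3) + 10)
            starts = np.cumsum(gaps)
            onsets = starts[starts < duration]
        else:
            raise ValueError(f"unknown burst_timing {burst_timing!r}")

    intra = intra_isi_ms / 1000.0
    burst_spikes = [onset + np.arange(spikes_per_burst) * intra for onset in onsets]
    labels = np.concatenate(
        [np.full(tonic.size, -1)]
        + [np.full(len(b), i) for i, b in enumerate(burst_spikes)]) if (
            tonic.size or burst_spikes) else np.array([], dtype=int)
    times = np.concatenate([tonic] + burst_spikes) if (tonic.size or burst_spikes) \
        else np.array([])
    keep = (times >= 0) & (times < duration)
    times, labels = times[keep], labels[keep]
    order = np.argsort(times, kind="stable")
    times, labels = times[order], labels[order]

    # absolute refractory: drop the later spike of any violating pair
    refr = refractory_ms / 1000.0
    kept_idx = []
    last = -np.inf
    for i, t in enumerate(times):
        if t - last >= refr:
            kept_idx.append(i)
            last = t
    times, labels = times[kept_idx], labels[kept_idx]

    bursts = []
    for i in range(len(burst_spikes)):
        member = times[labels == i]
        if member.size:
            bursts.append((float(member[0]), float(member[-1])))
    return times, bursts


@dataclass
class GeneratorParams:
    """Ground-truthed recording generator settings (one culture condition)."""

    n_channels: int = 60
    duration: float = 300.0
    sampling_rate: float = 25000.0
    noise_sd: float = 5.0
    tonic_rate: float = 1.0
    burst_rate: float = 0.2
    spikes_per_burst: int = 5
    intra_burst_isi_ms: float = 10.0
    burst_timing: str = "poisson"
    burst_onset_jitter_s: float = 0.0
    peak_amplitude: float = 50.0
    amplitude_jitter: float = 0.1
    class_mix: dict[str, float] = field(default_factory=lambda: {"RS": 1.0})
    refractory_ms: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.tonic_rate < 0 or self.burst_rate < 0:
            raise ValueError("rates must be >= 0")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture weights sum to {total}, not 1")
        for c in self.class_mix:
            if c not in WAVEFORM_CLASSES:
                raise ValueError(f"unknown class {c!r} in mixture")


@dataclass
class GroundTruth:
    """Per-channel ground truth of a rendered recording."""

    spike_times: list[np.ndarray]
    classes: list[np.ndarray]
    bursts: list[list[tuple[float, float]]]

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))

    def to_dict(self) -> dict:
        return {
            "spike_times_s": [t.tolist() for t in self.spike_times],
            "classes": [c.tolist() for c in self.classes],
            "bursts_s": [[list(b) for b in ch] for ch in self.bursts],
        }


# condition presets: ordered patterned > intermediate > irregular in spike
# rate, burstiness and template stereotypy.  Patterning (for the
# complexity-entropy contrast) comes from periodic bursts and identical
# templates; irregularity from Poisson-only timing and high jitter.
_PRESETS: dict[str, dict] = {
    # densely, rhythmically bursting culture: ~200 ms network bursts every
    # 0.5 s keep most 0.4 s embedding spans on burst structure, which is
    # what shows up as low entropy / high complexity after the 40 Hz chain
    "patterned": dict(
        tonic_rate=2.0, burst_rate=2.0, spikes_per_burst=25,
        intra_burst_isi_ms=8.0, burst_timing="periodic",
        burst_onset_jitter_s=0.02, peak_amplitude=60.0, amplitude_jitter=0.02,
        class_mix={"RS": 0.7, "FS": 0.3},
    ),
    "intermediate": dict(
        tonic_rate=1.5, burst_rate=1.2, spikes_per_burst=20,
        intra_burst_isi_ms=9.0, burst_timing="periodic",
        burst_onset_jitter_s=0.1, peak_amplitude=50.0, amplitude_jitter=0.15,
        class_mix={"RS": 0.5, "FS": 0.2, "TS": 0.15, "PS": 0.15},
    ),
    "irregular": dict(
        tonic_rate=0.8, burst_rate=0.05, spikes_per_burst=4,
        intra_burst_isi_ms=15.0, burst_timing="poisson",
        burst_onset_jitter_s=0.0, peak_amplitude=40.0, amplitude_jitter=0.35,
        class_mix={"RS": 0.3, "FS": 0.2, "TS": 0.2, "CS": 0.15, "PS": 0.15},
    ),
}


def preset(condition: str, **overrides) -> GeneratorParams:
    """GeneratorParams for a named condition preset.

    ``patterned`` / ``intermediate`` / ``irregular`` emulate cultures
    with decreasing rhythmicity and stereotypy (increasing astrocyte
    fraction).  Keyword overrides replace any field.
    """
    if condition not in _PRESETS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[condition])
    kwargs.update(overrides)
    return GeneratorParams(**kwargs)


def render_recording(params: GeneratorParams) -> tuple[RawRecording, GroundTruth]:
    """Render Gaussian noise plus template insertions at ground-truth times.

    Each channel draws one waveform class from the mixture (a channel
    records a stereotyped unit); per-spike amplitudes are jittered
    multiplicatively by ``amplitude_jitter``.  Spikes whose template
    window would cross a recording edge are dropped from the ground
    truth, so rendered insertions always equal the ground-truth count.
    Deterministic under a fixed seed.
    """
    rate = params.sampling_rate
    n_samples = int(round(params.duration * rate))
    noise_rng = substream_rng(params.seed, "noise")
    data = noise_rng.normal(0.0, params.noise_sd,
                            (params.n_channels, n_samples))

    classes_pool = sorted(params.class_mix)
    weights = np.array([params.class_mix[c] for c in classes_pool])
    n_pre = int(round(1e-3 * rate))
    n_post = int(round(2e-3 * rate))
    tpl_len = n_pre + n_post + 1

    gt_times, gt_classes, gt_bursts = [], [], []
    for ch in range(params.n_channels):
        rng = substream_rng(params.seed, f"channel:{ch}")
        ch_class = rng.choice(classes_pool, p=weights)
        sign = 1.0 if ch_class == "PS" else -1.0
        base = make_waveform_template(ch_class, sign * params.peak_amplitude,
                                      sampling_rate=rate)
        times, bursts = generate_spike_times(
            params.tonic_rate,
            (params.burst_rate, params.spikes_per_burst, params.intra_burst_isi_ms),
            params.duration, params.refractory_ms, rng,
            params.burst_timing, params.burst_onset_jitter_s)
        kept = []
        for t in times:
            idx = int(round(t * rate))
            if idx - n_pre < 0 or idx + n_post >= n_samples:
                continue  # boundary spike: not rendered, not ground truth
            gain = max(0.1, 1.0 + params.amplitude_jitter * rng.standard_normal())
            data[ch, idx - n_pre: idx - n_pre + tpl_len] += base * gain
            kept.append(idx / rate)  # ground truth at the rendered peak sample
        kept = np.asarray(kept)
        gt_times.append(kept)
        gt_classes.append(np.full(kept.size, ch_class, dtype=object))
        gt_bursts.append([b for b in bursts])

    rec = RawRecording(data=data, sampling_rate=rate)
    return rec, GroundTruth(gt_times, gt_classes, gt_bursts)
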