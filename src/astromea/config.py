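"""Analysis configuration with the defaults used throughout the pipeline.

Every stage reads its parameters from :class:`AnalysisConfig`; a single
global ``seed`` is fanned out deterministically to the stochastic stages
via stage-name-keyed substreams (:func:`substream_seed`), so a full
pipeline run is reproducible from one integer.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["AnalysisConfig", "substream_seed", "substream_rng"]


def substream_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def substream_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator seeded from the stage-keyed substream of ``seed``."""
    return np.random.default_rng(substream_seed(seed, stage))


@dataclass
class AnalysisConfig:
    """Parameters of every pipeline stage.

    Attributes
    ----------
    spike_band_hz : (low, high) passband of the spike-band elliptic filter.
    spike_filter_order : analog prototype order of the elliptic bandpass
        (applied forward-backward, doubling the effective order).
    spike_threshold_k : detection threshold in multiples of the filtered
        signal's standard deviation (applied to both polarities).
    spike_dead_time_ms : minimum separation between detected spikes.
    analysis_window_s : half-open (start, end) window, seconds, used for
        spike/burst and complexity-entropy analysis.
    ce_m, ce_tau : ordinal-pattern embedding dimension and lag (samples).
    ce_lowpass_hz, ce_rate_hz : denoising low-pass cutoff and target rate
        of the complexity-entropy preprocessing chain.
    n_surrogates : surrogate series per channel for the null-hypothesis
        test of nonlinear patterning.
    surrogate_max_iter : iteration cap of the iAAFT scheme.
    alpha : significance level of the Kolmogorov-Smirnov comparison.
    cutout_pre_ms, cutout_post_ms : waveform cutout extent around the peak.
    fs_max_duration_ms, triphasic_ratio, cs_prominence, cs_min_sep_ms :
        waveform decision-tree thresholds (implementation defaults; see
        docs/methods.md).
    predict_lowpass_hz, predict_order, predict_rate_hz : prediction-chain
        Butterworth low-pass cutoff/order and target rate.
    train_fraction : leading fraction of samples used to train the
        autoregressive random forest.
    n_lags : autoregressive history length in samples at the prediction rate.
    n_trees : forest size.
    seed : global seed fanned out to all stochastic stages.
    """

    # spike-band filtering / detection
    spike_band_hz: tuple[float, float] = (300.0, 3000.0)
    spike_filter_order: int = 2
    spike_ripple_db: float = 0.1
    spike_atten_db: float = 40.0
    spike_threshold_k: float = 5.0
    spike_dead_time_ms: float = 1.0
    # burst detection
    cma_bin_ms: float = 5.0
    cma_max_isi_ms: float = 1000.0
    burst_min_spikes: int = 3
    # analysis window
    analysis_window_s: tuple[float, float] = (100.0, 200.0)
    # complexity-entropy
    ce_m: int = 5
    ce_tau: int = 100
    ce_lowpass_hz: float = 40.0
    ce_rate_hz: float = 1000.0
    # surrogates
    n_surrogates: int = 49
    surrogate_max_iter: int = 1000
    surrogate_spectrum_tol: float = 5e-3
    alpha: float = 0.05
    # waveforms
    cutout_pre_ms: float = 1.0
    cutout_post_ms: float = 2.0
    fs_max_duration_ms: float = 0.5
    triphasic_ratio: float = 0.15
    cs_prominence: float = 0.3
    cs_min_sep_ms: float = 0.3
    max_clusters: int = 6
    # prediction
    predict_lowpass_hz: float = 300.0
    predict_order: int = 5
    predict_rate_hz: float = 250.0
    train_fraction: float = 0.7
    n_lags: int = 20
    n_trees: int = 100
    predict_horizon: int = 1  # steps ahead; only 1 is implemented
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.ce_m < 2:
            raise ValueError("ce_m must be >= 2")
        if self.ce_tau < 1:
            raise ValueError("ce_tau must be >= 1")
        lo, hi = self.analysis_window_s
        if not lo < hi:
            raise ValueError("analysis window start must precede end")

    def rng(self, stage: str) -> np.random.Generator:
        return substream_rng(self.seed, stage)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("spike_band_hz", "analysis_window_s"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        for key in ("spike_band_hz", "analysis_window_s"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
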