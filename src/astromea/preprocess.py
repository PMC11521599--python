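"""The three filtering/resampling chains applied before analysis.

* spike chain  — second-order elliptic bandpass, 300–3000 Hz, for
  threshold spike detection;
* C-E chain    — 40 Hz low-pass then decimation to 1 kHz, for the
  ordinal-pattern complexity–entropy analysis;
* predict chain — 5th-order Butterworth low-pass at 300 Hz then
  decimation to 250 Hz (one sample per 4 ms), for the autoregressive
  predictability analysis.

All filters are applied zero-phase (forward–backward, ``filtfilt``), so
spike timing is not skewed.  Decimation keeps every k-th sample after
low-pass filtering; the target rate must divide the input rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .recording import RawRecording

__all__ = ["FilterSpec", "bandpass_spike", "ce_preprocess", "predict_preprocess"]


@dataclass(frozen=True)
class FilterSpec:
    """Design parameters of one filter stage.

    ``kind`` is ``"elliptic-bandpass"`` or ``"butterworth-lowpass"``;
    ``band_hz`` is ``(low, high)`` for the bandpass or ``(cutoff,)`` for
    the low-pass.  Ripple/attenuation apply to the elliptic design only.
    """

    kind: str
    order: int
    band_hz: tuple[float, ...]
    ripple_db: float = 0.1
    atten_db: float = 40.0

    def sos(self, sampling_rate: float) -> np.ndarray:
        nyq = sampling_rate / 2.0
        if self.kind == "elliptic-bandpass":
            low, high = self.band_hz
            if not 0 < low < high < nyq:
                raise ValueError(
                    f"band ({low}, {high}) Hz invalid for Nyquist {nyq} Hz")
            return signal.ellip(self.order, self.ripple_db, self.atten_db,
                                [low, high], btype="bandpass", fs=sampling_rate,
                                output="sos")
        if self.kind == "butterworth-lowpass":
            (cut,) = self.band_hz
            if not 0 < cut < nyq:
                raise ValueError(f"cutoff {cut} Hz invalid for Nyquist {nyq} Hz")
            return signal.butter(self.order, cut, btype="lowpass",
                                 fs=sampling_rate, output="sos")
        raise ValueError(f"unknown filter kind {self.kind!r}")


def _filtfilt(spec: FilterSpec, rec: RawRecording) -> RawRecording:
    sos = spec.sos(rec.sampling_rate)
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def _decimate(rec: RawRecording, target_rate: float) -> RawRecording:
    factor = rec.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target rate {target_rate} Hz does not divide {rec.sampling_rate} Hz")
    k = int(round(factor))
    if k == 1:
        return rec
    return rec.with_data(rec.data[:, ::k], sampling_rate=target_rate)


def bandpass_spike(rec: RawRecording, config: AnalysisConfig | None = None) -> RawRecording:
    """Spike-band elliptic bandpass (default 300–3000 Hz, order 2, zero-phase).

    The per-channel mean is subtracted first so the DC level is removed
    exactly rather than only attenuated by the finite stopband.
    """
    config = config or AnalysisConfig()
    spec = FilterSpec("elliptic-bandpass", config.spike_filter_order,
                      tuple(config.spike_band_hz), config.spike_ripple_db,
                      config.spike_atten_db)
    centred = rec.with_data(rec.data - rec.data.mean(axis=1, keepdims=True))
    return _filtfilt(spec, centred)


def ce_preprocess(rec: RawRecording, config: AnalysisConfig | None = None) -> RawRecording:
    """Denoise and resample for complexity-entropy analysis.

    Low-pass at ``ce_lowpass_hz`` (default 40 Hz, 5th-order Butterworth,
    zero-phase) then keep every k-th sample down to ``ce_rate_hz``
    (default 1 kHz).  An input already at the target rate is only
    low-pass filtered.
    """
    config = config or AnalysisConfig()
    spec = FilterSpec("butterworth-lowpass", 5, (config.ce_lowpass_hz,))
    return _decimate(_filtfilt(spec, rec), config.ce_rate_hz)


def predict_preprocess(rec: RawRecording, config: AnalysisConfig | None = None) -> RawRecording:
    """Denoise and resample for signal prediction.

    Low-pass Butterworth (default 5th order, 300 Hz, zero-phase) then
    decimate to ``predict_rate_hz`` (default 250 Hz, i.e. a 4 ms sample
    period).
    """
    config = config or AnalysisConfig()
    spec = FilterSpec("butterworth-lowpass", config.predict_order,
                      (config.predict_lowpass_hz,))
    return _decimate(_filtfilt(spec, rec), config.predict_rate_hz)
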