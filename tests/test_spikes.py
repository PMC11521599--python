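"""Spike detection, CMA burst detection and activity metrics."""

import numpy as np
import pytest

from astromea import (AnalysisConfig, DegenerateSignalError, SpikeTrain,
                      activity_metrics, bandpass_spike, cma_burst_detect,
                      detect_spikes, slice_window)
from astromea.spikes import spike_pipeline
from conftest import make_recording


def pulse_recording(times_s, amp=-60.0, rate=25000.0, duration=2.0,
                    noise_sd=2.0, seed=0):
    """Noise plus sharp biphasic pulses at given times (already 'filtered')."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise_sd, int(duration * rate))
    t = np.arange(-25, 26) / rate * 1000.0
    shape = np.exp(-0.5 * (t / 0.15) ** 2) - 0.3 * np.exp(-0.5 * ((t - 0.5) / 0.3) ** 2)
    for ts in times_s:
        i = int(round(ts * rate))
        x[i - 25:i + 26] += amp * shape
    return make_recording(x[None, :], rate)


def burst_train(n_bursts=20, spikes_per_burst=5, intra_isi_s=0.010,
                period_s=2.0, t0=0.0):
    """Deterministic bursty spike train: bursts every ``period_s``."""
    times = np.concatenate([
        t0 + b * period_s + np.arange(spikes_per_burst) * intra_isi_s
        for b in range(n_bursts)])
    return SpikeTrain(channel_ids=["ch00"], times=[times],
                      polarities=[np.full(times.size, -1)],
                      amplitudes=[np.full(times.size, -50.0)],
                      sigma=np.array([5.0]))


class TestDetect:
    def test_pulses_recovered_at_extremum(self):
        times = [0.2, 0.5, 0.9, 1.4, 1.8]
        rec = pulse_recording(times)
        st = detect_spikes(rec, k=5.0)
        assert st.n_spikes == len(times)
        for t in times:
            assert np.min(np.abs(st.times[0] - t)) < 0.2e-3
        assert np.all(st.polarities[0] == -1)

    def test_constant_channel_rejected(self):
        with pytest.raises(DegenerateSignalError):
            detect_spikes(make_recording(np.zeros((1, 1000))))

    def test_negation_flips_polarity_only(self):
        rec = pulse_recording([0.3, 0.7, 1.2])
        st = detect_spikes(rec)
        st_neg = detect_spikes(rec.with_data(-rec.data))
        assert np.array_equal(st.times[0], st_neg.times[0])
        assert np.array_equal(st.polarities[0], -st_neg.polarities[0])

    def test_dead_time_suppresses_double_counts(self):
        rec = pulse_recording([0.5])
        st = detect_spikes(rec, dead_time_ms=1.0)
        assert st.times[0].size == 1

    def test_dc_offset_invariance_through_bandpass(self):
        rec = pulse_recording([0.3, 0.8, 1.3])
        n1 = detect_spikes(bandpass_spike(rec)).n_spikes
        shifted = rec.with_data(rec.data + 500.0)
        n2 = detect_spikes(bandpass_spike(shifted)).n_spikes
        assert n1 == n2


class TestCMABursts:
    def test_twenty_burst_fixture(self):
        st = burst_train()
        bs = cma_burst_detect(st, min_spikes=3)
        assert len(bs.bursts[0]) == 20
        assert 10.0 < bs.isi_threshold_ms < 2000.0
        for s, e, n in bs.bursts[0]:
            assert (e - s) * 1000.0 == pytest.approx(40.0, abs=1e-6)
            assert n == 5

    def test_regular_train_yields_no_bursts(self):
        times = np.arange(0.0, 10.0, 0.1)  # all ISIs exactly 100 ms
        st = SpikeTrain(channel_ids=["c"], times=[times],
                        polarities=[np.full(times.size, 1)],
                        amplitudes=[np.full(times.size, 30.0)],
                        sigma=np.array([5.0]))
        with pytest.warns(UserWarning, match="single-bin"):
            bs = cma_burst_detect(st)
        assert bs.n_bursts == 0

    def test_empty_train_yields_empty_burstset(self):
        st = SpikeTrain(channel_ids=["c"], times=[np.array([])],
                        polarities=[np.array([])], amplitudes=[np.array([])],
                        sigma=np.array([5.0]))
        with pytest.warns(UserWarning):
            bs = cma_burst_detect(st)
        assert bs.n_bursts == 0

    def test_diagnostics_populated(self):
        bs = cma_burst_detect(burst_train())
        for key in ("histogram", "cma", "skewness", "alpha1"):
            assert key in bs.diagnostics

    def test_threshold_is_network_wide(self):
        """Two channels with different trains share one ISI threshold."""
        a = burst_train().times[0]
        b = burst_train(t0=0.5).times[0]
        st = SpikeTrain(channel_ids=["a", "b"], times=[a, b],
                        polarities=[np.full(a.size, -1)] * 2,
                        amplitudes=[np.full(a.size, -50.0)] * 2,
                        sigma=np.array([5.0, 5.0]))
        bs = cma_burst_detect(st)
        assert len(bs.bursts[0]) == len(bs.bursts[1]) == 20


class TestActivityMetrics:
    def test_uniform_train_rate(self):
        times = np.linspace(0.0, 99.0, 100)
        st = SpikeTrain(channel_ids=["c"], times=[times],
                        polarities=[np.full(100, 1)],
                        amplitudes=[np.full(100, 30.0)],
                        sigma=np.array([5.0]))
        with pytest.warns(UserWarning):
            bs = cma_burst_detect(st)
        am = activity_metrics(st, bs, 100.0)
        assert am.network["sr_hz"] == pytest.approx(1.0)
        assert np.allclose(am.isis_ms[0], 1000.0)

    def test_burst_fixture_metrics(self):
        st = burst_train()
        bs = cma_burst_detect(st)
        am = activity_metrics(st, bs, 100.0)
        assert am.network["br_hz"] == pytest.approx(0.2)
        assert am.network["pct_in_bursts"] == pytest.approx(100.0)
        assert am.network["mean_bd_ms"] == pytest.approx(40.0, abs=1e-6)

    def test_zero_spikes(self):
        st = SpikeTrain(channel_ids=["c"], times=[np.array([])],
                        polarities=[np.array([])], amplitudes=[np.array([])],
                        sigma=np.array([5.0]))
        with pytest.warns(UserWarning):
            bs = cma_burst_detect(st)
        am = activity_metrics(st, bs, 100.0)
        assert am.network["sr_hz"] == 0.0
        assert am.network["pct_in_bursts"] == 0.0


class TestPipeline:
    def test_window_commutes_with_preslicing(self, small_patterned):
        rec, _ = small_patterned
        cfg = AnalysisConfig(analysis_window_s=(5.0, 25.0))
        st1, _, am1 = spike_pipeline(rec, cfg)
        pre = slice_window(rec, 5.0, 25.0)
        cfg2 = AnalysisConfig(analysis_window_s=(5.0, 25.0))
        st2, _, am2 = spike_pipeline(pre, cfg2)
        for a, b in zip(st1.times, st2.times):
            assert np.array_equal(a, b)
        assert am1.network == am2.network
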