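"""Cutout extraction, clustering, waveform features and classification."""

import numpy as np
import pytest

from astromea import (AnalysisConfig, SpikeCutout, WAVEFORM_CLASSES,
                      average_waveform, classify_waveform, cluster_cutouts,
                      compute_features, detect_spikes, extract_cutouts,
                      make_waveform_template, waveform_prevalence)
from astromea.spikes import SpikeTrain
from conftest import make_recording

RATE = 25000.0


def cutout_from(template):
    return SpikeCutout(np.asarray(template, dtype=float), RATE)


def constructed_waveform():
    """Baseline 0, 1st peak +10 uV at -0.4 ms, spike -50 uV at 0,
    2nd peak +20 uV at +0.8 ms."""
    t = (np.arange(76) - 25) / RATE * 1000.0
    y = (-50.0 * np.exp(-0.5 * (t / 0.08) ** 2)
         + 10.0 * np.exp(-0.5 * ((t + 0.4) / 0.08) ** 2)
         + 20.0 * np.exp(-0.5 * ((t - 0.8) / 0.08) ** 2))
    return cutout_from(y)


class TestExtract:
    def test_window_and_boundary_bookkeeping(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, 25000)
        rec = make_recording(x[None, :], RATE)
        times = np.array([0.0005, 0.3, 0.6, 0.9995])  # first and last overrun
        st = SpikeTrain(channel_ids=["ch00"], times=[times],
                        polarities=[np.full(4, -1)],
                        amplitudes=[np.full(4, -50.0)], sigma=np.array([1.0]))
        cutouts, skipped = extract_cutouts(rec, st)
        assert skipped == 2
        assert len(cutouts) == 2
        for c in cutouts:
            assert c.samples.size == int(3e-3 * RATE) + 1
            assert c.peak_index == int(1e-3 * RATE)


class TestCluster:
    def test_two_templates_high_purity(self):
        rng = np.random.default_rng(1)
        cuts, labels = [], []
        for cls in ("RS", "FS"):
            base = make_waveform_template(cls, -50.0)
            for _ in range(40):
                cuts.append(cutout_from(base + rng.normal(0, 5.0, base.size)))
                labels.append(cls)
        lab = cluster_cutouts(cuts, seed=1)
        from collections import Counter

        purity = sum(Counter(np.array(labels)[lab == j]).most_common(1)[0][1]
                     for j in np.unique(lab)) / len(labels)
        assert purity >= 0.95

    def test_single_cutout_single_cluster(self):
        lab = cluster_cutouts([cutout_from(make_waveform_template("RS", -50.0))])
        assert lab.tolist() == [0]

    def test_identical_cutouts_one_cluster(self):
        c = make_waveform_template("RS", -50.0)
        lab = cluster_cutouts([cutout_from(c.copy()) for _ in range(50)])
        assert np.all(lab == 0)


class TestAverage:
    def test_opposite_waveforms_cancel(self):
        x = make_waveform_template("RS", -50.0)
        avg = average_waveform([cutout_from(x), cutout_from(-x)])
        assert np.allclose(avg.samples, 0.0)

    def test_single_member_identity(self):
        x = make_waveform_template("FS", -50.0)
        avg = average_waveform([cutout_from(x)])
        assert np.array_equal(avg.samples, x)

    def test_mixed_rates_rejected(self):
        x = make_waveform_template("RS", -50.0)
        with pytest.raises(ValueError, match="mixed"):
            average_waveform([cutout_from(x), SpikeCutout(x, 20000.0)])

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            average_waveform([])


class TestFeatures:
    def test_constructed_example_features(self):
        f = compute_features(constructed_waveform())
        assert f.spike_amplitude == pytest.approx(-50.0, abs=0.2)
        assert f.first_peak_trough_ratio == pytest.approx(0.2, abs=0.01)
        assert f.amplitude_slope == pytest.approx(-150.0, rel=0.05)
        assert f.peak_to_peak_time == pytest.approx(1.2, abs=0.05)
        assert f.spike_duration == pytest.approx(0.8, abs=0.05)

    def test_baseline_is_mean_of_first_and_last_samples(self):
        y = np.zeros(76)
        y[0], y[-1] = 2.0, 4.0
        y[25] = -50.0
        f = compute_features(cutout_from(y))
        assert f.baseline == pytest.approx(3.0)

    def test_missing_second_peak_flags_window_end(self):
        t = (np.arange(76) - 25) / RATE * 1000.0
        y = -50.0 * np.exp(-0.5 * (t / 0.3) ** 2)  # monophasic trough
        f = compute_features(cutout_from(y))
        assert f.second_peak_missing
        assert f.spike_duration == pytest.approx(2.0, abs=0.01)

    def test_flat_waveform_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            compute_features(cutout_from(np.zeros(76)))


class TestClassify:
    def test_template_round_trip_all_classes(self):
        for cls in WAVEFORM_CLASSES:
            amp = 30.0 if cls == "PS" else -50.0
            f = compute_features(cutout_from(make_waveform_template(cls, amp)))
            assert abs(f.spike_amplitude - amp) < 1e-9 * abs(amp)
            assert classify_waveform(f) == cls

    def test_positive_amplitude_is_ps(self):
        f = compute_features(cutout_from(make_waveform_template("PS", 30.0)))
        assert f.spike_amplitude > 0
        assert classify_waveform(f) == "PS"

    def test_scale_invariance_of_negative_branches(self):
        for cls in ("RS", "FS", "TS", "CS"):
            base = make_waveform_template(cls, -50.0)
            for scale in (0.5, 2.0, 10.0):
                f = compute_features(cutout_from(base * scale))
                assert classify_waveform(f) == cls

    def test_short_single_trough_is_fs(self):
        f = compute_features(cutout_from(make_waveform_template("FS", -40.0)))
        assert f.spike_duration < AnalysisConfig().fs_max_duration_ms
        assert classify_waveform(f) == "FS"


class TestPrevalence:
    def test_four_rs_one_ps(self):
        tab = waveform_prevalence(["RS"] * 4 + ["PS"])
        d = dict(zip(tab["class"], tab["percent"]))
        assert d == {"RS": 80.0, "PS": 20.0}
        assert tab["percent"].sum() == pytest.approx(100.0)

    def test_single_class(self):
        tab = waveform_prevalence(["FS", "FS"])
        assert tab["percent"].tolist() == [100.0]

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            tab = waveform_prevalence([])
        assert tab.empty


class TestEndToEnd:
    def test_pipeline_on_rendered_recording(self, small_patterned):
        from astromea import bandpass_spike
        from astromea.waveforms import waveform_pipeline

        rec, gt = small_patterned
        filt = bandpass_spike(rec)
        st = detect_spikes(filt)
        out = waveform_pipeline(filt, st)
        assert len(out["features"])
        assert out["prevalence"]["percent"].sum() == pytest.approx(100.0)
        # per-channel dominant class should match the generating class
        feats = out["features"]
        correct = total = 0
        for ch, (cid, cls) in enumerate(zip(rec.channel_ids, gt.classes)):
            if not cls.size:
                continue
            sub = feats[feats.channel == cid]
            if not len(sub):
                continue
            dominant = sub.loc[sub.n_spikes.idxmax(), "class"]
            total += 1
            correct += int(dominant == cls[0])
        assert total and correct / total >= 0.9
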