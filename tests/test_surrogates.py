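"""iAAFT surrogates, empirical CDFs and the Kolmogorov-Smirnov test."""

import numpy as np
import pytest
from scipy import stats

from astromea import (RawRecording, ecdf, iaaft, ks_two_sample,
                      surrogate_ensemble)
from astromea.ordinal import ce_point


class TestIaaft:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_amplitude_distribution_preserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.exponential(size=2000)  # skewed values
        s, _, _ = iaaft(x, seed=seed + 10)
        assert np.array_equal(np.sort(s), np.sort(x))

    def test_periodogram_matches_at_convergence(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10000)
        s, it, conv = iaaft(x, seed=4)
        assert conv
        pa = np.abs(np.fft.rfft(x)) ** 2
        pb = np.abs(np.fft.rfft(s)) ** 2
        assert np.linalg.norm(pa - pb) / np.linalg.norm(pa) <= 1e-2

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=1024)
        s1, _, _ = iaaft(x, seed=7)
        s2, _, _ = iaaft(x, seed=7)
        s3, _, _ = iaaft(x, seed=8)
        assert np.array_equal(s1, s2)
        assert not np.array_equal(s1, s3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            iaaft(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            iaaft(np.r_[np.ones(100), np.nan])

    def test_surrogate_entropy_not_below_original_for_patterned_input(self):
        """Phase randomization cannot make a nonlinearly patterned signal
        look more deterministic, on average."""
        rng = np.random.default_rng(0)
        t = np.arange(30000) / 1000.0
        x = ((t * 2.0) % 1.0) + 0.3 * np.sin(2 * np.pi * 6.0 * t) \
            + 0.05 * rng.normal(size=t.size)
        orig = ce_point(x, 5, 100).hs
        diffs = [ce_point(iaaft(x, seed=s)[0], 5, 100).hs - orig
                 for s in range(10)]
        assert np.mean(diffs) > 0


class TestEnsemble:
    def test_counts_and_determinism(self):
        rng = np.random.default_rng(0)
        rec = RawRecording(data=rng.normal(size=(2, 1000)), sampling_rate=1000.0)
        e1 = surrogate_ensemble(rec, n=3, seed=11)
        e2 = surrogate_ensemble(rec, n=3, seed=11)
        assert sum(e.n_surrogates for e in e1) == 6
        for a, b in zip(e1, e2):
            assert np.array_equal(a.surrogates, b.surrogates)

    def test_single_channel_single_surrogate(self):
        rng = np.random.default_rng(1)
        rec = RawRecording(data=rng.normal(size=(1, 512)), sampling_rate=1000.0)
        (ens,) = surrogate_ensemble(rec, n=1, seed=0)
        assert ens.surrogates.shape == (1, 512)


class TestEcdf:
    def test_step_values(self):
        f = ecdf([1.0, 2.0, 3.0])
        assert f(2.0) == pytest.approx(2 / 3)
        assert f(0.5) == 0.0
        assert f(3.0) == 1.0
        assert f(np.min([1.0, 2.0, 3.0])) == pytest.approx(1 / 3)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        f = ecdf(rng.normal(size=50))
        grid = np.linspace(-4, 4, 200)
        vals = f(grid)
        assert np.all(np.diff(vals) >= 0)
        assert vals[0] == 0.0 and vals[-1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])


class TestKS:
    def test_identical_samples(self):
        d, p, h = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and h == 0

    def test_disjoint_supports(self):
        d, _, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_interleaved_quarter_gap(self):
        d, _, _ = ks_two_sample([1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5])
        assert d == pytest.approx(0.25)

    @pytest.mark.parametrize("shift", [0.0, 0.3, 0.8])
    def test_matches_scipy_asymptotic(self, shift):
        rng = np.random.default_rng(4)
        a = rng.normal(size=80)
        b = rng.normal(shift, 1.2, size=60)
        d, p, h = ks_two_sample(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        # scipy adds a small-sample correction to the plain asymptotic
        # Kolmogorov p-value; the correction grows with the statistic, so
        # agreement is checked on the order of magnitude and the decision
        assert ref.pvalue / 3.0 <= p <= 3.0 * ref.pvalue + 1e-12
        assert h == int(ref.pvalue < 0.05) or abs(p - 0.05) < 0.03

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_null_rejection_rates_calibrated(self):
        """Under the null (both samples from one distribution, n=60 each)
        the test rejects at close to (and not above) its nominal level;
        the discreteness of D at this sample size makes the p-value
        lumpy, so calibration is checked at two levels rather than by a
        goodness-of-fit to the uniform."""
        rng = np.random.default_rng(123)
        pvals = np.array([
            ks_two_sample(rng.normal(size=60), rng.normal(size=60))[1]
            for _ in range(1000)])
        assert np.mean(pvals < 0.05) <= 0.07   # 0.05 + ~3 binomial Ses
        assert 0.10 <= np.mean(pvals < 0.20) <= 0.25

    def test_split_half_null_calibration(self):
        """Splitting one pool of measure values in half rarely rejects."""
        rng = np.random.default_rng(9)
        pool = rng.normal(size=98)
        rejections = 0
        for _ in range(50):
            sh = rng.permutation(pool)
            _, _, h = ks_two_sample(sh[:49], sh[49:])
            rejections += h
        assert rejections <= 5  # h=0 in >= 90% of runs


class TestPooledKS:
    def test_pooling_concatenates_before_testing(self):
        rng = np.random.default_rng(6)
        reports = []
        for _ in range(3):
            reports.append({
                "original_hs": rng.normal(0.8, 0.01, 10),
                "original_cjs": rng.normal(0.25, 0.01, 10),
                "surrogate_hs": rng.normal(0.9, 0.01, 100),
                "surrogate_cjs": rng.normal(0.10, 0.01, 100),
            })
        from astromea import pooled_ks

        tab = pooled_ks(reports)
        assert set(tab["measure"]) == {"hs", "cjs"}
        assert (tab["h"] == 1).all()  # clearly separated pools

    def test_empty_pool_rejected(self):
        from astromea import pooled_ks

        with pytest.raises(ValueError):
            pooled_ks([])
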