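"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from astromea import AnalysisConfig, RawRecording


def brute_force_ordinal(x, m, tau):
    """Independent ordinal-pattern counter by explicit permutation matching.

    For every embedding vector with lag components ``y[s] = x[u - s*tau]``
    it searches all ``m!`` permutations ``(s_0, ..., s_{m-1})`` for the
    unique one with ``y[s_{m-1}] <= ... <= y[s_0]`` and, whenever two
    adjacent components are equal, ``s_l < s_{l-1}``.  Returns relative
    frequencies indexed by the lexicographic rank of the permutation.
    """
    x = np.asarray(x, dtype=float)
    perms = list(permutations(range(m)))
    counts = np.zeros(len(perms))
    span = (m - 1) * tau
    for u in range(span, x.size):
        y = [x[u - s * tau] for s in range(m)]
        for k, p in enumerate(perms):
            ok = True
            for pos in range(1, m):
                hi, lo = p[pos - 1], p[pos]  # positions pos-1 (larger) and pos
                if y[lo] > y[hi]:
                    ok = False
                    break
                if y[lo] == y[hi] and not lo < hi:
                    ok = False
                    break
            if ok:
                counts[k] += 1
                break
        else:  # pragma: no cover - the match is total by construction
            raise AssertionError("no permutation matched")
    return counts / counts.sum()


def make_recording(data, rate=25000.0, t0=0.0):
    return RawRecording(data=np.asarray(data, dtype=float), sampling_rate=rate,
                        t0=t0)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def noise_recording():
    """Two-channel white-noise recording, 5 s at 25 kHz."""
    rng = np.random.default_rng(123)
    return make_recording(rng.normal(0.0, 5.0, (2, 125000)))


@pytest.fixture(scope="session")
def small_patterned():
    """Patterned-preset recording at reduced scale (3 channels, 30 s)."""
    from astromea import preset, render_recording

    return render_recording(preset("patterned", n_channels=3, duration=30.0,
                                   seed=7))
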