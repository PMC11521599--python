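"""Ordinal-pattern distributions and the complexity-entropy causality plane.

A time series is embedded in ``M`` dimensions at lag ``tau`` and each
embedding vector is mapped to the permutation describing the rank order
of its lagged components (Bandt-Pompe symbolization).  The distribution
``P`` over the ``M!`` patterns yields two summary measures per channel:

* the normalized permutation entropy ``Hs = S[P] / log(M!)`` with ``S``
  the Shannon entropy, so ``Hs`` is 0 for a fully deterministic rank
  sequence and 1 for pattern-uniform (noise-like) dynamics; and
* the statistical complexity ``Cjs = Q[P, Pe] * Hs`` where
  ``Q = Q0 * Je`` is the Jensen-Shannon disequilibrium between ``P`` and
  the uniform distribution ``Pe``, normalized by the constant ``Q0``
  that makes ``max Q = 1``.

Patterned signals sit at intermediate entropy and high complexity; both
pure noise (``Hs -> 1``) and constant dynamics (``Hs -> 0``) have
``Cjs -> 0``, which is what makes the (Hs, Cjs) plane discriminate
structured from random activity.

Tie rule: when two lagged components are equal, the component with the
smaller lag index takes the lower-rank position in the descending
ordering (equivalently, the stable ascending argsort of the lag
components is reversed).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial, lgamma, log

import numpy as np

from .config import AnalysisConfig
from .recording import RawRecording

__all__ = [
    "OrdinalDistribution",
    "CEPoint",
    "ordinal_pattern_distribution",
    "normalized_entropy",
    "statistical_complexity",
    "ce_point",
    "ce_plane",
]

_MAX_M = 8  # M! patterns; beyond 8 the distribution is never populated


@dataclass
class OrdinalDistribution:
    """Counts and relative frequencies over the ``M!`` ordinal patterns."""

    m: int
    tau: int
    counts: np.ndarray  # length M!, integer counts per pattern

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size != factorial(self.m):
            raise ValueError(
                f"expected {factorial(self.m)} pattern slots, got {self.counts.size}")

    @property
    def n_vectors(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_vectors


@dataclass
class CEPoint:
    """One channel's coordinates on the complexity-entropy plane."""

    hs: float
    cjs: float
    channel_id: str = ""
    m: int = 5
    tau: int = 100
    n_vectors: int = 0


def _pattern_codes(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Mixed-radix code of the ordinal pattern of every embedding vector.

    Column ``s`` of the lag matrix holds ``x[u - s*tau]``; the pattern is
    the descending rank ordering with ties resolved toward the smaller
    lag index at the lower-rank position, i.e. the reversed stable
    ascending argsort.
    """
    T = x.size
    span = (m - 1) * tau
    n = T - span
    idx = span + np.arange(n)[:, None] - tau * np.arange(m)[None, :]
    lagged = x[idx]  # (n, m); column s = x[u - s*tau]
    pattern = np.argsort(lagged, axis=1, kind="stable")[:, ::-1]
    return pattern @ (m ** np.arange(m))


def _code_lookup(m: int) -> np.ndarray:
    """Map base-m permutation codes to dense slots 0..M!-1 (lexicographic)."""
    from itertools import permutations

    table = np.full(m**m, -1, dtype=np.int32)
    radix = m ** np.arange(m)
    for slot, perm in enumerate(permutations(range(m))):
        table[int(np.dot(perm, radix))] = slot
    return table


_LOOKUP_CACHE: dict[int, np.ndarray] = {}


def ordinal_pattern_distribution(x: np.ndarray, m: int, tau: int) -> OrdinalDistribution:
    """Distribution of ordinal patterns of dimension ``m`` at lag ``tau``.

    Requires ``len(x) >= (m - 1) * tau + 1``.  Equal neighbours are
    resolved deterministically (see module docstring), so the map from
    window to pattern is total: counts sum to ``T - (m - 1) * tau``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if m < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {m}")
    if m > _MAX_M:
        raise ValueError(f"embedding dimension {m} > {_MAX_M} not supported")
    if tau < 1:
        raise ValueError(f"lag must be >= 1, got {tau}")
    if x.size < (m - 1) * tau + 1:
        raise ValueError(
            f"need at least {(m - 1) * tau + 1} samples for M={m}, tau={tau}; "
            f"got {x.size}")
    if m not in _LOOKUP_CACHE:
        _LOOKUP_CACHE[m] = _code_lookup(m)
    slots = _LOOKUP_CACHE[m][_pattern_codes(x, m, tau)]
    counts = np.bincount(slots, minlength=factorial(m))
    return OrdinalDistribution(m=m, tau=tau, counts=counts)


def _shannon(p: np.ndarray) -> float:
    """Shannon entropy, natural log, with 0*log(0) := 0."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) + 0.0  # normalize -0.0


def normalized_entropy(dist: OrdinalDistribution | np.ndarray,
                       m: int | None = None) -> float:
    """Permutation entropy normalized to [0, 1] by ``log(M!)``."""
    if isinstance(dist, OrdinalDistribution):
        p, m = dist.probabilities, dist.m
    else:
        p = np.asarray(dist, dtype=np.float64)
        if m is None:
            raise ValueError("pass m when supplying a bare probability vector")
    return _shannon(p) / lgamma(m + 1)  # lgamma(m+1) == log(m!)


def statistical_complexity(dist: OrdinalDistribution | np.ndarray,
                           m: int | None = None) -> float:
    """Jensen-Shannon statistical complexity ``Cjs = Q0 * Je * Hs``.

    ``Je`` is the Jensen-Shannon divergence between ``P`` and the
    uniform distribution over the ``M!`` patterns, and ``Q0`` is the
    normalization constant making the disequilibrium reach 1 at its
    maximum (a degenerate distribution):

    ``Q0 = -2 / [ ((N+1)/N) log(N+1) - 2 log(2N) + log N ]``, ``N = M!``.
    """
    if isinstance(dist, OrdinalDistribution):
        p, m = dist.probabilities, dist.m
    else:
        p = np.asarray(dist, dtype=np.float64)
        if m is None:
            raise ValueError("pass m when supplying a bare probability vector")
    n = factorial(m)
    pe = np.full(n, 1.0 / n)
    je = _shannon((p + pe) / 2.0) - _shannon(p) / 2.0 - _shannon(pe) / 2.0
    q0 = -2.0 / (((n + 1.0) / n) * log(n + 1.0) - 2.0 * log(2.0 * n) + log(n))
    hs = _shannon(p) / lgamma(m + 1)
    return float(q0 * je * hs)


def ce_point(x: np.ndarray, m: int, tau: int, channel_id: str = "") -> CEPoint:
    """(Hs, Cjs) coordinates of one series."""
    dist = ordinal_pattern_distribution(x, m, tau)
    return CEPoint(hs=normalized_entropy(dist),
                   cjs=statistical_complexity(dist),
                   channel_id=channel_id, m=m, tau=tau,
                   n_vectors=dist.n_vectors)


def ce_plane(rec: RawRecording, config: AnalysisConfig | None = None) -> list[CEPoint]:
    """Complexity-entropy coordinates for every channel of a recording.

    Expects the complexity-entropy preprocessing chain to have been
    applied already (40 Hz low-pass, 1 kHz); with the default 100 s
    window, ``M=5`` and ``tau=100`` each channel contributes
    ``100000 - 400`` embedding vectors.
    """
    config = config or AnalysisConfig()
    return [
        ce_point(rec.data[i], config.ce_m, config.ce_tau, rec.channel_ids[i])
        for i in range(rec.n_channels)
    ]
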