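"""Optimal scalar context quantization by dynamic programming.

Conditioning a symbol model on a fine-grained variable (such as the exact
row mean) dilutes the adaptive statistics; grouping neighbouring condition
values into a few bins trades a small increase in conditional entropy for
much better-estimated counts.  Given an ordered condition set with priors
``p(m_i)`` and conditional symbol distributions ``p(x|m_i)``, this module
finds the contiguous partition into ``K`` bins minimizing the expected
distortion

    L = sum_i d(p(x|m_i), Q(p(x|m_i))) * p(m_i)

where ``Q`` maps each condition to its bin's representative distribution
(the prior-weighted mixture of the member conditionals).  Because the
conditions are scalar-ordered, only contiguous partitions are considered,
which makes the search an O(N^2 K) dynamic program; an exhaustive oracle in
the test-suite confirms optimality at small N.

The production codec ships the fixed row-mean rule
(:func:`acoqs.context_model.quantize_row_mean`); this module is the
machinery for deriving such rules from tabulated data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

_EPS = np.finfo(np.float64).tiny

_MEASURES = ("kl", "l1", "l2")


def distortion(p, q, measure: str = "kl") -> float:
    """Distortion between two distributions.

    ``kl`` is the Kullback-Leibler divergence in bits (0*log0 = 0, the
    second argument floored at machine epsilon); ``l1`` the total absolute
    difference; ``l2`` the Euclidean distance.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {q.shape}")
    if measure == "kl":
        ratio = p / np.maximum(q, _EPS)
        terms = np.where(p > 0, p * np.log2(np.maximum(ratio, _EPS)), 0.0)
        return float(terms.sum())
    if measure == "l1":
        return float(np.abs(p - q).sum())
    if measure == "l2":
        return float(np.sqrt(((p - q) ** 2).sum()))
    raise ValueError(f"unknown measure {measure!r}; expected one of {_MEASURES}")


@dataclass
class ConditionSet:
    """Ordered conditions with priors and conditional symbol distributions."""

    priors: np.ndarray          # (N,)
    conditionals: np.ndarray    # (N, A)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=np.float64)
        self.conditionals = np.asarray(self.conditionals, dtype=np.float64)
        if self.priors.ndim != 1 or self.conditionals.ndim != 2:
            raise ValueError("priors must be 1-D and conditionals 2-D")
        if self.priors.shape[0] != self.conditionals.shape[0]:
            raise ValueError("priors and conditionals disagree on N")
        if np.any(self.priors < 0) or np.any(self.conditionals < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.isclose(self.priors.sum(), 1.0, atol=1e-8):
            raise ValueError("priors must sum to 1")
        sums = self.conditionals.sum(axis=1)
        if not np.allclose(sums[self.priors > 0], 1.0, atol=1e-8):
            raise ValueError("each conditional distribution must sum to 1")

    def __len__(self) -> int:
        return int(self.priors.shape[0])

    @classmethod
    def from_joint_counts(cls, joint_counts) -> "ConditionSet":
        """Build from a (condition x symbol) count table (e.g. empirical)."""
        j = np.asarray(joint_counts, dtype=np.float64)
        if j.ndim != 2 or np.any(j < 0) or j.sum() <= 0:
            raise ValueError("need a non-negative 2-D table with positive total")
        priors = j.sum(axis=1) / j.sum()
        row = j.sum(axis=1)
        cond = np.where(row[:, None] > 0, j / np.maximum(row[:, None], _EPS),
                        1.0 / j.shape[1])
        return cls(priors, cond)


@dataclass
class ConditionPartition:
    """Contiguous grouping of conditions into K bins.

    ``bins`` holds inclusive (start, end) index ranges; ``representatives``
    the per-bin quantized distributions; ``objective`` the achieved L.
    """

    bins: List[Tuple[int, int]]
    representatives: np.ndarray  # (K, A)
    objective: float

    @property
    def k(self) -> int:
        return len(self.bins)

    def bin_of(self, i: int) -> int:
        for b, (s, e) in enumerate(self.bins):
            if s <= i <= e:
                return b
        raise IndexError(f"condition {i} not covered by partition")


def _bin_representative(cs: ConditionSet, s: int, e: int) -> np.ndarray:
    w = cs.priors[s:e + 1]
    wsum = w.sum()
    if wsum > 0:
        return (w[:, None] * cs.conditionals[s:e + 1]).sum(axis=0) / wsum
    return cs.conditionals[s:e + 1].mean(axis=0)


def _bin_cost(cs: ConditionSet, s: int, e: int, measure: str) -> float:
    rep = _bin_representative(cs, s, e)
    return float(sum(distortion(cs.conditionals[i], rep, measure) * cs.priors[i]
                     for i in range(s, e + 1)))


def optimal_partition(cs: ConditionSet, k: int,
                      measure: str = "kl") -> ConditionPartition:
    """Contiguous K-bin partition minimizing the quantization objective.

    Exact dynamic program over bin boundaries; ties are broken toward the
    earliest boundary.  Raises ``ValueError`` unless ``1 <= k <= N``.
    """
    n = len(cs)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= K <= N, got K={k}, N={n}")
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}")

    cost = np.empty((n, n), dtype=np.float64)
    for s in range(n):
        for e in range(s, n):
            cost[s, e] = _bin_cost(cs, s, e, measure)

    # dp[b][j]: best objective covering conditions 0..j with b+1 bins
    dp = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=np.int64)
    dp[0, :] = cost[0, :]
    for b in range(1, k):
        for j in range(b, n):
            best = np.inf
            best_i = b
            for i in range(b, j + 1):  # bin b spans i..j
                v = dp[b - 1, i - 1] + cost[i, j]
                if v < best:
                    best = v
                    best_i = i
            dp[b, j] = best
            back[b, j] = best_i
    bins: List[Tuple[int, int]] = []
    j = n - 1
    for b in range(k - 1, -1, -1):
        s = int(back[b, j]) if b > 0 else 0
        bins.append((s, j))
        j = s - 1
    bins.reverse()
    reps = np.stack([_bin_representative(cs, s, e) for s, e in bins])
    return ConditionPartition(bins, reps, float(dp[k - 1, n - 1]))


def entropy_gap(cs: ConditionSet,
                partition: ConditionPartition) -> Tuple[float, float]:
    """(H(X|M), H(X|Q)) for a partition; H(X|Q) >= H(X|M) always holds.

    H(X|M) conditions on the full set, H(X|Q) on the bins (whose conditional
    distributions are the prior-weighted member mixtures); the gap is the
    information lost to quantization.
    """
    def _h(p: np.ndarray) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, p * np.log2(p), 0.0)
        return float(-t.sum())

    h_m = float(sum(cs.priors[i] * _h(cs.conditionals[i]) for i in range(len(cs))))
    h_q = 0.0
    for (s, e), rep in zip(partition.bins, partition.representatives):
        h_q += float(cs.priors[s:e + 1].sum()) * _h(rep)
    return h_m, h_q
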