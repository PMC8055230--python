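"""Clustering-agreement indices and model parameter counts.

ARI, AMI and FMI are computed from the contingency table of two labelings of
the same items. All three are chance-adjusted or chance-robust, which matters
here because clonal deconvolution methods are compared on partitions whose
block counts differ. Implemented from first principles (pair counting,
permutation-model expected mutual information) rather than delegated, so the
formulas can be unit-tested against brute-force enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "contingency_table",
    "adjusted_rand_index",
    "adjusted_mutual_information",
    "fowlkes_mallows",
    "parameter_count",
]


def contingency_table(labels_a, labels_b) -> np.ndarray:
    """A x B matrix of co-occurrence counts n_ab between two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-d arrays of equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _comb2(x):
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-adjusted Rand index in [-1, 1]; 1 iff the partitions coincide."""
    table = contingency_table(labels_a, labels_b)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least two items")
    sum_ij = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-same or all-distinct)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log(p)))


def _mutual_information(table: np.ndarray, n: int) -> float:
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij > 0:
                mi += nij / n * np.log(n * nij / (a[i] * b[j]))
    return float(mi)


def _expected_mutual_information(table: np.ndarray, n: int) -> float:
    """E[MI] under the permutation (hypergeometric) null with fixed marginals."""
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(0, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(max(lo, 1), hi + 1):
                log_hyper = (
                    gammaln(ai + 1)
                    + gammaln(bj + 1)
                    + gammaln(n - ai + 1)
                    + gammaln(n - bj + 1)
                    - gammaln(n + 1)
                    - gammaln(nij + 1)
                    - gammaln(ai - nij + 1)
                    - gammaln(bj - nij + 1)
                    - gammaln(n - ai - bj + nij + 1)
                )
                emi += nij / n * np.log(n * nij / (ai * bj)) * np.exp(log_hyper)
    return float(emi)


def adjusted_mutual_information(labels_a, labels_b) -> float:
    """AMI with max-normalization: (MI - E[MI]) / (max(H_a, H_b) - E[MI])."""
    table = contingency_table(labels_a, labels_b)
    n = int(table.sum())
    if n < 2:
        raise ValueError("need at least two items")
    ha = _entropy(table.sum(axis=1), n)
    hb = _entropy(table.sum(axis=0), n)
    if ha == 0.0 and hb == 0.0:  # single cluster vs single cluster
        return 1.0
    mi = _mutual_information(table, n)
    emi = _expected_mutual_information(table, n)
    denom = max(ha, hb) - emi
    if denom == 0.0:
        return 1.0
    return float((mi - emi) / denom)


def fowlkes_mallows(labels_a, labels_b) -> float:
    """Geometric mean of pairwise precision and recall, in [0, 1]."""
    table = contingency_table(labels_a, labels_b)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least two items")
    tp = _comb2(table).sum()
    pa = _comb2(table.sum(axis=1)).sum()
    pb = _comb2(table.sum(axis=0)).sum()
    if pa == 0.0 and pb == 0.0:  # both all-singletons: identical partitions
        return 1.0
    if pa == 0.0 or pb == 0.0:
        return 0.0
    return float(tp / np.sqrt(pa * pb))


def parameter_count(family: str, L: int, M: int) -> int:
    """Free-parameter count per model family with L kept clusters, M samples.

    Flat: L + M*L; GP0 adds a shared (h^2, tau) pair; GP1 adds per-cluster
    amplitudes plus a shared tau; GP2 additionally adds the L(L-1)/2
    correlations; GP3 adds per-cluster (h_k^2, tau_k).
    """
    if L < 1 or M < 1:
        raise ValueError("L and M must be positive")
    np_flat = L + M * L
    if family == "Flat":
        return np_flat
    if family == "GP0":
        return np_flat + 2
    if family == "GP1":
        return np_flat + L + 1
    if family == "GP2":
        return np_flat + L + 1 + L * (L - 1) // 2
    if family == "GP3":
        return np_flat + 2 * L
    raise ValueError(f"unknown model family {family!r}")
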