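"""External clustering validation: ARI, NMI, FMI and the Jaccard index.

All four indices compare an identified partition ``I`` against an annotated
reference partition ``A`` and are invariant to how cluster ids are arranged.
They are built from the pair-count decomposition: over all C(n, 2) cell
pairs,

* ``a`` — together in both partitions,
* ``b`` — together in ``A`` but split in ``I``,
* ``c`` — split in ``A`` but together in ``I``,
* ``d`` — split in both.

The Rand index is ``(a + d) / C(n, 2)``; ARI adjusts it for chance with the
standard contingency-table expectation (Hubert–Arabie).  NMI is
``2 MI / (H(I) + H(A))`` with plug-in entropies (natural log; the ratio is
base-invariant).  FMI is ``a / sqrt((a + b)(a + c))`` and the Jaccard index
is ``a / (a + b + c)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairCounts", "pair_counts", "ari", "nmi", "fmi", "ji"]


@dataclass(frozen=True)
class PairCounts:
    """Pair-level agreement counts between two partitions of ``n`` items."""

    a: int  # together in both
    b: int  # together in A (reference), split in I
    c: int  # split in A, together in I
    d: int  # split in both

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def rand_index(self) -> float:
        return (self.a + self.d) / self.total if self.total else 1.0


def _as_codes(labels) -> np.ndarray:
    arr = np.asarray(labels)
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def contingency(I, A) -> np.ndarray:
    """Contingency table with rows indexing clusters of ``I``, columns of ``A``."""
    ci, ca = _as_codes(I), _as_codes(A)
    if ci.shape != ca.shape:
        raise ValueError("label vectors must have equal length")
    table = np.zeros((ci.max() + 1, ca.max() + 1), dtype=np.int64)
    np.add.at(table, (ci, ca), 1)
    return table


def pair_counts(I, A) -> PairCounts:
    """Classify all C(n, 2) item pairs by joint same/split membership."""
    table = contingency(I, A)
    n = int(table.sum())
    if n < 2:
        raise ValueError("need at least two items")

    def comb2(x):
        return (x * (x - 1)) // 2

    a = int(comb2(table).sum())
    same_a = int(comb2(table.sum(axis=0)).sum())  # together in A
    same_i = int(comb2(table.sum(axis=1)).sum())  # together in I
    b = same_a - a
    c = same_i - a
    d = comb2(n) - a - b - c
    return PairCounts(a=a, b=b, c=c, d=d)


def ari(I, A) -> float:
    """Adjusted Rand index (chance-corrected; 1 for identical partitions)."""
    table = contingency(I, A)
    n = int(table.sum())
    if n < 2:
        raise ValueError("need at least two items")

    def comb2(x):
        return x * (x - 1) / 2.0

    index = comb2(table.astype(np.float64)).sum()
    sum_rows = comb2(table.sum(axis=1).astype(np.float64)).sum()
    sum_cols = comb2(table.sum(axis=0).astype(np.float64)).sum()
    expected = sum_rows * sum_cols / comb2(float(n))
    max_index = 0.5 * (sum_rows + sum_cols)
    denom = max_index - expected
    if denom == 0:
        # both partitions all-singletons or both one cluster: identical -> 1
        pc = pair_counts(I, A)
        return 1.0 if pc.b == 0 and pc.c == 0 else 0.0
    return float((index - expected) / denom)


def nmi(I, A) -> float:
    """Normalized mutual information, ``2 MI / (H(I) + H(A))``."""
    table = contingency(I, A).astype(np.float64)
    n = table.sum()
    pi = table.sum(axis=1) / n
    pj = table.sum(axis=0) / n

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hi, ha = entropy(pi), entropy(pj)
    if hi == 0 and ha == 0:
        return 1.0  # both partitions trivial and identical
    pij = table / n
    mask = pij > 0
    outer = pi[:, None] * pj[None, :]
    mi = float((pij[mask] * np.log(pij[mask] / outer[mask])).sum())
    return 2.0 * mi / (hi + ha)


def fmi(I, A) -> float:
    """Fowlkes–Mallows index, ``a / sqrt((a + b)(a + c))``; 0 when ``a = 0``."""
    pc = pair_counts(I, A)
    if pc.a == 0:
        return 0.0
    return pc.a / float(np.sqrt((pc.a + pc.b) * (pc.a + pc.c)))


def ji(I, A) -> float:
    """Jaccard index, ``a / (a + b + c)``; 1 when both partitions are all-singleton."""
    pc = pair_counts(I, A)
    denom = pc.a + pc.b + pc.c
    if denom == 0:
        return 1.0
    return pc.a / denom


def all_metrics(I, A) -> dict[str, float]:
    """Convenience bundle of the four indices."""
    return {"ARI": ari(I, A), "NMI": nmi(I, A), "FMI": fmi(I, A), "JI": ji(I, A)}
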