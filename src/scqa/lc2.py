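"""Quantitative landmark constructor (LC2).

Scaled expression values are discretized into ``k`` bins — bin 1 reserved
for exact zeros, the remaining ``k - 1`` bins splitting ``(0, 1]`` evenly —
and genes are grouped by how many distinct bins they occupy, a cheap proxy
for the complexity of their expression trend.  Within each group, genes
whose rank orders over cells agree (quasi-trend-preserved genes) are
clustered: initial clusters come from a windowed Spearman-correlation graph
built like LC1's, and the remaining genes are swept in with a containment
similarity — the fraction of cells where the gene's value falls between the
cluster's per-cell lower and upper quartile bounds.  Each retained
cluster's mean expression profile is a landmark, a column of the
quantitative cell-landmark matrix ``Q2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .lc1 import GeneGraph, LandmarkMatrix, ScoredGenePair, n_pairs_to_keep
from .preprocess import ExpressionMatrix, ScqaParams

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretizedMatrix",
    "QuantCluster",
    "discretize",
    "group_by_bin_usage",
    "initial_clusters_quant",
    "bound_vectors",
    "quant_similarity",
    "assign_remaining_genes_quant",
    "build_q2",
    "build_quantitative_landmarks",
]


@dataclass
class DiscretizedMatrix:
    """Bin-index representation of a scaled matrix; bin 1 iff the value is 0."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # (m, n) int, entries in 1..k
    k: int


@dataclass
class QuantCluster:
    """A quasi-trend-preserved gene cluster with template and bound vectors.

    ``template`` is the per-cell mean of members' scaled expression;
    ``lower``/``upper`` are the per-cell order statistics at the
    ``quartile_pct`` positions of the members' values, so
    ``lower <= template <= upper`` need not hold exactly for tiny clusters
    but containment is always tested against [lower, upper] inclusively.
    """

    members: list[int]
    template: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    group: int = 0  # bin-usage count this cluster belongs to

    @property
    def size(self) -> int:
        return len(self.members)

    @classmethod
    def from_members(
        cls,
        members: list[int],
        E: ExpressionMatrix,
        quartile_pct: float = 25.0,
        group: int = 0,
    ) -> "QuantCluster":
        members = list(members)
        template = E.values[members].mean(axis=0)
        lower, upper = bound_vectors(members, E, quartile_pct)
        return cls(members=members, template=template, lower=lower, upper=upper, group=group)

    def add(self, gene: int, E: ExpressionMatrix, quartile_pct: float = 25.0) -> None:
        self.members.append(gene)
        self.template = E.values[self.members].mean(axis=0)
        self.lower, self.upper = bound_vectors(self.members, E, quartile_pct)


def discretize(E: ExpressionMatrix, k: int = 6) -> DiscretizedMatrix:
    """Assign each entry its 1-based bin index.

    Bins: ``[0, 0]``, ``(0, 1/(k-1)]``, ..., ``((k-2)/(k-1), 1]`` — exact
    zeros always land in bin 1, the value 1 in bin ``k``.
    """
    v = E.values
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("discretize expects entries scaled into [0, 1]")
    # small backoff so values sitting exactly on a bin edge (up to float
    # round-off) fall into the closed upper end of the lower bin
    pos = np.ceil(v * (k - 1) - 1e-9).astype(np.int64) + 1
    idx = np.where(v == 0, 1, np.clip(pos, 2, k))
    return DiscretizedMatrix(
        gene_ids=list(E.gene_ids), cell_ids=list(E.cell_ids), values=idx, k=k
    )


def group_by_bin_usage(Dp: DiscretizedMatrix) -> dict[int, list[int]]:
    """Map bin-usage count -> gene indices using that many distinct bins."""
    groups: dict[int, list[int]] = {}
    for g in range(Dp.values.shape[0]):
        usage = len(np.unique(Dp.values[g]))
        groups.setdefault(usage, []).append(g)
    return dict(sorted(groups.items()))


def bound_vectors(
    members: list[int], E: ExpressionMatrix, quartile_pct: float = 25.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell lower/upper quartile order statistics of the members' values.

    With the members' values at a cell sorted ascending (1-based), the lower
    bound is the element at position ``max(1, floor(q% * |C|))`` and the
    upper bound the element at ``min(|C|, ceil((100 - q)% * |C|))``.
    """
    size = len(members)
    vals = np.sort(E.values[members], axis=0)
    li = max(1, math.floor(quartile_pct / 100.0 * size))
    ui = min(size, math.ceil((100.0 - quartile_pct) / 100.0 * size))
    return vals[li - 1].copy(), vals[ui - 1].copy()


def quant_similarity(gene_row: np.ndarray, cluster: QuantCluster) -> float:
    """Fraction of cells where the gene's value lies within the cluster bounds."""
    g = np.asarray(gene_row)
    inside = (g >= cluster.lower) & (g <= cluster.upper)
    return float(inside.mean())


def _spearman_pairs(
    Dp_rows: np.ndarray, genes: np.ndarray, order: np.ndarray, window_frac: float
) -> list[ScoredGenePair]:
    """Windowed Spearman scores over a gene group, on discretized rows.

    ``genes`` are original gene indices; ``order`` permutes positions within
    the group.  Ties get average ranks; a constant row correlates 0 with
    everything.
    """
    m, n = Dp_rows.shape
    ranks = rankdata(Dp_rows, axis=1).astype(np.float64)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    w = max(1, int(round(window_frac * m)))
    ordered = centered[order]
    onorm = norms[order]
    pos_i, pos_j, rs = [], [], []
    for d in range(1, min(w, m - 1) + 1):
        num = (ordered[:-d] * ordered[d:]).sum(axis=1)
        den = onorm[:-d] * onorm[d:]
        r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        p = np.arange(m - d)
        pos_i.append(p)
        pos_j.append(p + d)
        rs.append(r)
    pi = np.concatenate(pos_i)
    pj = np.concatenate(pos_j)
    r = np.concatenate(rs)
    seq = np.lexsort((pj, pi))
    gi, gj = genes[order[pi[seq]]], genes[order[pj[seq]]]
    lo, hi = np.minimum(gi, gj), np.maximum(gi, gj)
    return [ScoredGenePair(int(a), int(b), float(s)) for a, b, s in zip(lo, hi, r[seq])]


def initial_clusters_quant(
    group_genes: list[int],
    Dp: DiscretizedMatrix,
    E: ExpressionMatrix,
    window_frac: float = 0.05,
    pair_keep_frac: float = 1.0 / 1000.0,
    quartile_pct: float = 25.0,
    group_key: int = 0,
) -> tuple[list[QuantCluster], list[int]]:
    """Seed clusters within one bin-usage group from a windowed Spearman graph.

    The top ``floor(pair_keep_frac * C(|group|, 2))`` pairs (at least one)
    become edges; connected components with >= 3 genes become clusters.
    Groups with fewer than 3 genes yield no clusters.
    """
    genes = np.asarray(sorted(group_genes))
    g = len(genes)
    if g < 3:
        return [], list(genes)
    rows = Dp.values[genes]
    zeros = (rows == 1).sum(axis=1)
    order = np.lexsort((np.arange(g), -zeros))
    pairs = _spearman_pairs(rows, genes, order, window_frac)
    e_keep = max(1, n_pairs_to_keep(g, pair_keep_frac))
    scores = np.array([p.score for p in pairs])
    top = np.argsort(-scores, kind="stable")[:e_keep]
    top.sort()
    local = {int(gi): i for i, gi in enumerate(genes)}
    edges = np.array(
        [[local[pairs[t].gene_i], local[pairs[t].gene_j]] for t in top], dtype=np.int64
    )
    graph = GeneGraph(n_vertices=g, edges=edges)
    clusters, unassigned = [], []
    for comp in graph.components():
        orig = [int(genes[v]) for v in comp]
        if len(comp) >= 3:
            clusters.append(QuantCluster.from_members(orig, E, quartile_pct, group_key))
        else:
            unassigned.extend(orig)
    return clusters, sorted(unassigned)


def assign_remaining_genes_quant(
    clusters: list[QuantCluster],
    unassigned: list[int],
    rho: float,
    order_key: dict[int, int],
    E: ExpressionMatrix,
    quartile_pct: float = 25.0,
    min_gene_cluster: int = 3,
    group_key: int = 0,
) -> list[QuantCluster]:
    """Sweep a group's unassigned genes into clusters by containment similarity.

    Same control flow as LC1's sweep: join the argmax cluster when the
    similarity strictly exceeds ``rho`` (bounds are re-estimated after every
    join), otherwise open a singleton; prune clusters below
    ``min_gene_cluster`` at the end.
    """
    clusters = list(clusters)
    pool = sorted(unassigned, key=lambda g: order_key[g])
    if not pool:
        return [c for c in clusters if c.size >= min_gene_cluster]
    n = E.values.shape[1]
    cap = len(clusters) + len(pool)
    TL = np.zeros((cap, n))
    TU = np.zeros((cap, n))
    for i, c in enumerate(clusters):
        TL[i], TU[i] = c.lower, c.upper
    live = len(clusters)
    for g in pool:
        d = E.values[g]
        if live:
            sims = ((d >= TL[:live]) & (d <= TU[:live])).mean(axis=1)
            j = int(np.argmax(sims))
            best = float(sims[j])
        else:
            j, best = -1, -np.inf
        if best > rho:
            clusters[j].add(g, E, quartile_pct)
            TL[j], TU[j] = clusters[j].lower, clusters[j].upper
        else:
            c = QuantCluster.from_members([g], E, quartile_pct, group_key)
            clusters.append(c)
            TL[live], TU[live] = c.lower, c.upper
            live += 1
    return [c for c in clusters if c.size >= min_gene_cluster]


def build_q2(clusters: list[QuantCluster], cell_ids: list[str]) -> LandmarkMatrix:
    """Stack cluster templates (mean profiles) into the cells x landmarks matrix Q2.

    Clusters are ordered by ascending bin-usage group, then creation order
    within the group.
    """
    if not clusters:
        raise ValueError("no landmarks to build Q2 from")
    ordered = sorted(range(len(clusters)), key=lambda i: clusters[i].group)
    values = np.stack([clusters[i].template for i in ordered], axis=1)
    return LandmarkMatrix(
        cell_ids=list(cell_ids),
        landmark_ids=[f"LM2_{r}" for r in range(len(clusters))],
        values=values,
    )


def build_quantitative_landmarks(
    E: ExpressionMatrix, params: ScqaParams | None = None
) -> tuple[LandmarkMatrix, list[QuantCluster]]:
    """Run the full LC2 stage on a pre-processed (scaled) matrix."""
    params = params or ScqaParams()
    Dp = discretize(E, params.n_bins)
    groups = group_by_bin_usage(Dp)
    zeros = (Dp.values == 1).sum(axis=1)
    order_key = {
        g: i
        for i, g in enumerate(np.lexsort((np.arange(len(zeros)), -zeros)))
    }
    all_clusters: list[QuantCluster] = []
    for usage, genes in groups.items():  # ascending usage order
        if len(genes) < params.min_gene_cluster:
            continue
        clusters, unassigned = initial_clusters_quant(
            genes, Dp, E, params.window_frac, params.pair_keep_frac,
            params.quartile_pct, usage,
        )
        clusters = assign_remaining_genes_quant(
            clusters, unassigned, params.rho, order_key, E,
            params.quartile_pct, params.min_gene_cluster, usage,
        )
        all_clusters.extend(clusters)
    if not all_clusters:
        raise ValueError("no quantitative gene cluster survived pruning")
    logger.info("LC2: %d landmarks across %d bin-usage groups",
                len(all_clusters), len(groups))
    return build_q2(all_clusters, E.cell_ids), all_clusters
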