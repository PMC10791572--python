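"""Qualitative landmark constructor (LC1).

Genes are reduced to their binary detection patterns (expressed / not
expressed across cells) and clustered by pattern similarity; each retained
cluster's consensus pattern becomes one *landmark*, a column of the
qualitative cell-landmark matrix ``Q1``.  Observed zeros are treated as
potential dropouts: when a candidate gene is silent at a cell where the
cluster consensus is "on", the mismatch is discounted by the cluster's
*subsidiary* value ``a_k = max(0.5 - mean member expression at cell k, 0)``
— the dimmer the cluster is at that cell, the more plausible a dropout and
the smaller the penalty.

Pipeline: sort genes by decreasing zero count, score pairs within a sliding
window of that order by normalized Hamming similarity, keep the top
one-thousandth of all possible pairs as graph edges, seed clusters from
connected components with >= 3 genes, then sweep the remaining genes —
each joins its most similar cluster if the similarity strictly exceeds
``rho``, otherwise it opens a new singleton cluster that later genes may
join.  Clusters with fewer than ``min_gene_cluster`` members are dropped.
The whole stage is deterministic: every tie is broken by index order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .preprocess import ExpressionMatrix, ScqaParams

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMatrix",
    "ScoredGenePair",
    "QualCluster",
    "LandmarkMatrix",
    "binarize",
    "order_by_zeros",
    "windowed_pair_scores",
    "build_gene_graph",
    "initial_clusters",
    "gene_cluster_similarity",
    "assign_remaining_genes",
    "build_q1",
    "build_qualitative_landmarks",
]


@dataclass
class BinaryMatrix:
    """Detection-pattern matrix: entry 1 iff the gene is expressed in the cell."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # (m, n) uint8 in {0, 1}


class ScoredGenePair(NamedTuple):
    gene_i: int  # original gene index, gene_i < gene_j
    gene_j: int
    score: float  # 1 - hamming/n, in [0, 1]


@dataclass
class QualCluster:
    """A gene cluster with its consensus (template) and subsidiary vectors.

    ``template_mean`` is the per-cell mean of the members' binary patterns;
    ``template`` is its binarization at 0.5 (>= 0.5 -> 1); ``subsidiary`` is
    ``max(0.5 - mean member scaled expression, 0)`` per cell, in [0, 0.5].
    Running sums are kept so joins are O(n).
    """

    members: list[int]
    binary_sum: np.ndarray  # sum of members' binary rows
    expr_sum: np.ndarray  # sum of members' scaled expression rows

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def template_mean(self) -> np.ndarray:
        return self.binary_sum / self.size

    @property
    def template(self) -> np.ndarray:
        return (self.template_mean >= 0.5).astype(np.uint8)

    @property
    def subsidiary(self) -> np.ndarray:
        return np.maximum(0.5 - self.expr_sum / self.size, 0.0)

    @classmethod
    def from_members(
        cls, members: list[int], binary: np.ndarray, expr: np.ndarray
    ) -> "QualCluster":
        idx = list(members)
        return cls(
            members=idx,
            binary_sum=binary[idx].sum(axis=0, dtype=np.float64),
            expr_sum=expr[idx].sum(axis=0, dtype=np.float64),
        )

    def add(self, gene: int, binary_row: np.ndarray, expr_row: np.ndarray) -> None:
        self.members.append(gene)
        self.binary_sum = self.binary_sum + binary_row
        self.expr_sum = self.expr_sum + expr_row


@dataclass
class LandmarkMatrix:
    """Cells x landmarks consensus matrix (Q1: binary, Q2: values in [0, 1])."""

    cell_ids: list[str]
    landmark_ids: list[str]
    values: np.ndarray  # (n_cells, n_landmarks)

    @property
    def n_landmarks(self) -> int:
        return self.values.shape[1]


def binarize(E: ExpressionMatrix) -> BinaryMatrix:
    """Binary detection pattern: 1 wherever expression is strictly positive."""
    return BinaryMatrix(
        gene_ids=list(E.gene_ids),
        cell_ids=list(E.cell_ids),
        values=(E.values > 0).astype(np.uint8),
    )


def order_by_zeros(B: BinaryMatrix) -> np.ndarray:
    """Gene order of decreasing zero count; ties by ascending gene index."""
    zeros = (B.values == 0).sum(axis=1)
    return np.lexsort((np.arange(len(zeros)), -zeros))


def windowed_pair_scores(
    B: BinaryMatrix, order: np.ndarray, window_frac: float = 0.05
) -> list[ScoredGenePair]:
    """Score gene pairs within +-``round(window_frac * m)`` positions of the order.

    The score of a pair is ``1 - h/n`` with ``h`` the Hamming distance of
    the two binary patterns.  Each unordered pair is scored once; pairs are
    returned ordered by their window positions (earlier, then closer).
    """
    m, n = B.values.shape
    if m < 2:
        raise ValueError("need at least two genes")
    w = max(1, int(round(window_frac * m)))
    ordered = B.values[order]
    pos_i, pos_j, hams = [], [], []
    for d in range(1, min(w, m - 1) + 1):
        h = (ordered[:-d] != ordered[d:]).sum(axis=1)
        p = np.arange(m - d)
        pos_i.append(p)
        pos_j.append(p + d)
        hams.append(h)
    pi = np.concatenate(pos_i)
    pj = np.concatenate(pos_j)
    h = np.concatenate(hams)
    seq = np.lexsort((pj, pi))  # deterministic pair order: by (pos_i, pos_j)
    scores = 1.0 - h[seq] / n
    gi, gj = order[pi[seq]], order[pj[seq]]
    lo, hi = np.minimum(gi, gj), np.maximum(gi, gj)
    return [
        ScoredGenePair(int(a), int(b), float(s)) for a, b, s in zip(lo, hi, scores)
    ]


@dataclass
class GeneGraph:
    """Undirected graph over all ``m`` genes with the retained top pairs as edges."""

    n_vertices: int
    edges: np.ndarray  # (E, 2) gene indices

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def components(self) -> list[list[int]]:
        """Connected components as sorted index lists, ordered by smallest member."""
        if self.n_edges:
            adj = coo_matrix(
                (np.ones(self.n_edges), (self.edges[:, 0], self.edges[:, 1])),
                shape=(self.n_vertices, self.n_vertices),
            )
        else:
            adj = coo_matrix((self.n_vertices, self.n_vertices))
        _, comp = connected_components(adj, directed=False)
        out: dict[int, list[int]] = {}
        for v, c in enumerate(comp):
            out.setdefault(int(c), []).append(v)
        return [sorted(vs) for _, vs in sorted(out.items(), key=lambda kv: kv[1][0])]


def n_pairs_to_keep(m: int, pair_keep_frac: float = 1.0 / 1000.0) -> int:
    """Number of retained edges: ``floor(pair_keep_frac * C(m, 2))``."""
    return math.floor(pair_keep_frac * m * (m - 1) / 2)


def build_gene_graph(
    pairs: list[ScoredGenePair], m: int, pair_keep_frac: float = 1.0 / 1000.0
) -> GeneGraph:
    """Keep the top ``floor(pair_keep_frac * C(m, 2))`` pairs by score as edges.

    Ties are resolved by the order pairs were produced in (stable sort).
    """
    e_keep = n_pairs_to_keep(m, pair_keep_frac)
    if e_keep == 0:
        raise ValueError(f"pair retention rule keeps zero of C({m},2) pairs")
    scores = np.array([p.score for p in pairs])
    top = np.argsort(-scores, kind="stable")[:e_keep]
    top.sort()  # preserve generation order among the kept pairs
    edges = np.array([[pairs[t].gene_i, pairs[t].gene_j] for t in top], dtype=np.int64)
    return GeneGraph(n_vertices=m, edges=edges)


def initial_clusters(
    graph: GeneGraph,
    B: BinaryMatrix,
    E: ExpressionMatrix,
    min_component: int = 3,
) -> tuple[list[QualCluster], list[int]]:
    """Seed clusters from connected components with >= ``min_component`` genes.

    Genes in smaller components are returned as the unassigned pool.
    """
    clusters, unassigned = [], []
    for comp in graph.components():
        if len(comp) >= min_component:
            clusters.append(QualCluster.from_members(comp, B.values, E.values))
        else:
            unassigned.extend(comp)
    return clusters, sorted(unassigned)


def gene_cluster_similarity(gene_row: np.ndarray, cluster: QualCluster) -> float:
    """Mean per-cell similarity increment between a binary pattern and a cluster.

    A cell contributes 1 when the gene matches the template, 0 when the gene
    is on where the template is off, and the subsidiary value (dropout
    allowance) when the gene is off where the template is on.
    """
    t = cluster.template
    a = cluster.subsidiary
    g = np.asarray(gene_row)
    mu = np.where(g == t, 1.0, np.where(g == 1, 0.0, a))
    return float(mu.mean())


def _similarities_to_all(
    g: np.ndarray, T: np.ndarray, A: np.ndarray
) -> np.ndarray:
    """Vectorized gene-vs-all-clusters similarity (rows of T/A are clusters)."""
    mu = np.where(g[None, :] == T, 1.0, np.where(g[None, :] == 1, 0.0, A))
    return mu.mean(axis=1)


def assign_remaining_genes(
    clusters: list[QualCluster],
    unassigned: list[int],
    rho: float,
    order: np.ndarray,
    B: BinaryMatrix,
    E: ExpressionMatrix,
    min_gene_cluster: int = 3,
    rho_schedule: tuple[float, ...] | None = None,
) -> list[QualCluster]:
    """Sweep unassigned genes (in sorted order) into clusters; then prune.

    A gene joins the cluster of maximal similarity when that similarity
    strictly exceeds ``rho``; otherwise it opens a singleton cluster that
    later genes in the sweep may join.  After the sweep, clusters smaller
    than ``min_gene_cluster`` are dropped.  An optional ``rho_schedule``
    runs further sweeps at (typically lower) thresholds over the genes freed
    by pruning.
    """
    schedule = tuple(rho_schedule) if rho_schedule else (rho,)
    n = B.values.shape[1]
    pos = {int(g): i for i, g in enumerate(order)}
    clusters = list(clusters)
    pool = sorted(unassigned, key=lambda g: pos[g])

    for round_rho in schedule:
        # growable stacked template/subsidiary arrays for vectorized argmax
        cap = len(clusters) + len(pool)
        T = np.zeros((cap, n), dtype=np.uint8)
        A = np.zeros((cap, n), dtype=np.float64)
        for idx, c in enumerate(clusters):
            T[idx] = c.template
            A[idx] = c.subsidiary
        live = len(clusters)
        for g in pool:
            b = B.values[g]
            d = E.values[g]
            if live:
                sims = _similarities_to_all(b, T[:live], A[:live])
                j = int(np.argmax(sims))
                best = sims[j]
            else:
                j, best = -1, -np.inf
            if best > round_rho:
                clusters[j].add(g, b, d)
                T[j] = clusters[j].template
                A[j] = clusters[j].subsidiary
            else:
                c = QualCluster.from_members([g], B.values, E.values)
                clusters.append(c)
                T[live] = c.template
                A[live] = c.subsidiary
                live += 1
        kept = [c for c in clusters if c.size >= min_gene_cluster]
        pruned = [c for c in clusters if c.size < min_gene_cluster]
        pool = sorted((g for c in pruned for g in c.members), key=lambda g: pos[g])
        clusters = kept
        if not pool:
            break

    if not clusters:
        raise ValueError("no gene cluster survived pruning")
    return clusters


def build_q1(clusters: list[QualCluster], cell_ids: list[str]) -> LandmarkMatrix:
    """Stack the clusters' binary templates into the cells x landmarks matrix Q1."""
    if not clusters:
        raise ValueError("no landmarks to build Q1 from")
    values = np.stack([c.template for c in clusters], axis=1).astype(np.float64)
    return LandmarkMatrix(
        cell_ids=list(cell_ids),
        landmark_ids=[f"LM1_{r}" for r in range(len(clusters))],
        values=values,
    )


def build_qualitative_landmarks(
    E: ExpressionMatrix, params: ScqaParams | None = None
) -> tuple[LandmarkMatrix, list[QualCluster]]:
    """Run the full LC1 stage on a pre-processed (scaled) matrix."""
    params = params or ScqaParams()
    B = binarize(E)
    order = order_by_zeros(B)
    pairs = windowed_pair_scores(B, order, params.window_frac)
    graph = build_gene_graph(pairs, E.n_genes, params.pair_keep_frac)
    clusters, unassigned = initial_clusters(graph, B, E)
    logger.info(
        "LC1: %d initial clusters from %d edges; %d genes to assign",
        len(clusters), graph.n_edges, len(unassigned),
    )
    clusters = assign_remaining_genes(
        clusters, unassigned, params.rho, order, B, E,
        params.min_gene_cluster, params.rho_schedule,
    )
    logger.info("LC1: %d landmarks retained", len(clusters))
    return build_q1(clusters, E.cell_ids), clusters
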