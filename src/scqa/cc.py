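"""Cluster constructor (CC): seeded bidirectional label propagation on cells.

Cells are nodes of a directed kNN graph whose edge weights are Pearson
correlations between rows of the quantitative landmark matrix ``Q2`` (each
node keeps its ``0.1 n`` most similar cells as out-neighbors, ``0.05 n``
for datasets of 10,000 cells or more).  Clustering proceeds in four steps:

1. **Seed generation** — cells are grouped by exact equality of their
   binary ``Q1`` rows; each node's density is the mean weight of its
   out-edges; the threshold ``beta`` is the smallest of the per-group
   maximum densities, every node at or above it is a seed candidate, and
   mutually-neighboring candidates are merged (transitively) into seeds.
2. **Label propagation** — unlabeled nodes, visited in decreasing density,
   join the cluster with the highest two-hop similarity (a convex mix,
   weighted ``alpha``, of out-edge and in-edge evidence over directed paths
   of length <= 2) provided it strictly beats their similarity to the
   unlabeled set; otherwise they stay unlabeled for now.
3. **Pruning and merging** — clusters below a minimum size are dissolved;
   each remaining cluster, smallest first, is merged into a strictly larger
   one when it sends more out-edges into it than it keeps internally; a
   cluster that has assimilated another is itself never merged away.
4. **Cluster expansion** — every still-unlabeled node either joins the
   cluster into which it sends the most out-edges above that cluster's
   average internal connectivity, or founds a new singleton cluster;
   refinement sweeps then reassign nodes until labels are stable.

Everything is deterministic: no randomness, all ties broken by index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .lc1 import LandmarkMatrix, QualCluster, build_qualitative_landmarks
from .lc2 import QuantCluster, build_quantitative_landmarks
from .preprocess import ExpressionMatrix, ScqaParams, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "CellGraph",
    "ClusterState",
    "ScqaResult",
    "build_cell_graph",
    "group_cells",
    "node_densities",
    "generate_seeds",
    "node_cluster_similarity",
    "node_unlabeled_similarity",
    "propagate_labels",
    "propagate_to_convergence",
    "prune_and_merge",
    "expand_clusters",
    "run_scqa",
]


# ---------------------------------------------------------------------------
# graph construction


@dataclass
class CellGraph:
    """Directed kNN graph over cells with Pearson edge weights.

    ``out[i]`` holds the ``k_out`` out-neighbors of node ``i`` (most similar
    cells, self excluded, ties by index); ``adj`` is the boolean adjacency
    (``adj[i, j]`` iff ``j in out[i]``) and ``weights`` the full pairwise
    similarity matrix (used only on edges).
    """

    n: int
    k_out: int
    out: np.ndarray  # (n, k_out) int
    adj: np.ndarray  # (n, n) bool
    weights: np.ndarray  # (n, n) float

    def out_neighbors(self, i: int) -> np.ndarray:
        return self.out[i]

    def in_neighbors(self, i: int) -> np.ndarray:
        return np.where(self.adj[:, i])[0]


def k_out_for(n: int) -> int:
    """Out-degree rule: 10% of cells below 10,000 cells, 5% at or above."""
    k = int(np.floor(0.1 * n)) if n < 10000 else int(np.floor(0.05 * n))
    return max(1, min(k, n - 1))


def pearson_rows(M: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of rows; constant rows correlate 0."""
    centered = M - M.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    corr = (centered @ centered.T) / np.outer(safe, safe)
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    return corr


def build_cell_graph(Q2: LandmarkMatrix) -> CellGraph:
    """Directed kNN graph from Pearson similarity of Q2 rows."""
    values = Q2.values
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    if values.shape[1] < 2:
        raise ValueError("Pearson similarity needs at least 2 landmarks")
    W = pearson_rows(values)
    np.fill_diagonal(W, -np.inf)  # never a neighbor of itself
    k = k_out_for(n)
    # top-k by similarity, ties by ascending index
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), -W), axis=1)
    out = np.ascontiguousarray(order[:, :k])
    adj = np.zeros((n, n), dtype=bool)
    adj[np.repeat(np.arange(n), k), out.ravel()] = True
    np.fill_diagonal(W, 0.0)
    return CellGraph(n=n, k_out=k, out=out, adj=adj, weights=W)


# ---------------------------------------------------------------------------
# seed generation


def group_cells(Q1: LandmarkMatrix) -> list[list[int]]:
    """Partition cells by exact equality of their Q1 rows.

    Groups are ordered by their first cell; cells within a group ascending.
    """
    seen: dict[bytes, list[int]] = {}
    rows = np.ascontiguousarray(Q1.values)
    for i in range(rows.shape[0]):
        seen.setdefault(rows[i].tobytes(), []).append(i)
    return list(seen.values())


def node_densities(G: CellGraph) -> np.ndarray:
    """Density of a node: mean similarity over its out-neighbors."""
    return G.weights[np.arange(G.n)[:, None], G.out].mean(axis=1)


@dataclass
class ClusterState:
    """Mutable per-cell labeling state during cluster construction.

    ``labels[i] = -1`` marks an unlabeled cell; non-negative labels index
    ``clusters``.  ``order`` fixes the processing order (decreasing density,
    ties by cell index).  ``assimilators`` records labels that merged
    another cluster in and so may not themselves be merged away.
    """

    labels: np.ndarray
    densities: np.ndarray
    beta: float
    order: np.ndarray
    clusters: dict[int, list[int]] = field(default_factory=dict)
    assimilators: set[int] = field(default_factory=set)
    next_label: int = 0

    @property
    def unlabeled(self) -> np.ndarray:
        return np.where(self.labels < 0)[0]

    def new_cluster(self, members: list[int]) -> int:
        lbl = self.next_label
        self.next_label += 1
        self.clusters[lbl] = sorted(members)
        self.labels[self.clusters[lbl]] = lbl
        return lbl

    def assign(self, node: int, label: int) -> None:
        self.labels[node] = label
        self.clusters[label].append(node)

    def dissolve(self, label: int) -> None:
        for node in self.clusters.pop(label):
            self.labels[node] = -1


def generate_seeds(
    G: CellGraph, groups: list[list[int]], densities: np.ndarray
) -> ClusterState:
    """Select high-density seed cells guided by the Q1 groups.

    ``beta`` is the minimum over groups of the maximum in-group density;
    all nodes with density >= beta are candidates.  Candidates that are
    mutually out-neighbors are unioned transitively into a single seed;
    each seed becomes an initial labeled cluster.
    """
    if not groups:
        raise ValueError("need at least one cell group")
    beta = min(float(densities[g].max()) for g in groups)
    candidates = np.where(densities >= beta)[0]
    # union-find over the mutual-neighbor relation among candidates
    parent = {int(c): int(c) for c in candidates}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cand = set(parent)
    for i in candidates:
        for j in G.out[i]:
            j = int(j)
            if j in cand and G.adj[j, i]:  # mutual
                ri, rj = find(int(i)), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    seeds: dict[int, list[int]] = {}
    for c in candidates:
        seeds.setdefault(find(int(c)), []).append(int(c))

    labels = np.full(G.n, -1, dtype=np.int64)
    order = np.lexsort((np.arange(G.n), -densities))
    state = ClusterState(labels=labels, densities=densities, beta=beta, order=order)
    for root in sorted(seeds):
        state.new_cluster(seeds[root])
    logger.info(
        "seeds: beta=%.4f, %d candidates -> %d seeds", beta, len(candidates),
        len(state.clusters),
    )
    return state


# ---------------------------------------------------------------------------
# label propagation


def _term(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def node_cluster_similarity(
    ni: int, label: int, state: ClusterState, G: CellGraph, alpha: float = 0.5
) -> float:
    """Two-hop similarity between an unlabeled node and a cluster.

    Out-evidence: weights of direct out-edges into the cluster plus, for
    each unlabeled out-neighbor ``r``, the weights of ``r``'s out-edges into
    the cluster; normalized by the number of such length-<=2 paths.  The
    in-evidence term mirrors this over in-edges.  A term with no paths
    contributes 0.  The unlabeled set excludes ``ni`` itself.
    """
    in_cluster = np.zeros(G.n, dtype=bool)
    in_cluster[state.clusters[label]] = True
    unlabeled = state.labels < 0
    unlabeled = unlabeled.copy()
    unlabeled[ni] = False

    W, A = G.weights, G.adj
    # out direction: paths ni -> Cj and ni -> r(unlabeled) -> Cj
    oi = G.out[ni]
    direct = oi[in_cluster[oi]]
    mid = oi[unlabeled[oi]]
    out_num = W[ni, direct].sum()
    out_den = float(len(direct))
    if len(mid):
        sub = A[mid][:, in_cluster]
        out_num += (W[mid][:, in_cluster] * sub).sum()
        out_den += sub.sum()
    # in direction: paths Cj -> ni and Cj -> r(unlabeled) -> ni
    ii = np.where(A[:, ni])[0]
    directi = ii[in_cluster[ii]]
    midi = ii[unlabeled[ii]]
    in_num = W[directi, ni].sum()
    in_den = float(len(directi))
    if len(midi):
        sub = A[:, midi][in_cluster, :]
        in_num += (W[:, midi][in_cluster, :] * sub).sum()
        in_den += sub.sum()
    return alpha * _term(out_num, out_den) + (1 - alpha) * _term(in_num, in_den)


def node_unlabeled_similarity(
    ni: int, state: ClusterState, G: CellGraph, alpha: float = 0.5
) -> float:
    """Mean similarity between a node and the other unlabeled nodes."""
    unlabeled = state.labels < 0
    unlabeled = unlabeled.copy()
    unlabeled[ni] = False
    oi = G.out[ni]
    out_set = oi[unlabeled[oi]]
    ii = np.where(G.adj[:, ni])[0]
    in_set = ii[unlabeled[ii]]
    out_term = G.weights[ni, out_set].mean() if len(out_set) else 0.0
    in_term = G.weights[in_set, ni].mean() if len(in_set) else 0.0
    return alpha * float(out_term) + (1 - alpha) * float(in_term)


def propagate_labels(
    state: ClusterState, G: CellGraph, alpha: float = 0.5
) -> ClusterState:
    """One sweep: each unlabeled node (decreasing density) joins its best
    cluster if that similarity strictly beats its similarity to the
    unlabeled set; otherwise it stays unlabeled."""
    for ni in state.order:
        ni = int(ni)
        if state.labels[ni] >= 0:
            continue
        sims = {
            lbl: node_cluster_similarity(ni, lbl, state, G, alpha)
            for lbl in sorted(state.clusters)
        }
        best_lbl = max(sims, key=lambda l: (sims[l], -l))
        if sims[best_lbl] > node_unlabeled_similarity(ni, state, G, alpha):
            state.assign(ni, best_lbl)
    return state


def propagate_to_convergence(
    state: ClusterState, G: CellGraph, alpha: float = 0.5, max_iter: int = 50
) -> ClusterState:
    """Repeat propagation sweeps until no node changes in a full sweep.

    As clusters grow and the unlabeled set shrinks, nodes that previously
    sided with the unlabeled pool become assignable, so sweeps are repeated
    to a fixed point (guaranteed: each productive sweep strictly shrinks U).
    """
    for _ in range(max_iter):
        before = len(state.unlabeled)
        propagate_labels(state, G, alpha)
        if len(state.unlabeled) == before:
            break
    return state


# ---------------------------------------------------------------------------
# pruning, merging, expansion


def cluster_cluster_similarity(ci: list[int], cj: list[int], G: CellGraph) -> int:
    """Number of directed edges from cluster ``ci`` into cluster ``cj``."""
    mask = np.zeros(G.n, dtype=bool)
    mask[cj] = True
    return int(mask[G.out[ci]].sum())


def internal_edges(c: list[int], G: CellGraph) -> int:
    """Number of directed edges with both endpoints in the cluster."""
    return cluster_cluster_similarity(c, c, G)


def prune_and_merge(
    state: ClusterState, G: CellGraph, min_cluster_size: int
) -> ClusterState:
    """Dissolve undersized clusters, then merge weakly-bound small clusters.

    Visiting clusters smallest first, a cluster is merged into the strictly
    larger cluster that receives most of its out-edges whenever that count
    strictly exceeds its own internal edge count.  A cluster that has
    assimilated another is never merged away itself.
    """
    for lbl in [l for l, c in state.clusters.items() if len(c) < min_cluster_size]:
        state.dissolve(lbl)
    if not state.clusters:
        raise ValueError("every cluster fell below the minimum size")

    for lbl in sorted(state.clusters, key=lambda l: (len(state.clusters[l]), l)):
        if lbl not in state.clusters or lbl in state.assimilators:
            continue
        ci = state.clusters[lbl]
        larger = [l for l in state.clusters if len(state.clusters[l]) > len(ci)]
        if not larger:
            continue
        scores = {l: cluster_cluster_similarity(ci, state.clusters[l], G) for l in larger}
        best = max(sorted(scores), key=lambda l: (scores[l], -l))
        if scores[best] > internal_edges(ci, G):
            members = state.clusters.pop(lbl)
            state.clusters[best].extend(members)
            state.clusters[best].sort()
            state.labels[members] = best
            state.assimilators.add(best)
    return state


def expand_clusters(state: ClusterState, G: CellGraph) -> ClusterState:
    """Label every remaining node, then refine until labels are stable.

    An unlabeled node joins the *retained* cluster maximizing
    ``|ON_i ∩ C_j| - A(C_j)``, where ``A(C_j)`` is the average number of
    out-neighbors inside ``C_j`` over the still-unlabeled nodes — a
    relative-attachment score: the node must be better connected to the
    cluster than the typical unassigned cell.  If every difference is
    negative the node is an outlier and founds a new cluster.  Candidate
    clusters and the reference levels are the snapshot at entry, so new
    clusters never compete for the remaining nodes; propagation is a fixed
    point afterwards (every node labeled), making the labeling final.
    """
    retained = sorted(state.clusters)
    pending = state.unlabeled
    if not len(pending):
        return state
    counts = {}  # per cluster: |ON_i ∩ C_j| for every node i
    for lbl in retained:
        mask = np.zeros(G.n, dtype=bool)
        mask[state.clusters[lbl]] = True
        counts[lbl] = mask[G.out].sum(axis=1)
    avg_attach = {lbl: float(counts[lbl][pending].mean()) for lbl in retained}
    for ni in state.order:
        ni = int(ni)
        if state.labels[ni] >= 0:
            continue
        diffs = {lbl: float(counts[lbl][ni]) - avg_attach[lbl] for lbl in retained}
        best = max(sorted(diffs), key=lambda l: (diffs[l], -l)) if diffs else None
        if best is None or diffs[best] < 0:
            state.new_cluster([ni])
        else:
            state.assign(ni, best)
    return state


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class ScqaResult:
    """Bundle returned by :func:`run_scqa`."""

    labels: np.ndarray  # (n,) 0-based contiguous cluster labels
    cell_ids: list[str]
    gene_ids: list[str]  # genes of the working (pre-processed) matrix
    Q1: LandmarkMatrix | None
    Q2: LandmarkMatrix | None
    lc1_clusters: list[QualCluster] | None
    lc2_clusters: list[QuantCluster] | None

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_landmarks(self) -> dict[int, int]:
        """For each cell cluster, the landmark (Q2 column, or Q1 in its
        absence) with highest mean value over the cluster's cells."""
        Q = self.Q2 if self.Q2 is not None else self.Q1
        out = {}
        for lbl in np.unique(self.labels):
            members = self.labels == lbl
            out[int(lbl)] = int(np.argmax(Q.values[members].mean(axis=0)))
        return out


def _binarize_landmarks(Q: LandmarkMatrix, threshold: float = 0.5) -> LandmarkMatrix:
    return LandmarkMatrix(
        cell_ids=list(Q.cell_ids),
        landmark_ids=list(Q.landmark_ids),
        values=(Q.values >= threshold).astype(np.float64),
    )


def cluster_cells(
    Q_seed: LandmarkMatrix,
    Q_prop: LandmarkMatrix,
    params: ScqaParams | None = None,
) -> np.ndarray:
    """Run the four CC steps given a seeding matrix and a propagation matrix.

    ``Q_seed`` (binary rows) defines the cell groups guiding seed selection;
    ``Q_prop`` defines the kNN graph and its Pearson weights.
    """
    params = params or ScqaParams()
    G = build_cell_graph(Q_prop)
    groups = group_cells(Q_seed)
    densities = node_densities(G)
    state = generate_seeds(G, groups, densities)
    state = propagate_to_convergence(state, G, params.alpha, params.max_iter)
    min_size = params.min_cell_cluster
    if min_size is None:
        min_size = max(3, int(round(0.01 * G.n)))
    state = prune_and_merge(state, G, min_size)
    state = propagate_to_convergence(state, G, params.alpha, params.max_iter)
    state = expand_clusters(state, G)
    # relabel 0..K-1 in order of first appearance by cell index
    labels = state.labels
    remap: dict[int, int] = {}
    final = np.empty_like(labels)
    for i, lbl in enumerate(labels):
        if int(lbl) not in remap:
            remap[int(lbl)] = len(remap)
        final[i] = remap[int(lbl)]
    return final


def run_scqa(
    E: ExpressionMatrix,
    params: ScqaParams | None = None,
    mode: str = "full",
    preprocessed: bool = False,
) -> ScqaResult:
    """End-to-end pipeline: pre-process, build landmarks, cluster cells.

    ``mode`` selects the feature sets: ``"full"`` seeds from Q1 and
    propagates on Q2; ``"lc1_only"`` uses Q1 for both; ``"lc2_only"`` seeds
    from a binarized Q2 (threshold 0.5) and propagates on Q2.
    """
    if mode not in ("full", "lc1_only", "lc2_only"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or ScqaParams()
    D = E if preprocessed else preprocess(E, params)
    Q1 = Q2 = None
    lc1_clusters = lc2_clusters = None
    if mode in ("full", "lc1_only"):
        Q1, lc1_clusters = build_qualitative_landmarks(D, params)
    if mode in ("full", "lc2_only"):
        Q2, lc2_clusters = build_quantitative_landmarks(D, params)
    if mode == "full":
        labels = cluster_cells(Q1, Q2, params)
    elif mode == "lc1_only":
        labels = cluster_cells(Q1, Q1, params)
    else:
        labels = cluster_cells(_binarize_landmarks(Q2), Q2, params)
    logger.info("CC: %d cell clusters", len(np.unique(labels)))
    return ScqaResult(
        labels=labels,
        cell_ids=list(D.cell_ids),
        gene_ids=list(D.gene_ids),
        Q1=Q1,
        Q2=Q2,
        lc1_clusters=lc1_clusters,
        lc2_clusters=lc2_clusters,
    )
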