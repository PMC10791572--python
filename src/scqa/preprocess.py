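"""Loading and pre-processing of genes x cells expression matrices.

The working representation is a dense :class:`ExpressionMatrix` (genes as
rows, cells as columns, non-negative values).  Pre-processing performs three
steps, in order:

1. :func:`filter_genes` — drop genes detected in fewer than ``x%`` or more
   than ``(100 - x)%`` of cells (ubiquitous and near-silent genes carry no
   grouping information),
2. :func:`select_hvgs` — keep the most highly variable genes by a binned
   mean–dispersion z-score,
3. :func:`log_and_scale` — ``log1p`` transform followed by per-gene max
   scaling so every entry lies in ``[0, 1]`` and zeros stay exactly zero.

Cells are never filtered.  No imputation is performed: downstream stages
treat observed zeros (dropouts) as weak qualitative signal in their own
right rather than as missing data to be filled in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ScqaParams",
    "load_expression",
    "filter_genes",
    "select_hvgs",
    "log_and_scale",
    "preprocess",
]


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of non-negative expression values.

    Attributes
    ----------
    gene_ids
        Unique gene identifiers, one per row (length ``m``).
    cell_ids
        Unique cell identifiers, one per column (length ``n``).
    values
        ``(m, n)`` float array; entry ``[i, j]`` is the expression of gene
        ``i`` in cell ``j``.
    is_scaled
        True once entries have been mapped into ``[0, 1]`` by
        :func:`log_and_scale`.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    is_scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {m} matrix rows"
            )
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n} matrix columns"
            )
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell identifiers")
        if m and n and self.values.min() < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ScqaParams:
    """Tunable parameters of the pipeline with their default values.

    Parameters
    ----------
    filter_pct
        ``x`` in the gene filter: keep genes detected in between ``x%`` and
        ``(100 - x)%`` of cells (bounds inclusive).
    n_hvg
        Number of highly variable genes retained after filtering.
    rho
        Gene-to-cluster similarity threshold; a gene joins its best cluster
        only when the similarity strictly exceeds ``rho``.
    n_bins
        Number of expression bins ``k`` used by the quantitative landmark
        constructor (bin 1 is reserved for exact zeros).
    alpha
        Mixing weight in ``[0, 1]`` between out-edge and in-edge evidence
        when scoring a cell against a cluster on the directed graph.
    window_frac
        Fraction of the (sorted) gene list scanned on either side of a gene
        when scoring candidate gene pairs.
    pair_keep_frac
        Fraction of all possible gene pairs retained as edges of the gene
        similarity graph (one-thousandth by default).
    quartile_pct
        Percentile used for the lower/upper bound vectors of quantitative
        clusters (25 = quartiles).
    min_gene_cluster
        Gene clusters smaller than this are discarded after assignment.
    min_cell_cluster
        Cell clusters smaller than this are dissolved during pruning;
        ``None`` means ``max(3, round(0.01 n))``.
    rho_schedule
        Optional list of decreasing ``rho`` values for additional assignment
        rounds; by default a single round at ``rho`` is performed.
    max_iter
        Cap on label-refinement sweeps after cluster expansion.
    seed
        Seed for the synthetic-data generator only; the clustering pipeline
        itself is deterministic.
    """

    filter_pct: float = 2.5
    n_hvg: int = 2000
    rho: float = 0.7
    n_bins: int = 6
    alpha: float = 0.5
    window_frac: float = 0.05
    pair_keep_frac: float = 1.0 / 1000.0
    quartile_pct: float = 25.0
    min_gene_cluster: int = 3
    min_cell_cluster: int | None = None
    rho_schedule: tuple[float, ...] | None = None
    max_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.filter_pct < 50:
            raise ValueError("filter_pct must lie in (0, 50)")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


def load_expression(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells matrix from dense CSV/TSV or sparse Matrix Market.

    CSV/TSV layout: first column holds gene ids, header row holds cell ids.
    MTX layout: coordinate file with genes as rows, plus companion
    ``genes.tsv`` and ``barcodes.tsv`` (one id per line, first column used)
    in the same directory unless ``genes_path``/``cells_path`` are given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}.get(
            suffix
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=np.float64)
        return ExpressionMatrix(
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
            values=values,
        )
    if format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "barcodes.tsv"
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(p)
        mat = mmread(str(path))
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        gene_ids = [ln.split("\t")[0] for ln in _read_lines(genes_path)]
        cell_ids = [ln.split("\t")[0] for ln in _read_lines(cells_path)]
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
        return ExpressionMatrix(gene_ids=gene_ids, cell_ids=cell_ids, values=values)
    raise ValueError(f"unknown format {format!r}")


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def filter_genes(E: ExpressionMatrix, x: float = 2.5) -> ExpressionMatrix:
    """Keep genes detected in between ``x%`` and ``(100 - x)%`` of cells.

    Both boundaries are inclusive.  Gene order is preserved.  Raises if no
    gene survives.
    """
    if E.is_scaled:
        raise ValueError("filter_genes expects an unscaled matrix")
    frac = 100.0 * (E.values > 0).sum(axis=1) / E.n_cells
    keep = (frac >= x) & (frac <= 100.0 - x)
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(E.gene_ids, keep) if k],
        cell_ids=list(E.cell_ids),
        values=E.values[keep],
    )


def select_hvgs(E: ExpressionMatrix, n_hvg: int = 2000, n_mean_bins: int = 20) -> ExpressionMatrix:
    """Retain the ``n_hvg`` most highly variable genes.

    Dispersion (variance / mean) is z-scored within equal-count bins of the
    log mean so that variability is judged relative to genes of comparable
    abundance; genes are ranked by that z-score, ties broken by input order.
    If fewer than ``n_hvg`` genes are available the matrix is returned
    unchanged (with a warning); fewer than 10 genes is an error.
    """
    m = E.n_genes
    if m < 10:
        raise ValueError(f"only {m} genes remain; need at least 10")
    if m <= n_hvg:
        warnings.warn(
            f"requested {n_hvg} highly variable genes but only {m} are "
            "available; keeping all",
            stacklevel=2,
        )
        return E
    mean = E.values.mean(axis=1)
    var = E.values.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    log_mean = np.log(np.maximum(mean, 1e-12))
    # equal-count bins over the log-mean ranks
    n_bins = min(n_mean_bins, m)
    ranks = np.argsort(np.argsort(log_mean, kind="stable"), kind="stable")
    bins = (ranks * n_bins) // m
    z = np.empty(m, dtype=np.float64)
    for b in np.unique(bins):
        sel = bins == b
        d = dispersion[sel]
        sd = d.std()
        z[sel] = (d - d.mean()) / sd if sd > 0 else 0.0
    # top n_hvg by z-score, ties by gene index; keep original gene order
    order = np.lexsort((np.arange(m), -z))
    chosen = np.zeros(m, dtype=bool)
    chosen[order[:n_hvg]] = True
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(E.gene_ids, chosen) if k],
        cell_ids=list(E.cell_ids),
        values=E.values[chosen],
    )


def log_and_scale(E: ExpressionMatrix) -> ExpressionMatrix:
    """``log1p``-transform and scale each gene so its maximum is exactly 1.

    Zeros are preserved exactly (``log1p(0) = 0``), so the dropout pattern
    is untouched, and the transform is rank-preserving within every gene.
    A gene whose entries are all zero cannot be scaled and is an error
    (impossible after :func:`filter_genes`).
    """
    logv = np.log1p(E.values)
    gene_max = logv.max(axis=1)
    if np.any(gene_max <= 0):
        bad = [E.gene_ids[i] for i in np.where(gene_max <= 0)[0][:5]]
        raise ValueError(f"gene(s) with no positive expression: {bad}")
    scaled = logv / gene_max[:, None]
    return ExpressionMatrix(
        gene_ids=list(E.gene_ids),
        cell_ids=list(E.cell_ids),
        values=scaled,
        is_scaled=True,
    )


def preprocess(E: ExpressionMatrix, params: ScqaParams | None = None) -> ExpressionMatrix:
    """Full pre-processing chain: filter, select HVGs, log-transform, scale."""
    params = params or ScqaParams()
    out = filter_genes(E, params.filter_pct)
    logger.info("gene filter kept %d of %d genes", out.n_genes, E.n_genes)
    out = select_hvgs(out, params.n_hvg)
    out = log_and_scale(out)
    logger.info("working matrix: %d genes x %d cells", out.n_genes, out.n_cells)
    return out
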