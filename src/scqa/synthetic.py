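"""Synthetic scRNA-seq matrices with planted cell types and dropout.

The generator emulates the gross statistical features that drive the
pipeline: ``K`` planted cell types, a block of marker genes per type
(lognormal positives inside the type, zero elsewhere up to a small leak
rate), housekeeping genes expressed everywhere, unstructured noise genes,
and mean-dependent dropout — the probability that an observed entry is
zeroed follows a logistic curve in the gene's log mean, so dim genes lose
proportionally more entries, mimicking the empirical mean–dropout
relationship of real droplet data.

It makes no attempt at batch effects, trajectories, doublets or UMI depth
variation; it is a fixture, not a data model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate", "generate_quasi_trend_block"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-type generator.

    Defaults produce 5 types of 100 cells each with 30 marker genes per
    type, 100 housekeeping and 100 noise genes (350 genes x 500 cells), and
    moderate mean-dependent dropout.
    """

    n_types: int = 5
    cells_per_type: tuple[int, ...] | int = 100
    n_marker_genes_per_type: int = 30
    n_housekeeping: int = 100
    n_noise_genes: int = 300
    marker_leak_rate: float = 0.01
    dropout_shape: float = 0.4
    dropout_midpoint: float = 2.0  # expression level of half-maximal dropout
    dropout_scale: float = 0.3
    expression_scale: tuple[float, float] = (1.0, 0.5)  # lognormal (mu, sigma) of markers
    depth_sd: float = 0.3  # per-cell library-size factor, lognormal(0, depth_sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("need at least one cell type")
        if not 0 <= self.marker_leak_rate <= 1:
            raise ValueError("marker_leak_rate must lie in [0, 1]")
        if not 0 <= self.dropout_shape <= 1:
            raise ValueError("dropout_shape must lie in [0, 1]")

    @property
    def cells(self) -> tuple[int, ...]:
        if isinstance(self.cells_per_type, int):
            return (self.cells_per_type,) * self.n_types
        if len(self.cells_per_type) != self.n_types:
            raise ValueError("cells_per_type length must equal n_types")
        return tuple(self.cells_per_type)


def generate(spec: SyntheticSpec | None = None) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one synthetic dataset; returns the matrix and true type labels.

    Deterministic for a fixed ``spec.seed``.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    cells = spec.cells
    n = int(sum(cells))
    labels = np.repeat(np.arange(spec.n_types), cells)

    mu, sigma = spec.expression_scale
    blocks: list[np.ndarray] = []
    gene_ids: list[str] = []

    # type-specific marker blocks
    for t in range(spec.n_types):
        in_type = labels == t
        block = np.zeros((spec.n_marker_genes_per_type, n))
        block[:, in_type] = rng.lognormal(mu, sigma, (spec.n_marker_genes_per_type, in_type.sum()))
        leak = rng.random(block.shape) < spec.marker_leak_rate
        leak &= ~in_type[None, :]
        block[leak] = rng.lognormal(mu - 1.5, sigma, int(leak.sum()))
        blocks.append(block)
        gene_ids += [f"marker_t{t}_{g}" for g in range(spec.n_marker_genes_per_type)]

    # housekeeping genes: highly expressed everywhere (so their dropout is
    # negligible and the ubiquity filter removes them, as in real data)
    if spec.n_housekeeping:
        level = rng.lognormal(3.0, 0.3, spec.n_housekeeping)
        hk = level[:, None] * rng.lognormal(0.0, 0.2, (spec.n_housekeeping, n))
        blocks.append(hk)
        gene_ids += [f"housekeeping_{g}" for g in range(spec.n_housekeeping)]

    # unstructured noise genes: moderate detection probability and expression,
    # as in a real HVG panel's non-marker tail
    if spec.n_noise_genes:
        p_expr = rng.uniform(0.4, 0.7, spec.n_noise_genes)
        on = rng.random((spec.n_noise_genes, n)) < p_expr[:, None]
        noise = np.where(on, rng.lognormal(0.7, 0.5, (spec.n_noise_genes, n)), 0.0)
        blocks.append(noise)
        gene_ids += [f"noise_{g}" for g in range(spec.n_noise_genes)]

    values = np.vstack(blocks)

    # per-cell library-size variation: a lognormal depth factor scales every
    # gene of a cell, as sequencing depth does in real data
    if spec.depth_sd > 0:
        depth = rng.lognormal(0.0, spec.depth_sd, n)
        values = values * depth[None, :]

    # mean-dependent dropout: per-gene zeroing probability, logistic in the
    # log mean over expressing cells (the gene's abundance where it is on);
    # dropout_shape = 0 disables excess zeros entirely
    if spec.dropout_shape > 0:
        pos = values > 0
        n_pos = np.maximum(pos.sum(axis=1), 1)
        gene_mean = (values * pos).sum(axis=1) / n_pos
        z = (np.log1p(gene_mean) - np.log1p(spec.dropout_midpoint)) / spec.dropout_scale
        p_drop = spec.dropout_shape / (1.0 + np.exp(z))
        dropped = rng.random(values.shape) < p_drop[:, None]
        values = np.where(dropped, 0.0, values)

    E = ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=[f"cell_{j}" for j in range(n)],
        values=values,
    )
    return E, labels


def generate_quasi_trend_block(
    n_genes: int,
    base_profile: np.ndarray,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Genes that follow one expression trend up to monotone warping + noise.

    Each generated row is ``scale * base_profile ** p + noise`` with a
    gene-specific exponent ``p`` in [0.5, 2] — a monotone increasing
    transform, so the rank order of cells is (approximately) shared across
    the block.  Noise perturbs only cells where the base profile is
    positive, so the zero (dropout) pattern is preserved exactly.
    ``noise_sd = 0`` with the identity transform reproduces the base
    profile exactly.
    """
    base = np.asarray(base_profile, dtype=np.float64)
    if base.ndim != 1:
        raise ValueError("base_profile must be a 1-D vector")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_genes, base.size))
    pos = base > 0
    for g in range(n_genes):
        p = rng.uniform(0.5, 2.0) if noise_sd > 0 else 1.0
        scale = rng.uniform(0.5, 2.0) if noise_sd > 0 else 1.0
        row = scale * np.power(base, p)
        if noise_sd > 0:
            sd = noise_sd * max(row[pos].std(), 1e-12) if pos.any() else 0.0
            row[pos] = row[pos] + rng.normal(0.0, sd, int(pos.sum()))
        rows[g] = np.where(pos, np.maximum(row, 1e-9), 0.0)
    return rows
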