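"""Shared fixtures: tiny hand-built matrices, synthetic datasets, graphs."""

from __future__ import annotations

import numpy as np
import pytest

from scqa.cc import CellGraph
from scqa.preprocess import ExpressionMatrix, preprocess
from scqa.synthetic import SyntheticSpec, generate, generate_quasi_trend_block


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = np.array(
        [
            [0.0, 2.0, 1.0],
            [3.0, 0.0, 0.5],
            [1.0, 1.0, 1.0],
        ]
    )
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"], cell_ids=["c1", "c2", "c3"], values=values
    )


@pytest.fixture(scope="session")
def default_synth():
    """Default planted-type dataset (5 types x 100 cells), seed 1."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def preprocessed(default_synth):
    E, _ = default_synth
    with pytest.warns(UserWarning):
        return preprocess(E)


@pytest.fixture(scope="session")
def quasi_trend_dataset():
    """Three 40-gene quasi-trend blocks over 240 cells (3 types x 80).

    Each block follows one type-elevated base profile up to monotone
    warping and small noise; returns (matrix, block ids per gene).
    """
    rng = np.random.default_rng(7)
    n_cells, n_types, per_block = 240, 3, 40
    type_of = np.repeat(np.arange(n_types), n_cells // n_types)
    rows, block_ids = [], []
    for t in range(n_types):
        base = np.zeros(n_cells)
        in_type = type_of == t
        base[in_type] = rng.lognormal(1.0, 0.4, int(in_type.sum()))
        block = generate_quasi_trend_block(per_block, base, noise_sd=0.05, seed=100 + t)
        rows.append(block)
        block_ids += [t] * per_block
    # a modest unstructured tail so clustering is non-trivial
    p = rng.uniform(0.4, 0.6, 120)
    on = rng.random((120, n_cells)) < p[:, None]
    rows.append(np.where(on, rng.lognormal(0.5, 0.4, (120, n_cells)), 0.0))
    block_ids += [-1] * 120
    values = np.vstack(rows)
    E = ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        cell_ids=[f"c{j}" for j in range(n_cells)],
        values=values,
    )
    return E, np.array(block_ids)


def make_cell_graph(out_lists: list[list[int]], weights: np.ndarray) -> CellGraph:
    """Build a CellGraph directly from explicit out-neighbor lists."""
    n = len(out_lists)
    k = len(out_lists[0])
    out = np.array(out_lists, dtype=np.int64)
    assert out.shape == (n, k)
    adj = np.zeros((n, n), dtype=bool)
    for i, nbrs in enumerate(out_lists):
        assert i not in nbrs
        adj[i, nbrs] = True
    return CellGraph(n=n, k_out=k, out=out, adj=adj, weights=np.asarray(weights, float))


def random_cell_graph(rng: np.random.Generator, n: int, k: int) -> CellGraph:
    """Random directed graph with uniform out-degree and random weights."""
    weights = np.round(rng.uniform(-0.5, 1.0, (n, n)), 3)
    weights = (weights + weights.T) / 2.0
    np.fill_diagonal(weights, 0.0)
    out_lists = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        out_lists.append(sorted(rng.choice(others, size=k, replace=False).tolist()))
    return make_cell_graph(out_lists, weights)
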