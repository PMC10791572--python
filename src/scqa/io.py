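"""Writers for pipeline outputs: label tables, landmark matrices, memberships.

All tables are plain text with deterministic row order (input cell/gene
order) and floats printed with 6 significant digits, so re-running an
identical configuration reproduces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import coo_matrix

from .cc import ScqaResult
from .lc1 import LandmarkMatrix, QualCluster
from .lc2 import QuantCluster
from .preprocess import ExpressionMatrix

__all__ = [
    "write_labels",
    "write_landmark_matrix",
    "write_lc1_membership",
    "write_lc2_membership",
    "write_cluster_landmarks",
    "write_result",
    "write_mtx",
]

FLOAT_FMT = "%.6g"


def write_labels(path: str | Path, cell_ids: list[str], labels: np.ndarray) -> None:
    """CSV with columns ``cell_id,cluster``."""
    with open(path, "w") as fh:
        fh.write("cell_id,cluster\n")
        for cid, lbl in zip(cell_ids, labels):
            fh.write(f"{cid},{int(lbl)}\n")


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return [str(c) for c in df.iloc[:, 0]], df.iloc[:, 1].to_numpy()


def write_landmark_matrix(path: str | Path, Q: LandmarkMatrix) -> None:
    """CSV, cells as rows, landmarks as columns."""
    with open(path, "w") as fh:
        fh.write("cell_id," + ",".join(Q.landmark_ids) + "\n")
        for cid, row in zip(Q.cell_ids, Q.values):
            fh.write(cid + "," + ",".join(FLOAT_FMT % v for v in row) + "\n")


def write_lc1_membership(
    path: str | Path, clusters: list[QualCluster], gene_ids: list[str]
) -> None:
    """TSV mapping each qualitative landmark to its member genes."""
    with open(path, "w") as fh:
        fh.write("landmark_id\tgene_id\n")
        for r, c in enumerate(clusters):
            for g in sorted(c.members):
                fh.write(f"LM1_{r}\t{gene_ids[g]}\n")


def write_lc2_membership(
    path: str | Path, clusters: list[QuantCluster], gene_ids: list[str]
) -> None:
    """TSV mapping each quantitative landmark to its member genes and group."""
    with open(path, "w") as fh:
        fh.write("landmark_id\tgene_id\tbin_usage_group\n")
        for r, c in enumerate(clusters):
            for g in sorted(c.members):
                fh.write(f"LM2_{r}\t{gene_ids[g]}\t{c.group}\n")


def write_cluster_landmarks(path: str | Path, result: ScqaResult) -> None:
    """TSV associating each cell cluster with its most active landmark and
    that landmark's member genes (the bidirectional-clustering report)."""
    assoc = result.cluster_landmarks()
    clusters = result.lc2_clusters if result.lc2_clusters is not None else result.lc1_clusters
    Q = result.Q2 if result.Q2 is not None else result.Q1
    gene_sets = {}
    for lbl, lm in assoc.items():
        gene_sets[lbl] = sorted(clusters[lm].members) if clusters else []
    with open(path, "w") as fh:
        fh.write("cluster\tlandmark_id\tn_member_genes\tmember_gene_indices\n")
        for lbl in sorted(assoc):
            lm = assoc[lbl]
            genes = gene_sets[lbl]
            fh.write(
                f"{lbl}\t{Q.landmark_ids[lm]}\t{len(genes)}\t"
                + ";".join(str(g) for g in genes)
                + "\n"
            )


def write_result(out_dir: str | Path, result: ScqaResult) -> list[Path]:
    """Write every available artifact of a run into ``out_dir``."""
    gene_ids = result.gene_ids
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    write_labels(out / "labels.csv", result.cell_ids, result.labels)
    written.append(out / "labels.csv")
    if result.Q1 is not None:
        write_landmark_matrix(out / "q1.csv", result.Q1)
        write_lc1_membership(out / "lc1_membership.tsv", result.lc1_clusters, gene_ids)
        written += [out / "q1.csv", out / "lc1_membership.tsv"]
    if result.Q2 is not None:
        write_landmark_matrix(out / "q2.csv", result.Q2)
        write_lc2_membership(out / "lc2_membership.tsv", result.lc2_clusters, gene_ids)
        written += [out / "q2.csv", out / "lc2_membership.tsv"]
    write_cluster_landmarks(out / "cluster_landmarks.tsv", result)
    written.append(out / "cluster_landmarks.tsv")
    return written


def write_mtx(out_dir: str | Path, E: ExpressionMatrix) -> None:
    """Write a matrix as MTX plus ``genes.tsv``/``barcodes.tsv`` companions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sparse = coo_matrix(E.values)
    mmwrite(str(out / "matrix.mtx"), sparse)
    (out / "genes.tsv").write_text("".join(f"{g}\n" for g in E.gene_ids))
    (out / "barcodes.tsv").write_text("".join(f"{c}\n" for c in E.cell_ids))
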