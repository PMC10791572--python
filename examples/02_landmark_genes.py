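"""Inspect the gene landmarks behind a clustering (bidirectional view).

The pipeline clusters genes as well as cells: each landmark is a cluster
of co-patterned genes with a consensus profile over cells.  This example
shows which genes make up each landmark and which landmark characterizes
each recovered cell cluster.
"""

import warnings

import numpy as np

from scqa import ScqaParams, SyntheticSpec, generate, run_scqa

warnings.filterwarnings("ignore", message="requested .* highly variable")

E, truth = generate(SyntheticSpec(seed=1))
result = run_scqa(E, ScqaParams())

print("qualitative landmarks (binary detection-pattern consensus):")
for r, cluster in enumerate(result.lc1_clusters):
    names = sorted(result.gene_ids[g] for g in cluster.members)
    on_cells = int(result.Q1.values[:, r].sum())
    print(f"  LM1_{r}: {cluster.size} genes, consensus 'on' in {on_cells} cells, "
          f"e.g. {names[0]}, {names[1]}")

print("\nquantitative landmarks (mean expression consensus):")
for r, cluster in enumerate(result.lc2_clusters):
    print(f"  LM2_{r}: {cluster.size} genes, bin-usage group {cluster.group}")

print("\nmost active landmark per cell cluster:")
for lbl, lm in result.cluster_landmarks().items():
    members = result.lc2_clusters[lm].members
    sample = sorted(result.gene_ids[g] for g in members)[:3]
    n_cells = int((result.labels == lbl).sum())
    print(f"  cluster {lbl} ({n_cells} cells) <- {result.Q2.landmark_ids[lm]} "
          f"({len(members)} genes, e.g. {', '.join(sample)})")
print("\nEach cell cluster is characterized by the landmark whose consensus "
      "is highest inside it — its candidate marker-gene set.")
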