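"""Score agreement between two cell partitions with ARI, NMI, FMI and JI.

All four indices are label-arrangement invariant.  The tiny worked
example below (two clusters vs one cluster over three cells) shows their
different sensitivities: the chance-corrected indices (ARI, NMI) drop to
0, while the pair-overlap indices (FMI, JI) stay positive because one
cell pair is still grouped consistently.
"""

from scqa import all_metrics, pair_counts

identified = [0, 0, 1]  # cells 1+2 together, cell 3 apart
annotated = [0, 0, 0]  # all three cells together

pc = pair_counts(identified, annotated)
print(f"pair counts: a={pc.a} (together in both), b={pc.b} "
      f"(together only in the annotation), c={pc.c}, d={pc.d}")

for name, value in all_metrics(identified, annotated).items():
    print(f"{name}: {value:.4f}")
print("ARI and NMI are 0 (no better than chance); FMI = 1/sqrt(3) and "
      "JI = 1/3 reflect the single concordant pair.")

print("\nidentical partitions score 1.0 everywhere:")
print(all_metrics([2, 0, 0, 1], [5, 7, 7, 9]))
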