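"""Splice-event classification and delta-PSI testing.

Detects SE/A5SS/A3SS/MXE events from the junction graph of each gene in
a small simulated study, computes per-sample PSI, and tests the PSI
difference between conditions with an exact label-permutation test.
"""
import numpy as np

import sjkit

config = sjkit.SimConfig(seed=3, n_genes=60, n_switch=8, n_de=0)
result = sjkit.simulate_study(config)
matrix = result.matrix
assignment = sjkit.assign_junctions_to_genes(matrix, result.models)

events = []
for model in result.models:
    js = [j for j, g in assignment.items() if g == model.gene_id and j in matrix]
    if not js:
        continue
    graph = sjkit.build_splice_graph(js)
    events.extend(sjkit.detect_events(graph, model))

table = sjkit.delta_psi_test(events, matrix, seed=3)
print("events by type:", table.event_type.value_counts().to_dict())

top = table.reindex(table.delta_psi.abs().sort_values(ascending=False).index)
print("\nstrongest PSI shifts (delta = knockdown - control inclusion level):")
print(top.head(8).to_string(index=False, float_format="%.3f"))
switch = set(result.truth.switch_gene_ids())
strong = top[top.delta_psi.abs() > 0.1]
print(f"\n{strong.gene_id.isin(switch).head(10).sum()} of the 10 largest "
      f"|delta PSI| events sit in the {len(switch)} genes with a planted switch.")
print("Note: with 3v3 replicates the exact permutation p cannot go below "
      "2/C(6,3) = 0.1, so BH FDR < 0.05 is unreachable at this design size; "
      "rank events by |delta PSI| and p instead, or use more replicates.")
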