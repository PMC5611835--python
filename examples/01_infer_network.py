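"""Infer a gene regulatory network from one simulated expression dataset.

Simulates a 150-gene dataset with two planted co-expression blocks, runs the
repeat-averaged bagged ensemble (BC3Net10) on the diseased samples, thresholds
the result at edge weight > 0.5 and scores it against the planted structure.
"""

import numpy as np

from grnloop import (
    InferenceParams,
    SimulationSpec,
    bc3net10,
    filter_phenotype,
    planted_edge_recovery,
    simulate_expression,
    threshold_subnetwork,
)

spec = SimulationSpec(
    n_genes=150,
    n_samples_diseased=60,
    n_samples_control=20,
    blocks=((15, 0.85), (15, 0.85)),
    rng_seed=1,
)
matrix = simulate_expression(spec)
diseased = filter_phenotype(matrix, "diseased")
print(f"dataset: {matrix.n_genes} genes x {matrix.n_samples} samples "
      f"({diseased.n_samples} diseased)")

params = InferenceParams(B=20, R=3, rng_seed=1)
network = bc3net10(diseased, params, np.random.default_rng(1))
print(f"ensemble network: {network.n_nodes} nodes, {network.n_edges} edges "
      f"(weights are mean bootstrap frequencies)")

subnetwork = threshold_subnetwork(network, tau=0.5)
precision, recall = planted_edge_recovery(subnetwork, spec)
print(f"subnetwork at weight > 0.5: {subnetwork.n_nodes} nodes, "
      f"{subnetwork.n_edges} edges")
print(f"against planted within-block pairs: precision {precision:.2f}, "
      f"recall {recall:.2f}")
print("high precision means the stable, high-frequency edges sit almost "
      "exclusively inside the planted co-expression blocks; recall is low by "
      "construction because each gene nominates at most one partner per run.")
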