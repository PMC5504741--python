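"""Build a gene-mass correlation network with communities and cliques.

A latent factor drives 12 genes and 4 masses up together and a second
factor drives another block; the network built from strong positive
gene-mass correlations (r > 0.85) should recover each block as one
community, and its dense cores as maximal cliques.
"""

import numpy as np

import stressfactor as sf

rng = np.random.default_rng(3)
n = 56  # paired samples
factor_a, factor_b = rng.standard_normal((2, n))
genes = np.vstack([
    factor_a[None, :] + 0.25 * rng.standard_normal((12, n)),
    factor_b[None, :] + 0.25 * rng.standard_normal((12, n)),
    rng.standard_normal((40, n)),                       # unrelated genes
])
masses = np.vstack([
    factor_a[None, :] + 0.25 * rng.standard_normal((4, n)),
    factor_b[None, :] + 0.25 * rng.standard_normal((4, n)),
    rng.standard_normal((20, n)),
])
x = sf.OmicsMatrix(genes, [f"g{i}" for i in range(len(genes))],
                   [f"s{j}" for j in range(n)], scale="log2")
y = sf.OmicsMatrix(masses, [f"m{i}" for i in range(len(masses))],
                   x.sample_ids, layer="metabolome", scale="log2")

candidates = sf.pairwise_correlations(
    x, y, classes=("gene-mass", "gene-gene", "mass-mass"))
graph = sf.build_network(candidates, sf.Thresholds(edge_r=0.85,
                                                   edge_alpha=1e-5))
print(f"network: {graph.number_of_nodes()} nodes, "
      f"{graph.number_of_edges()} edges")

part = sf.label_propagation(graph, seed=11)
n_comm = len(set(part["labels"].values()))
print(f"label propagation found {n_comm} communities "
      f"in {part['sweeps']} sweep(s)")

cliques = sf.maximal_cliques(graph, min_size=3, require_mass=True)
print(f"{len(cliques)} maximal cliques (size >= 3) contain a mass; largest:")
print("  ", ", ".join(cliques[0]))

kept = sf.top_genes_per_mass(candidates[candidates["r"] > 0.85], k=3)
print(f"top-3-genes-per-mass reduction keeps {len(kept)} genes")
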