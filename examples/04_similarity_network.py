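"""Build a bitscore-thresholded sequence similarity network.

All-vs-all local alignment bitscores (BLOSUM62, gap 11/1, Karlin-Altschul
lambda=0.267, K=0.041), edges above 380 bits, connected components compared
with the known family labels, and a threshold sweep.
"""

from padckit import (all_vs_all, build_ssn, cluster_concordance, components,
                     default_demo_specs, generate_dataset, threshold_sweep)

ds = generate_dataset(default_demo_specs(n_members=4, within_divergence=0.15),
                      global_seed=42)
pairs = all_vs_all(ds.sequences)
labels = dict(zip(ds.truth.sequence_id, ds.truth.family))
attrs = {sid: {"family": labels[sid]} for sid in ds.sequences}

graph = build_ssn(pairs, attrs, threshold=380)
comp = components(graph)
purity, rand = cluster_concordance(comp, labels)
print(f"{graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges "
      f"above 380 bits, {len(set(comp.values()))} connected components")
print(f"cluster purity {purity:.2f}, Rand index {rand:.2f} "
      f"against the planted families")

sweep = threshold_sweep(pairs, attrs, labels, [100, 380, 700, 1000])
print("\nthreshold sweep (edges shrink, components grow, purity never drops):")
print(sweep.to_string(index=False))
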