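"""Build the weighted heterogeneous network from synthetic input layers.

Generates a planted dataset (drugs, targets, lncRNAs, miRNAs), merges the
eight constituent networks into one weighted graph, and prints its census.
"""

from lmdti import (
    PlantedConfig,
    build_heterogeneous_network,
    dataset_statistics,
    dti_subnetwork,
    generate_planted_hetnet,
)

dd_sim, tt_sim, layers, truth = generate_planted_hetnet(PlantedConfig(seed=1))

g = build_heterogeneous_network(dd_sim, tt_sim, **layers)
sub = dti_subnetwork(g)
stats = dataset_statistics(layers["dti"], dd_sim.n, tt_sim.n)

print(f"nodes: {g.number_of_nodes()}  (drugs {sub.n_drugs}, targets {sub.n_targets})")
print(f"edges: {g.number_of_edges()}")
print(f"known DTIs: {stats.known_dtis}, unknown DTIs: {stats.unknown_dtis}")
for name, count in truth.edge_counts.items():
    print(f"  layer {name}: {count} interaction edges")
# Interaction edges carry weight 1; similarity edges carry the similarity
# value, so the graph mixes hard interactions with soft relatedness.
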