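"""Infer a signed correlation network from one biomass table.

Autoscale each taxon, compute all pairwise Pearson correlations, and
keep the pairs whose |r| reaches the two-tailed critical value at
P <= 0.05 for the class sample size.
"""

from planknet import autoscale, critical_r, make_study_fixture, pearson_matrix, threshold_network

m = make_study_fixture(seed=0)["HT"]
scaled, dropped = autoscale(m)
corr = pearson_matrix(scaled, alpha=0.05)
net = threshold_network(corr)

n = m.shape[0]
print(f"critical |r| at n={n}, alpha=0.05: {critical_r(n, 0.05):.3f}")
print(f"network: {net.number_of_nodes()} taxa, {net.number_of_edges()} significant edges")
pos = sum(1 for _, _, d in net.edges(data=True) if d["sign"] == "+")
print(f"positive (guild/coexistence) edges: {pos}; negative (predation/competition): {net.number_of_edges() - pos}")

# Every edge's weight is |r|; the sign separates coexistence-type from
# antagonistic interactions. Isolated taxa stay in the node set, flagged.
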