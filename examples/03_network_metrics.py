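"""Global attributes, centralities and sub-network structure of one network.

Computes the NetworkAnalyzer-style attribute panel (clustering,
centralization, density, heterogeneity, path statistics), the NDC/NCC/
NBC node centralities and EBC edge betweenness, and the divisive
edge-betweenness (Girvan-Newman) communities.
"""

from planknet import (
    autoscale,
    communities,
    global_attributes,
    make_study_fixture,
    node_centralities,
    pearson_matrix,
    threshold_network,
)

m = make_study_fixture(seed=0)["HT"]
scaled, _ = autoscale(m)
net = threshold_network(pearson_matrix(scaled))

attrs = global_attributes(net)
for key, val in attrs.to_dict().items():
    print(f"{key:28s} {val}")

table = node_centralities(net)
top = table.nodes.sort_values("nbc", ascending=False).head(3)
print("\nhighest-betweenness taxa (bridges between sub-networks):")
print(top.to_string(index=False))

top_edges = table.edges.sort_values("ebc", ascending=False).head(3)
print("\nhighest edge betweenness (relationships critical to cohesion):")
print(top_edges.to_string(index=False))

parts = communities(net)
print(f"\n{len(parts)} communities at maximal modularity; sizes: {sorted(map(len, parts), reverse=True)}")
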