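"""Reconstruct a disease's associative gene network and inspect its shape.

Generates a desk-scale synthetic knowledge base, extracts the star
network of genes and proteins linked to the disease node, and prints its
cardinalities and relation-type mix.
"""

from agnet import (
    agn_stats,
    generate,
    reconstruct_agn,
    relation_type_distribution,
    small_params,
)

data = generate(small_params(seed=1))
g = data.graph

agn = reconstruct_agn(g, ["disease:RA"])
stats = agn_stats(agn, g)

print(f"members : {stats.n_members} ({stats.n_genes} genes + {stats.n_proteins} proteins)")
print(f"edges   : {stats.n_edges} (exceeds members because one member can carry")
print("          several parallel edges, one per interaction type)")
print()
print("relation-type mix of the disease star:")
print(relation_type_distribution(g, agn.edges).head(5).to_string(index=False))
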