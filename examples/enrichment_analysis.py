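"""Overrepresentation of a disease gene list against GO-style gene sets.

Collapses the disease network's members to a gene list (proteins fold
onto their coding genes), tests every gene set with the hypergeometric
upper tail and applies Bonferroni correction.
"""

from agnet import (
    enrich,
    generate,
    member_gene_list,
    reconstruct_agn,
    small_params,
)
from agnet.enrichment import results_to_frame

data = generate(small_params(seed=1))
g = data.graph

agn = reconstruct_agn(g, ["disease:RA"])
query = member_gene_list(agn, g, data.mapping)
results = enrich(query, data.sets, alpha=0.05)

n_sig = sum(r.significant for r in results)
print(f"query size: {len(query)} genes; universe: {results[0].N} genes")
print(f"{n_sig} of {len(results)} tested terms significant at Bonferroni alpha=0.05")
print()
print("top terms (k of K annotated genes found in the n-gene query):")
print(results_to_frame(results[:5]).to_string(index=False))
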