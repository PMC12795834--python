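# agnet

Network-based prioritization of biological processes as drug targets,
built on typed biomedical knowledge graphs.

Many diseases — rheumatoid arthritis is the motivating case — are treated
with drugs that leave a substantial fraction of patients without a full
response. One way to look for new therapeutic entry points is to ask which
biological processes are involved in the disease but untouched by the
drugs already in clinical use. `agnet` implements that analysis over a
knowledge graph of typed relations between genes, proteins, diseases,
drugs and biological processes:

1. **Associative gene networks (AGNs).** Star-topology extraction of the
   genes/proteins linked to a focus entity (a disease, or a group of
   drugs). A member may carry several parallel edges to the focus, one per
   interaction type, so edge counts exceed member counts.
2. **Overrepresentation analysis.** Each GO biological-process gene set is
   scored against an AGN's gene list by the hypergeometric upper tail
   P[X ≥ k] with X ~ Hypergeom(N, K, n) — N the background universe, K the
   term size, n the query size, k the overlap — and Bonferroni-corrected:
   p_adj = min(1, m · p_raw) over the m tested terms, significant at
   p_adj < 0.05.
3. **The subtraction cascade.** A process is a *candidate target* iff it is
   (i) significantly enriched in the disease AGN, (ii) linked to the
   disease by a Regulation / Downregulation / Upregulation relation,
   (iii) **not** enriched in any drug-group response AGN, and (iv) **not**
   regulation-linked to any considered drug. Stage counts are reported as
   an audit trail.
4. **Mechanisms.** Signed path and feedback-loop search over regulatory
   edges: the sign of a path is the product of edge polarities, and a
   simple cycle with product +1 is a positive feedback loop (e.g. two
   genes that mutually activate each other's expression).
5. **Synthetic knowledge bases.** Curated knowledge bases are proprietary
   snapshots, so a generator emulates their structure — including an exact
   mode that plants enrichments, regulation links and loops constructively,
   making every pipeline stage's counts deterministic and testable.

Intended users: computational biologists studying drug repurposing /
target discovery pipelines, and anyone needing a transparent, tested
reference implementation of the AGN → enrichment → subtraction workflow.

## Worked example

```bash
python examples/find_target_processes.py
```

```
significant_disease_terms                40
disease_regulated                        12
after_drug_enriched_subtraction          8
drug_regulated_removed                   5
candidates                               3
significant_terms[csDMARD]               10
significant_terms[tsDMARD]               6

candidate target processes (not touched by any considered drug):
  GO:0000010  synthetic biological process 10  p_adj=1.50e-03
  GO:0000011  synthetic biological process 11  p_adj=1.50e-03
  GO:0000012  synthetic biological process 12  p_adj=1.50e-03
```

Reading: of 40 processes significantly overrepresented in the disease
network, 12 carry a regulation-type link to the disease; 4 of those are
also enriched in a drug-response network (12 → 8), and 5 more are
regulated by one of the drugs (8 → 3). The 3 survivors are disease-
relevant processes no considered drug touches — the candidates. On the
study-scale preset (`--preset study-scale`) the same pipeline reports
4,685 network members behind 9,877 multi-typed edges and a 381 → 71 →
59 → 11 cascade.

Other examples: `build_disease_network.py` (AGN cardinalities and the
relation-type mix), `enrichment_analysis.py` (hypergeometric table),
`feedback_loops.py` (the IL1B/WNT5A positive expression loop and signed
cytokine→DKK1 paths).

The same stages are available as a CLI for file-based runs:

```bash
agnet generate --preset small --seed 1 --out kb/
agnet identify-targets --graph-dir kb/ --gmt kb/go_bp.gmt \
      --mapping kb/mapping.tsv --universe kb/universe.txt \
      --config cascade.yaml --out run/
agnet mechanisms --graph-dir kb/ --seeds seeds.txt --out mech/
```

Inputs are plain TSV tables (`entities.tsv`, `relations.tsv`,
`vocabulary.tsv`), standard GMT gene sets, and a `protein_id → gene_id`
mapping; outputs are TSV/JSON plus SIF for network viewers. See
`docs/methods.md` for the model, parameter and design details.

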