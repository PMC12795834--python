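"""The full target-discovery cascade on a planted knowledge base.

A process is a candidate drug target when it is enriched in the disease
network, regulation-linked to the disease, and neither enriched in nor
regulation-linked to the considered drug groups. The stage counts form
the run's audit trail; on this fixture they equal the planted values.
"""

from agnet import CascadeConfig, generate, run_cascade, small_params

data = generate(small_params(seed=1))

cfg = CascadeConfig(
    drug_groups={k: list(v) for k, v in data.truth["drug_groups"].items()}
)
report = run_cascade(
    data.graph, data.truth["disease"], data.sets, cfg, data.mapping
)

for stage, count in report.stage_counts.items():
    print(f"{stage:40s} {count}")
print()
print("candidate target processes (not touched by any considered drug):")
for c in report.candidates:
    print(f"  {c.term_id}  {c.term_name}  p_adj={c.p_adj_disease:.2e}")
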