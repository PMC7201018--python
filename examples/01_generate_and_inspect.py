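"""Generate a small planted-signal dataset and inspect what was planted.

Prints the per-term signal wiring (which domain / motif / PPI cluster makes a
protein carry each GO term) and basic dataset counts.
"""

from gofuse import simulate

cfg = simulate.SimConfig(n_proteins=60, n_terms=6, n_clusters=3,
                         seq_len_range=(40, 80), seed=42)
dataset = simulate.generate_dataset(cfg)

print(f"{len(dataset.sequences)} proteins, {len(dataset.domain_hits)} domain hits, "
      f"{len(dataset.links)} scored links, {len(dataset.annotations)} GO annotations")
for sig in dataset.truth_signals:
    detail = sig.domain_id or sig.motif or f"cluster {sig.cluster}"
    print(f"  {sig.term}: {sig.kind:<7} <- {detail}")

# A classifier that reads the planted truth directly recovers the labels:
# with label_noise=0 its F-max is exactly 1.0 (generator identifiability).
from gofuse.encode import build_label_matrix, select_go_terms
from gofuse.metrics import fmax

term_set = select_go_terms(dataset.annotations, cfg.ontology, 1)
labels = build_label_matrix(dataset.protein_ids, dataset.annotations, term_set)
scores = simulate.rule_based_scores(dataset)
order = [int(t.split(":")[1]) - 1 for t in term_set.terms]
f, _, _ = fmax(scores[:, order], labels)
print(f"rule-based oracle F-max: {f:.3f} (1.0 means the signal is exactly recoverable)")
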