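"""Quantify what the domain branch contributes.

Plants signal only in domain architecture, then trains the full stack and a
no-domain variant (sequence + PPI, classifier mask rows summing to 2) under
identical seeds and splits. The F-max gap is the value of domain features.
"""

from gofuse import pipeline, simulate
from gofuse.train import TrainConfig

cfg = simulate.SimConfig(n_proteins=200, n_terms=6, n_domains=12,
                         signal_kinds=["domain"] * 6,
                         seq_len_range=(40, 100), seed=2)
dataset = simulate.generate_dataset(cfg)
table = simulate.make_protvec_stub(seed=2)
enc = pipeline.encode_synthetic(dataset, table,
                                pipeline.PipelineConfig(pad_len=100, min_count=10))

full, ablated = pipeline.run_domain_ablation(
    enc,
    TrainConfig(seed=2, learning_rate=3e-3, max_epochs=40, patience=15,
                batch_size=16),
    overrides={"classifier": dict(learning_rate=3e-2, max_epochs=100, patience=25)},
)
print(f"full stack      F-max {full.fmax:.3f}  AUC {full.auc:.3f}")
print(f"no-domain stack F-max {ablated.fmax:.3f}  AUC {ablated.auc:.3f}")
print(f"F-max gain from domain features: {full.fmax - ablated.fmax:+.3f}")
print("With domain-only signal the ablated model has nothing to learn from, "
      "so a large positive gap is expected.")
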