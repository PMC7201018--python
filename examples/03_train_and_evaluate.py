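"""Train the three branches plus the masked fusion classifier on a small
planted-signal dataset and evaluate on held-out proteins.

A miniature version of the full protocol (~1 minute on one CPU): pretrain
each branch with BCE + Adam under 80/20 validation selection, fit the
weighted classifier on out-of-sample branch scores, and report protein-
centric F-max, AUPR and AUC on the 20% held-out split.
"""

from gofuse import pipeline, simulate
from gofuse.train import TrainConfig

cfg = simulate.SimConfig(n_proteins=150, n_terms=6, n_clusters=3,
                         seq_len_range=(40, 100), seed=1)
dataset = simulate.generate_dataset(cfg)
table = simulate.make_protvec_stub(seed=1)
enc = pipeline.encode_synthetic(dataset, table,
                                pipeline.PipelineConfig(pad_len=100, min_count=10))
print(f"encoded: {len(enc.protein_ids)} proteins, {enc.n_terms} terms, "
      f"M_max={enc.m_max}, vocab={enc.vocab.size}")

result = pipeline.run_pipeline(
    enc,
    TrainConfig(seed=1, learning_rate=3e-3, max_epochs=30, patience=10),
    overrides={"classifier": dict(learning_rate=3e-2, max_epochs=100, patience=25)},
)
r = result.report
print(f"held-out F-max {r.fmax:.3f} at t={r.fmax_threshold:.2f}, "
      f"AUPR {r.aupr:.3f}, AUC {r.auc:.3f}")
print("F-max near 1 means the planted domain/PPI/motif rules were recovered; "
      "AUC ~0.5 would mean the branches learned nothing.")
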