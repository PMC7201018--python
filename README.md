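# gofuse

Multi-branch protein function prediction with CAFA-style evaluation.

Assigning Gene Ontology (GO) terms to proteins is a large-scale multi-label
problem: a protein typically carries many terms, and only a tiny fraction of
known proteins have experimentally supported annotations. `gofuse`
re-implements an integrated predictor that learns three complementary views
of a protein and fuses them per GO term:

* **Sequence branch** — the amino-acid sequence is padded to a fixed length
  L (classically 1,500), decomposed into L−2 overlapping 3-grams, and each
  trigram mapped to a 100-D ProtVec-style embedding; a 1-D CNN
  (out-channels 64/32/16, kernel 16, stride 1, each stage followed by ReLU
  and max-pool k=2/s=2) reduces the (L−2)×100 matrix to one score per term.
* **Domain branch** — InterPro-style domain hits are deduplicated, sorted by
  their *regional center point* (start+end)/2 (which resolves detached,
  crossing and containing hit pairs alike), and encoded as a fixed-length
  integer "domain sentence" over a vocabulary with a reserved padding
  index 0. A trainable 128-wide lookup table and a two-stage 1-D CNN
  (out-channels 128/64, kernel 2, stride 2) turn the sentence into per-term
  scores.
* **PPI branch** — STRING-style scored links are filtered at a combined
  score strictly above 400 and assembled into a symmetric score matrix; a
  protein's row is densified by a three-layer trapezoidal perceptron.
* **Weighted classifier** — one tiny classifier per GO term. Hidden node *j*
  receives exactly the three branch scores for term *j* — enforced by a
  constant binary mask whose rows sum to 3 — and output node *j* sees only
  hidden node *j* (identity mask). Its weights are interpretable as the
  per-term preference for each evidence source.

Training follows the original protocol: each branch is pretrained with
binary cross-entropy and Adam under an 80/20 validation split with
best-validation model selection; the fusion classifier is then trained on
out-of-sample branch scores. Evaluation implements the protein-centric CAFA
measures: F-max over a 101-point threshold grid, AUPR by the trapezoid rule
and ROC AUC over pooled protein×term pairs.

Because the original training corpora (UniProt/GOA/STRING/InterPro
snapshots) are far beyond desk scale, the package ships a synthetic
benchmark generator that emulates all four input formats and plants an
exactly recoverable signal: a GO term is carried by the proteins bearing a
specific domain, containing a specific 5-residue motif, or belonging to a
planted PPI cluster.

## Worked example

```python
from gofuse import pipeline, simulate
from gofuse.train import TrainConfig

cfg = simulate.SimConfig(n_proteins=150, n_terms=6, n_clusters=3,
                         seq_len_range=(40, 100), seed=1)
dataset = simulate.generate_dataset(cfg)
table = simulate.make_protvec_stub(seed=1)
enc = pipeline.encode_synthetic(dataset, table,
                                pipeline.PipelineConfig(pad_len=100, min_count=10))
result = pipeline.run_pipeline(
    enc, TrainConfig(seed=1, learning_rate=3e-3, max_epochs=30, patience=10),
    overrides={"classifier": dict(learning_rate=3e-2, max_epochs=100, patience=25)},
)
r = result.report
print(f"held-out F-max {r.fmax:.3f} at t={r.fmax_threshold:.2f}, "
      f"AUPR {r.aupr:.3f}, AUC {r.auc:.3f}")
```

prints (about one minute on one CPU):

```
held-out F-max 0.779 at t=0.50, AUPR 0.844, AUC 0.892
```

F-max near 1 would mean the planted rules were recovered perfectly on the
20% held-out proteins; AUC ≈ 0.5 would mean nothing was learned. The
`examples/` directory has one short script per capability: generating and
inspecting a planted dataset, the fixed-shape encodings, training plus
evaluation, and the domain-ablation comparison.

A thin CLI wires the same pieces into reproducible commands:

```bash
gofuse simulate --seed 5 --n-proteins 200 --out fixture/
gofuse preprocess --data-dir fixture/ --out enc.npz --pad-len 200
gofuse train --archive enc.npz --out-dir ckpt/ --seed 5
gofuse predict --archive enc.npz --checkpoint-dir ckpt/ --out pred.tsv
gofuse evaluate --predictions pred.tsv --annotations fixture/annotations.tsv \
    --out report.json
```

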