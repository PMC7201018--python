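# Methods

This note records the model, the data representations, the training
protocol, the synthetic benchmark and the numerical choices, together with
what the passing tests do and do not establish.

## Data representations

**Sequences.** A protein is a string over the 20 standard residues
(X tolerated as "unknown"). Sequences are right-padded with a dedicated
non-residue symbol (rendered `0`) to a fixed length L; proteins longer than
L are excluded with a logged warning rather than truncated. A window of
length 3 with step 1 produces L−2 trigrams; each is looked up in a
ProtVec-style table of 100-D vectors. Trigrams containing the padding
symbol, and trigrams absent from the table (e.g. containing X), map to the
zero vector — the padding rule is the defined behaviour, and treating
out-of-vocabulary tokens the same way is the minimal extension that keeps
the encoding total. The classical configuration is L = 1,500, giving a
1,498 × 100 matrix; the synthetic benchmark uses L = 200 to match its
60–200-residue sequences (`PipelineConfig.pad_len`).

**Domain sentences.** Hits identical in (domain id, start, end) are
collapsed to the first occurrence. Hits are then ordered by the regional
center point (start+end)/2: for detached pairs this reproduces left-to-right
order, and for crossing or containing pairs — where true extents are
unknown — the midpoint is the only well-defined key. Center ties break by
(start, end, domain id); the tie rule is arbitrary but fixed, because the
sentence feeds a position-sensitive model and must be reproducible.
Distinct domain ids get indices 1..D in sorted order; index 0 is reserved
for padding, so the lookup table has D+1 rows (e.g. 14,242 distinct domains
give a 14,243-row table). Sentences are padded with 0 to the dataset-wide
maximum domain count M_max.

**PPI matrix.** Links with combined score strictly greater than 400 (the
conventional "medium confidence" cutoff; the threshold is a parameter) fill
a symmetric N × N matrix with zero diagonal; endpoints outside the protein
set are ignored. The raw 0–1000 integer scores can be kept as-is
(`normalize=False`, the encode-level default) or divided by 1000; the
pipeline defaults to normalized scores because features in [0, 1] condition
the dense net's optimisation much better than raw hundreds.

**Labels.** Per sub-ontology (BP/MF/CC), terms annotated on at least
`min_count` distinct proteins are kept, ordered by descending count with
GO-id tie-break; a protein's label vector is the binary indicator over that
ordered list. Counting distinct proteins (not annotation rows) makes the
threshold robust to duplicated annotation records. No true-path propagation
to ancestor terms is performed.

## Models

All four models output sigmoid probabilities; training minimises unweighted
binary cross-entropy. The original description names only ReLU activations
and BCE loss; BCE requires (0, 1) outputs, so sigmoid heads are the minimal
consistent completion.

* Sequence branch: [conv(k=16, s=1, same-padding) → ReLU → maxpool(2/2)] × 3
  with out-channels 64/32/16 over the position axis (the 100 embedding
  dimensions are the input channels), flatten, one affine map to T terms.
  The FC stack depth is unspecified in the source description; a single
  affine reduction is the minimal reading, and `fc_hidden` optionally
  inserts one hidden layer.
* Domain branch: trainable (D+1) × 128 lookup table with the padding row
  frozen at zero (padded positions then contribute exactly nothing);
  [conv(k=2, s=2, same-padding) → ReLU → maxpool(2/2)] × 2 with out-channels
  128/64. Following the printed in-channel counts, the M_max sentence
  positions are the input channels and the convolution runs along the
  128-wide embedding axis; this is also the only orientation that survives
  two conv/pool stages for short sentences (M_max ≈ 10 collapses to an
  empty feature map in the conventional orientation, which remains
  available as `channels_are_positions=False` for long sentences).
* PPI branch: dense N → hidden → T with ReLU, hidden defaulting to the
  geometric mean of N and T (clipped to [T, N]) — a "trapezoidal"
  intermediate width.
* Weighted classifier: hidden[j] = ReLU(w₁ⱼ·s_seq[j] + w₂ⱼ·s_dom[j] +
  w₃ⱼ·s_ppi[j] + bⱼ), out[j] = σ(vⱼ·hidden[j] + cⱼ). Both layers are dense
  layers elementwise-gated by constant binary masks (rows of the input mask
  sum to 3; the output mask is the identity); gradients are gated by the
  same masks and masked weights are re-zeroed after each optimizer step, so
  the sparsity pattern is exact at all times, which the locality tests
  verify by finite differences. The classifier consumes post-sigmoid branch
  probabilities. Its masked weights are initialised *nonnegative*: inputs
  are probabilities in [0, 1], so a random-sign init would leave roughly
  1/8 of the per-term ReLU units permanently dead.

Parameter initialisation is uniform Kaiming-style fan-in scaling with
zero biases, driven by an explicit generator seed. Convolution
"same"-padding puts the extra zero on the right for even kernels; pooling
drops a trailing odd element.

The layers live in a compact NumPy engine (`gofuse.nn`) with hand-written
forward/backward passes and Adam (β₁=0.9, β₂=0.999, ε=1e-8, optional L2
weight decay); every layer's backward pass is finite-difference-checked in
the test suite, and every model's forward pass is checked against explicit
loop-based recomputations.

## Training protocol

Each component draws an 80/20 train/validation split, optimises mean BCE
with Adam in minibatches, evaluates validation loss each epoch, and returns
the parameters of the best-validation epoch (early stopping after a
patience window, default 10 epochs). All randomness — splits,
initialisation, shuffling — flows from named substreams of a single run
seed, so identical configurations reproduce identical histories bit for
bit.

Within a full pipeline run the three branches share one 80/20 split, and
the fusion classifier is trained on the branch scores of the shared
validation portion. This departs from feeding training-set outputs forward:
branch scores on their own training proteins are memorised (effectively
equal to the labels), which would make every branch look equally reliable
and leave the classifier unable to weight branches by how well they
generalise. Training the fusion on out-of-sample scores is standard
stacked-generalisation practice; sub-models stay frozen during fusion
training either way.

k-fold cross-validation re-runs the entire protocol (branch pretraining
included) inside each fold, so no information crosses fold boundaries. The
no-domain ablation shares the pretrained sequence/PPI branches and the
held-out split with the full model and retrains only the fusion layer with
a two-branch mask (rows sum to 2).

Per-component hyperparameters for the standard benchmark
(`gofuse.benchmark.TRAIN_OVERRIDES`) were selected on validation
loss/validation AUC, mirroring the original per-module manual adjustment:
the domain branch benefits from lr 1e-2 with weight decay 1e-3, the fusion
layer (4 effective parameters per term) from lr 3e-2 and a long epoch
budget.

## Synthetic benchmark

The generator emulates the four input files with planted, exactly
recoverable signal. Study conditions: 500 proteins, 20 GO terms in one
sub-ontology, term signals cycling through the three modalities. Sequences
are i.i.d. over the 20 residues, 60–200 residues long — long enough to
carry motifs and domains, short enough that the whole suite runs on one CPU
in minutes. Motif terms plant a 5-residue motif at a uniform position
(non-overlapping with other motifs) in ~30% of proteins; truth is defined
by actual substring presence, so chance occurrences count. Domain terms
mark carriers of a dedicated signal domain (carried with probability 0.3);
background hits per protein number 1–5 with a configurable fraction of
forced crossing/containing overlaps. PPI terms mark the members of one of
7 planted clusters; within-cluster links appear with probability 0.5 and
score in [700, 999], background links with probability 0.01 score in
[150, 699] — so the 400-score filter keeps most signal plus some noise and
is exercised meaningfully. Labels are noiseless by default, making the
planted rules exactly recoverable (a rule-reading oracle reaches F-max
1.0, which the tests verify before any learning test); `label_noise` flips
labels independently when a noisy variant is wanted. The embedding table is
a deterministic stand-in: one pseudo-random unit-norm 100-D vector per
possible trigram.

What the generator does **not** emulate: GO's DAG structure and true-path
consistency, realistic domain co-occurrence and granularity, homology and
phylogenetic correlation between sequences, degree heterogeneity of real
interaction networks, and the semantic structure of a trained ProtVec
embedding. Passing the planted-signal tests therefore shows that the
architecture, masking, training loop and evaluation work end to end and
can recover clean multi-modal signal at desk scale — not that the model
attains its published performance on real proteome-scale data, which is
out of scope here.

## Known limitations

* **Sequence branch at desk scale.** With 400 training proteins the
  sequence CNN does not discover planted 5-residue motifs: held-out AUC on
  motif terms stays ≈ 0.53 across learning rates, batch sizes, weight
  decay, full-batch training, longer budgets, rescaled embeddings, a
  position-invariant global-max readout variant, and a 6× larger dataset.
  Credit assignment from a position-specific readout back to first-layer
  motif detectors appears to need corpus-scale data (the original setting
  trains on 10⁴–10⁵ proteins). The benchmark's composite scores
  (F-max ≈ 0.72–0.74, micro-AUC ≈ 0.92 across seeds) are carried by the
  domain and PPI branches, whose terms are recovered almost perfectly; the
  measured ceiling with chance-level motif terms is F-max 0.758 /
  micro-AUC 0.940.
* Evaluation follows the CAFA benchmark reading: proteins with empty truth
  sets are excluded from the recall average (a switch restores the
  divide-by-all-n variant); AUPR/AUC are micro-averaged over pooled
  protein×term pairs by default with a per-term macro mode, since the
  source description leaves the averaging axis ambiguous.
* F(t) is defined as 0 at thresholds where no protein predicts any term,
  keeping the maximum well-defined; the threshold grid is
  t = 0.00, 0.01, …, 1.00.
* The 5-fold CV harness is exercised on small data in the tests; paper-scale
  cross-validated tables require external database snapshots and long
  training and are out of scope.
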