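# Methods

## Problem

Prime editing installs a programmed edit at a genomic target using a pegRNA
(prime-editing guide RNA). For a given pegRNA–target pair, the outcome of an
editing experiment splits into three fractions that sum to 100%: the fraction
of reads carrying exactly the intended edit (*validly edited*), the fraction
left unchanged (*unedited*), and the fraction carrying unintended products
(*erroneously edited*). PrimeNet is a convolutional network that predicts this
triple from the pair's sequence context, functional-region layout, and two
epigenetic tracks (chromatin accessibility and DNA methylation).

## Input encoding

Each pair is encoded as a binary **pseudo-image of shape 128 × 8 × 2**
(`primenet.encoder`):

- **Positions (128).** The wild-type and edited sequences are left-aligned in
  a 128-nt frame and zero-padded on the right. Sequences longer than 128 nt
  are rejected.
- **Channels (8).** Channels 0–3 one-hot encode the base with the mapping
  A→0, G→1, T→2, C→3. Channel 4 is chromatin accessibility (1 = DNase
  sensitive), channel 5 is methylation (1 = methylated). Channel 6 marks the
  union of protospacer, PAM and primer-binding site (PBS); channel 7 marks the
  reverse-transcriptase (RT) template.
- **Sequences (2).** Slice 0 holds the wild-type sequence, slice 1 the edited
  sequence. Per-base epigenetic annotation is carried from the wild sequence
  onto the edited one position-for-position when lengths match; for indels an
  ungapped anchor alignment (longest common prefix and suffix) is used and
  inserted bases get 0.

Epigenetic tracks are genomic interval sets (`primenet.epitracks`); a record's
genomic anchor (chromosome, start, strand) converts them to per-base vectors,
reversing the readout on the minus strand.

## Architecture

`primenet.network.PrimeNet` processes a batch of pseudo-images
(B, 128, 8, 2), treating the 8 channels as feature maps over a 128 × 2 grid:

1. **Convolutional spatial attention** on the input: per-position channel mean
   and max are concatenated into two maps, convolved along the length axis
   with a **kernel of size 5**, and passed through a sigmoid; the input is
   multiplied by the resulting weights. (A softmax variant over positions is
   available behind a config flag.)
2. **MixConv** with **three kernel scales** — (1 × 2), (3 × 2), (9 × 2) —
   each length-padded to preserve the 128 positions. The size-2 kernel over
   the sequence axis collapses the wild/edited pair into one map, so each
   branch reads the wild–edited *difference context* at its own receptive
   field. Branch outputs are concatenated on the channel axis.
3. **Channel attention**: global average pooling per channel, a 1-D
   convolution of kernel 3 across the channel axis, sigmoid gate.
4. A 1 × 1 convolution compresses channels, followed by two convolution
   blocks (kernel 3 along the length axis, ReLU), each followed by another
   convolutional spatial attention.
5. The flattened features feed a shared fully-connected trunk, then **three
   disjoint branches** (one per outcome). Each head ends in
   `sigmoid × 100`, so predictions live on the percent scale.

Defaults (see `ModelConfig`): 16 channels per MixConv branch, 32 compressed
channels, two 32-channel conv layers, a 256-unit trunk, 64-unit branches
(~1.1 M parameters).

All gradients come from `primenet.autodiff`, a small numpy reverse-mode
engine (no external deep-learning framework is required). Convolution is
implemented as im2col + matrix multiplication so BLAS carries the arithmetic;
its gradients are verified against finite differences in the test suite.

## Training

(`primenet.training`)

- **Initialization.** Every weight matrix (flattened to output × fan-in) is
  made orthogonal via a sign-corrected QR decomposition of a Gaussian draw:
  WᵀW = I when rows ≥ columns, WWᵀ = I otherwise. Biases start at exactly 0.
- **Optimizer.** Adam (learning rate 1e-3) wrapped in **Lookahead**
  (k = 5, α = 0.5): the fast weights θ take k Adam steps, then the slow
  weights φ move φ ← φ + α(θ − φ) and θ is reset to φ. A shortened final
  cycle at the end of an epoch is closed explicitly. The Lookahead
  implementation is checked to 1e-10 against a hand-stepped reference.
- **Loss and selection.** Mean-squared error on the percent scale, averaged
  over the three heads. Data are split 8:1:1 into train/validation/test with
  a seeded permutation. Model selection and early stopping (patience 10) use
  the validation Spearman correlation of the validly-edited head, which is
  also the objective of the random hyperparameter search
  (`tune_hyperparameters`).

## Evaluation

(`primenet.evaluation`)

Per head: Spearman and Pearson correlations; AUROC/AUPRC after binarizing
observed efficiencies at a strictly-greater 50% threshold. AUROC is computed
through the rank identity AUROC = U/(n₁·n₂), where U is the Mann–Whitney
statistic of positive-class scores over negative-class scores; AUPRC is the
step-interpolated average precision. The Mann–Whitney U test (used for the
epigenetic group comparisons) wraps `scipy.stats.mannwhitneyu`: exact
enumeration when n₁·n₂ ≤ 400 and the pooled sample is tie-free, otherwise the
normal approximation with tie and continuity corrections. Group analyses
split records into "completely open" (every base DNase-accessible) vs
"presence of closure", and "with" vs "without methylation".

## Interpretation

(`primenet.interpretability`)

- **Integrated gradients** with a zero baseline and a Riemann midpoint rule
  (default 256 steps) attribute a head's output to every input cell. The
  completeness identity Σ attributions = F(x) − F(baseline) bounds the
  discretization error; the package checks it to within 1% relative error.
  On a linear model the implementation reproduces w ⊙ x exactly.
  Note: with a zero baseline, cells whose input value is 0 receive exactly
  zero attribution, so attribution over the accessibility channel is only
  informative for records with at least one accessible base.
- **Channel optimization**: starting from the 200 highest-efficiency
  pseudo-images, the chosen head is maximized by gradient ascent **on channel
  4 or 5 only** — gradients for all other channels are masked, so those
  channels remain bit-identical — with values clamped to [0, 1] each step;
  the optimized channels are averaged into a per-position profile.
- **Attention maps** from each convolutional-attention stage can be extracted
  and averaged over a set of images.

## Synthetic data generator

(`primenet.simdata`) No experimental dataset ships with the package; a
generator with planted, fully recorded ground truth supports end-to-end
testing.

- One synthetic chromosome of i.i.d. bases. Accessibility is an alternating
  exponential block model (mean peak length 300 bp, 40% coverage — typical
  DNase peak widths); methylation is Bernoulli(0.3) per CpG site.
- Each record draws a 99-nt window (20% on the minus strand) with a realistic
  layout: 20-nt protospacer, 3-nt PAM, nick 17 nt into the protospacer, PBS
  of 8–17 nt ending at the nick, RT template of 10–30 nt starting at the
  nick. The edit (70% substitution, 15% insertion of 1–2 nt, 15% deletion of
  1–2 nt) lands inside the RT region.
- Outcomes follow a latent valid-edit score over the protospacer+PAM window:

      s0 = β0 + β_acc·acc − β_meth·meth + β_gc·GC(PBS)

  with defaults β0 = −1.5, β_acc = 2, β_meth = 1, β_gc = 1, where `acc` and
  `meth` are the accessible/methylated fractions of the window. The noiseless
  expected triple is the softmax of (s0, −s0, −1) scaled to percent; the
  observed triple is a Dirichlet draw (concentration 200) around the softmax
  of the noise-perturbed score (Gaussian noise, scale 0.25), so triples sum
  to exactly 100. β0 = −1.5 centers the valid-efficiency distribution across
  the 50% binarization threshold so both outcome classes occur.
- Canned fixtures: `tiny` (32 records), `smoke` (300), and `recovery`
  (5000 records with *strong planted effects*: noise 0.1, concentration
  1000). Under the default noise the Spearman correlation between observed
  triples and the noiseless oracle is ≈ 0.85 — an irreducible ceiling no
  model can beat — so the recovery fixture lowers the noise to make a ≥ 0.8
  held-out bound a statement about the model rather than about the noise
  (ceiling ≈ 0.93).

## What the synthetic experiments do and do not show

They show that the full pipeline — encoding, training, evaluation,
attribution — can *recover a planted effect*: a model trained on the recovery
fixture reaches held-out Spearman ≈ 0.9 on the valid head, collapses when the
accessibility channel is zeroed at prediction time, and concentrates
integrated-gradients mass on the planted protospacer+PAM × accessibility
cells. They do **not** show that the architecture predicts real prime-editing
outcomes: the generator's effect structure is far simpler than biology, its
sequence content is i.i.d., and no claim about real-data accuracy can be made
without experimental training data.

## Reproducibility and numerics

Every stochastic step takes an explicit seed; CLI runs write a
`manifest.json` with the merged configuration and dataset digest. Model
parameters are float32; optimizer moments, Lookahead slow weights, and all
exactness oracles run in float64. Checkpoints are `.npz` files storing
parameters, the model configuration, and the seed; loading verifies the
configuration and every parameter shape.
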