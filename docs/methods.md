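# Methods

`ddacl` predicts drug–disease associations from learned text-style
representations of both modalities. This note documents the model, its
assumptions, the defaults that matter, and the limits of what the synthetic
benchmark can demonstrate.

## Model

**Drug encoding.** A drug enters as a SMILES string. An encoder adapter maps
it to a token-embedding matrix `M ∈ R^{L×384}` with `L ≤ 512` (longer
sequences are truncated). A learned scoring network

    e_j = W2 · tanh(W1 · m_j + b1) + b2

assigns a scalar to each token; softmax-normalized weights
`α_j = softmax(e)_j` (computed with max-subtraction for numerical stability)
give the pooled drug vector `M_d = Σ_j α_j m_j`, a convex combination of the
token rows. The weights are exportable per token for inspection. The
attention-free ablation replaces `α` with uniform weights (mean pooling).

**Disease encoding.** A disease enters as up to three text fields — name,
synonyms, definition. Each non-empty field is encoded to a 768-vector (the
first-position aggregate a transformer text encoder would emit). Fields are
combined by weight-normalized fusion `D_fused = Σ_f w_f v_f / Σ_f w_f` over
the *present* fields (absent fields are dropped and the weights renormalize;
the default weights are `(1, 1, 1)`). The fused vector is projected to 128
dimensions by a linear map, seeded at random by default.

**Contrastive enhancement.** Two projection heads (linear → ReLU → linear →
layer normalization, output dimension 256) map `M_d` and `D_i` into a shared
space. For a batch of known pairs the temperature-scaled similarity matrix
`S_ij = z_drug_i · z_disease_j / τ` feeds an InfoNCE loss,

    loss(d, i) = −log( exp(S_di) / Σ_j exp(S_dj) ),

which pushes each drug's matched disease above the other in-batch diseases.
The loss is reduced as the **mean** over positives (the summed form differs
only by a constant factor, and the mean is batch-size independent).
Negatives are in-batch only — the denominator runs over the batch columns —
and the loss is written in the drug→disease direction only. A third head
(affine + ReLU) maps the concatenated projected pair to an interaction
feature `Z_interact`; because the interaction feature does not enter the
similarity matrix it receives no gradient and acts as a fixed random
cross-modal feature map. The final enhanced feature is the concatenation

    X = [M_d ; D_i ; Z_drug ; Z_disease ; Z_interact]

(384 + 128 + 256 + 256 + 256 = 1280 dimensions at the defaults). The
contrastive-free ablation uses `[M_d ; D_i]` alone.

**Scoring and thresholding.** A random forest (250 trees, depth ≤ 25,
min-split 5, min-leaf 2, √p features per split, balanced class weights)
scores each pair as the soft vote — the mean over trees of the positive-class
probability — so scores live in `[0, 1]` and support both ranking and
thresholded metrics. The wording "majority voting" and the averaging formula
disagree in the source description of this family of models; the averaging
form is implemented because ranking metrics require graded scores. Binary
calls use the Youden-optimal threshold `θ* = argmax_θ TPR(θ) − FPR(θ)`,
searched over all midpoints of adjacent distinct scores plus ±∞ sentinels,
ties broken toward the smallest threshold (favoring sensitivity). θ* is
always selected on training-fold scores and applied unchanged to the test
fold, so no test labels leak into threshold selection.

## Training

The projection heads are trained with Adam (learning rate 5 × 10⁻⁴, the
published setting) on the training fold's positive pairs, batch size 128,
for up to 25 epochs with early stopping (patience 8) on a 10% held-out
positive split. Training runs in float32 — it halves linear-algebra time and
remains exactly reproducible per seed — and the parameters are returned in
float64. Twenty-five epochs is where the training loss plateaus on the
reference benchmark; the epoch budget is a config knob.

The attention-pooling network receives no training signal of its own in the
source description; here it is trained jointly under the same contrastive
objective (gradients flow from the loss through the pooled drug vector into
the scoring network), which is the smallest consistent choice. An untrained
(seeded random) mode and the mean-pooling ablation are both available. The
disease 768→128 projection is a fixed seeded random map by default, with a
flag reserved for joint training. Whether any of these components are frozen
or trained end-to-end in the original system is not stated; these choices
are documented interpretations, not reproductions.

The projection dimension is stated as 128 in one place and 256 (the tuned
value) in another in the source material; 256 is the default here and the
value is configurable. With layer-normalized 256-dimensional outputs and
τ = 0.25, initial logits are large (the softmax starts saturated); the
learned gain/bias of the normalization layer rescales them during training.

## Evaluation protocol

* **Balanced sampling.** Known associations are positives; an equal number
  of unknown pairs is drawn uniformly without replacement, once, before any
  splitting, so all folds share one labeled universe.
* **5-fold CV**, stratified by label; every pair is tested exactly once.
* **Cold start.** C1 holds out 20% of drugs (all their pairs go to test and
  the drugs never appear in training), C2 mirrors this for diseases, C3
  requires both entities of a test pair to be held out and **discards**
  pairs touching exactly one held-out entity — the strictest leak-free
  reading of a double cold-start.
* **Metrics.** AUROC by the rank/concordance formula (ties count ½ — agrees
  with trapezoidal ROC integration to 1e-9); AUPR by step (average-precision)
  interpolation; F1 and accuracy at θ*. Ranking metrics (P@K, R@K, MRR,
  NDCG@10 with binary gains and 1/log₂(rank+1) discounts) are macro-averaged
  over query drugs ranking their candidate diseases (a flag flips the
  direction); queries with no relevant candidate are excluded with a warning.
  Top-K metrics are computed on out-of-fold CV scores, so every candidate
  pair is scored by a model that never trained on it.
* **Noise robustness.** Gaussian noise with standard deviation ρ·σ_c per
  feature column (σ_c from the clean training features; zero-variance
  columns stay clean) is injected into the assembled features for the train
  and/or test phase. The `apply_to` switch restricts noise to the raw
  embedding block, the full enhanced vector, or both. The enhancer itself
  trains on clean embeddings: noise enters the classifier's view of the
  features, which keeps the comparison across noise levels exactly
  controlled (the representation is shared) at a fraction of the cost of
  re-propagating noise through training.
* **Diagnostics.** Feature quality samples up to 1,000 positive and 1,000
  negative pairs, reports mean cosine similarities, Cohen's d with the
  pooled (ddof = 1) standard deviation, and the AUROC of similarity as a
  classifier. Clustering runs seeded KMeans (k = 6) on disease embeddings
  against category labels and reports NMI, ARI and silhouette.

## Synthetic benchmark

Real curated association tables are sparse bipartite graphs; the generator
emulates that structure with a planted low-rank model. Latent factors
`u_d, v_i ∈ R^8` are drawn from seeded normals; each association is sampled
independently with probability `sigmoid(u_d·v_i + b)`, where `b` is solved
by bisection on the realized score matrix so the expected density hits the
target (0.05 by default at the reference scale of 200 drugs × 150 diseases
— dense and small enough for a desk-scale run while keeping the 1:1
balanced-sampling protocol meaningful). Diseases belong to one of six
latent-space categories (centroids separated by at least 3× the encoder
noise, within-category spread 0.7), mirroring the six-way taxonomy used in
clustering diagnostics. Drug strings come from a tiny SMILES grammar
(single bonds, rings of six, branch depth ≤ 2) whose concatenative units
keep every generated string chemically parseable; disease texts are filled
from per-category templates, with ~10% of synonym/definition fields left
empty to exercise the missing-field fusion path.

Oracle encoder adapters embed the latent factors through fixed random linear
maps plus per-token Gaussian noise (sd 0.3), so the planted signal is
recoverable by pooling; the hashing adapter produces stable pseudo-random
embeddings with no semantic content and serves as the matched null — under
cold-start splits it cannot beat chance, because entity identity is all it
encodes.

What passing tests on this benchmark **do** show: the pipeline recovers a
planted cross-modal signal end to end, respects its split contracts, and
degrades gracefully under noise. What they **do not** show: performance on
real pharmacological data, where token embeddings carry chemistry rather
than a linear image of a latent factor, disease texts are free prose, the
association matrix is far sparser (~0.0016), and negatives are unverified
rather than known-absent.

## Numerical choices and problem sizes

* Softmax and log-sum-exp are always max-stabilized; attention weights sum
  to 1 within 1e-9.
* Layer normalization uses ε = 1e-5; the layer-norm of an all-equal row is
  zero, so a zero input yields the bias vector.
* Cosine similarity with a zero vector is defined as 0 (logged).
* Youden candidates are midpoints of adjacent distinct scores plus ±∞, a
  finite and complete search space.
* The protocol-comparison experiments use single splits per seed (cold-start
  modes are single holdouts by definition; the noise ladder uses one
  stratified 80/20 split per seed with the representation stage shared
  across noise levels). Five seeds per experiment; the reference 5-CV runs
  in full.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-entity encoder noise is keyed by a
  BLAKE2b digest of (seed, entity), so results are independent of iteration
  order and of `PYTHONHASHSEED`.

## Known limitations

* No pretrained molecular or biomedical text encoders ship with the
  package; the adapter protocol (`encode_tokens` / `encode_text`) is the
  integration point for them, and all shipped adapters are synthetic.
* The interaction head is untrained by construction (see above); a trained
  variant would require adding its output to the contrastive objective.
* In-batch negatives only; no hard-negative mining, momentum encoders or
  memory banks.
* The forest offers no probability calibration; scores are soft votes.
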