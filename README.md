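# ddacl — drug–disease association prediction with contrastive feature enhancement

`ddacl` is a library and CLI for predicting which drugs treat which
diseases from learned representations of both modalities. It is aimed at
computational drug-repositioning work: you bring a drug table (SMILES
strings), a disease table (name / synonyms / definition texts) and a table
of known associations; the package builds pooled molecular embeddings and
fused disease-text embeddings, aligns the two modalities contrastively,
scores candidate pairs with a random forest, and evaluates the result under
warm-start and cold-start protocols.

## The model in brief

For a drug with token embeddings `m_1..m_L` (L ≤ 512), a learned attention
network pools them into a single vector:

    e_j = W₂ · tanh(W₁ m_j + b₁) + b₂,   α = softmax(e),   M_d = Σ_j α_j m_j

Disease field texts are encoded to 768-vectors, fused by weighted averaging
over the present fields, and projected to 128 dimensions (`D_i`). Two
projection heads map `M_d` and `D_i` into a shared 256-dimensional space
where an InfoNCE loss with temperature τ = 0.25 separates known pairs from
in-batch negatives:

    S_ij = z_drug_i · z_disease_j / τ,    loss = −mean log softmax_i(S_d·)

Each candidate pair is scored by a 250-tree random forest on the enhanced
feature `[M_d ; D_i ; Z_drug ; Z_disease ; Z_interact]` (soft vote, in
[0, 1]) and binarized at the Youden-optimal threshold
θ* = argmax (TPR − FPR), selected on training scores only.

No pretrained transformer ships with the package: encoders are pluggable
adapters (two methods, `encode_tokens` and `encode_text`), and the built-in
synthetic benchmark provides oracle adapters with a planted, recoverable
low-rank signal plus a hash adapter that serves as a content-free null.
See `docs/methods.md` for the full model, defaults and limitations.

## Worked example

```bash
ddacl simulate --seed 0 --out bench/            # 200 drugs x 150 diseases
ddacl encode   --data bench/ --out cache/ --encoder oracle --seed 0
ddacl evaluate --data bench/ --cache cache/ --out results/ --seed 0
```

The `evaluate` command runs stratified five-fold cross-validation — per
fold it trains the contrastive heads on the training positives, fits the
forest, picks θ* on training scores and evaluates held out — and prints the
mean metrics:

```
{
 "auroc": 0.9156193539896954,
 "aupr": 0.9151884270252442,
 "f1": 0.813107564313549,
 "accuracy": 0.8213960146587265
}
```

AUROC ≈ 0.92 means a random true association outranks a random non-
association 92% of the time — the pipeline has recovered most of the
planted signal (shuffling the labels drops it to ≈ 0.5). Cold-start
evaluation is one flag away:

```bash
ddacl coldstart --data bench/ --cache cache/ --out cs/ --mode C3 --verify --seed 0
```

C1 holds out 20% of drugs entirely, C2 20% of diseases, C3 both; scores
drop in that order (≈ 0.90 / 0.90 / 0.86 on the synthetic benchmark),
mirroring the increasing difficulty of predicting for entities never seen
in training. `quality` reports embedding separability and disease-text
clustering diagnostics, and `attn-export` writes the per-token attention
weights as TSV.

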