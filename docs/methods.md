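# Methods

## Task and label model

A screening row is the tuple x = {d1, d2, c, t, ri1, ri2} — two drug names,
a cell line, its tissue of origin, and the two single-drug sensitivities
(relative inhibition) — together with a Loewe synergy score on the nominal
scale [−100, 75]. The binary synergy class is y = 1 iff Loewe > 5, with a
strict inequality: a score of exactly 5 is negative. Tissues with fewer
than 4000 rows are *rare* (strict "less than": a tissue at exactly 4000 is
common); models are trained on common tissues and adapted to each rare
tissue from k labeled examples.

## Serialization and prompt

Rows are rendered with a fixed six-sentence text template:

    The first drug is {d1}. The second drug is {d2}. The cell line is {c}.
    Tissue is {t}. The first drug's sensitivity using relative inhibition
    is {ri1}. The second drug's sensitivity using relative inhibition is
    {ri2}.

wrapped as

    Decide in a single word if the synergy of the drug combination in the
    cell line is positive or not. {serialized} Synergy:

Two deliberate choices:

* The template's trailing period before `Synergy:` is not duplicated — the
  serialized block already ends in one, so the wrapper contributes a single
  space and the cue. Any one of the adjacent punctuation readings is
  faithful; this one avoids a double period.
* Sensitivities are rendered from the *source text* of the file they were
  read from (`ri1_text`/`ri2_text`) when available, falling back to the
  shortest round-trip decimal. This keeps prompts bit-stable across
  read/write cycles and avoids float-representation drift.

Serialization never truncates names; context-length handling belongs to the
model layer, which truncates prompts from the left so the suffix ending in
`Synergy:` always survives.

## Classifier model

The backbone contract is a decoder-only causal transformer exposing
per-position final-layer hidden states and tied-embedding LM logits.
Batches are padded on the left so the hidden state at the last position —
always the prompt's own final token — feeds an affine head H → 2 trained
with cross-entropy (no class weighting). The head bias is always
zero-initialized; head weights default to zero (an untrained model scores
exactly 0.5) and can be seeded-random so that full-mode fine-tuning passes
gradients into the backbone from the first step.

Two tuning strategies: `full` (backbone + head) and `head_only` (backbone
frozen; the probe is fit on cached last-token features, which makes the
freeze bit-exact by construction and is orders of magnitude faster). The
optimizer is Adam with decoupled weight decay (applied to matrix-shaped
parameters only); the reference defaults are lr 5e-5, weight decay 0.01,
4 epochs, batch 8 — the conventional recipe for a pretrained
GPT-2-small-scale backbone (H = 768), which is the reference configuration
of `BackboneSpec`.

Zero-shot labeling is constrained two-candidate scoring: the total
log-likelihood of `" Positive"` and of `" Not positive"` appended to the
prompt, combined by a two-way softmax. Free generation is not parsed —
small models cannot be relied on to emit one of the two labels verbatim.

### The shipped backbone

No pretrained weights ship with the package. The trainable instance is a
small random-initialized byte-level transformer (vocabulary: 256 bytes plus
PAD; H = 32, 2 layers, 2 heads, context 256–384), built on an in-package
NumPy reverse-mode autodiff engine whose gradients are validated against
central finite differences in the test suite. Position indices count from
each row's first real token, so left-padded and solo encodings agree
exactly.

Training a *random* tiny transformer differs from fine-tuning a pretrained
one, and the simulation studies use settings chosen for that regime, as a
package-level design decision: initialization scale 0.1 (at the
GPT-2-style 0.02 the attention pattern is so uniform that ~250-byte prompts
average away and last-token features are nearly constant across examples),
learning rate 3e-3, and seeded random head weights. The `FineTuneConfig`
defaults are unchanged.

Known limitation: a byte-level model with learned absolute positions has no
length-invariant reading skills. If the surface forms of train and test
prompts differ in length (for instance, tissue names of different byte
widths), every downstream byte shifts position and transfer degrades or
inverts. The warm-up study therefore uses equal-width tissue names; a
pretrained subword model would not need this crutch.

## Warm-up

The classifier is fine-tuned in full mode on common-tissue rows only:
80/20 label-stratified split, per-epoch validation, and the epoch
checkpoint with the best validation AUPRC restored at the end (AUPRC is the
primary metric under label imbalance; a flag selects the final epoch
instead). Rare-tissue rows are rejected with a `LeakageError`. The warmed
model keeps its trained head, so at k = 0 it predicts with that head; an
unwarmed model, whose head was never trained, uses the generative zero-shot
path.

## k-shot protocol

Per rare tissue, an 80/20 train/test split stratified by label: per-class
test counts are round-half-up of test_fraction × class size, a class with
fewer than 2 examples is a protocol error. "Equally represented" is read
as proportion-preserving stratification (not 50/50 forcing), consistent
with shot sets that follow the tissue's own label distribution.

Shot sets for k in (2, 4, …, 128) are nested: per-class pools are shuffled
once (seeded) and each set takes prefixes, so S_k ⊂ S_2k automatically.
Per-class quotas are round-half-up of k × class proportion, repaired to
keep at least one example of each class and sum k (the majority class
absorbs the adjustment, deterministically). k larger than the training
split, or with infeasible quotas, is dropped with a warning — small
tissues truncate their schedule naturally.

Grid cells (model × tissue × k × seed) are independent: each re-fits a
fresh copy of the arm's base state on the full nested shot set rather than
continuing from the previous k (the alternative is available by chaining
manually, but independent cells are reproducible in isolation). The test
split is fixed across k, enforced by fingerprint. Arms without a zero-shot
path record k = 0 as not-applicable.

## Baselines

All baselines consume only (d1, d2, c, ri1, ri2); the tissue name is
provably absent from every feature set, because evaluation tissues never
occur in training and an indicator would carry no transferable signal.

* **Collaborative filtering** — logistic matrix factorization
  p = σ(⟨u_{d1} + u_{d2}, v_c⟩ + b_{d1} + b_{d2} + b_c + b_0), full-batch
  Adam on cross-entropy, latent dimension 32 by default. Additive drug
  embeddings give exact symmetry under swapping the pair (drug bias terms
  are summed before the rest so the symmetry is bit-exact). Unseen
  entities fall back to the mean embedding and bias of their type; k-shot
  adaptation warm-starts from the fitted state.
* **Gradient-boosted trees** — one-hot drug1 | one-hot drug2 | one-hot
  cell | ri1 | ri2 (sparse), XGBoost with the reference configuration
  (eta 0.3, 1000 rounds, depth 20), single-thread hist for determinism.
  "Fine-tuning" a tree ensemble is realized as boosting continuation:
  extra rounds (default 50) on the shot set starting from the
  common-tissue model.
* **TabTransformer-style model** — embeddings for the two drugs and the
  cell (dim 32), a learned column embedding, a stack of self-attention
  blocks (6 layers, 8 heads by default — depths unreported anywhere, so
  conventional values recorded in `TabConfig`), then the flattened
  contextual embeddings concatenated with the two sensitivities
  (standardized with statistics frozen from the common-tissue fit) through
  a feed-forward classifier. Training: 50 epochs at lr 1e-4, weight decay
  0.01, best-validation-AUPRC checkpoint; k-shot is exactly one epoch at
  the same lr/decay. Unseen cells get a mean-initialized embedding slot
  (logged).

## Metrics

AUROC is the Mann–Whitney statistic — P(score_pos > score_neg) plus half
the tie probability — computed from average ranks. AUPRC is average
precision in descending-score order, with tied scores processed as one
group using the precision after the whole group; average precision is used
rather than trapezoidal PR interpolation because interpolation is
optimistically biased at low prevalence. Both error on single-class label
sets, are invariant under strictly monotone score transforms, and match
exhaustive pairwise / rank-scan oracles to 1e-12 in the tests.

## Synthetic screens

Drug i carries a latent a_i ~ N(0, I_d) and cell c a latent
b_c = base + spread·N(0, I_d) around a shared unit direction; a tissue's
*shift angle* rotates its cells' latents in a fixed coordinate plane,
making the tissue out-of-distribution while preserving its marginal score
scale (angle 0 is statistically indistinguishable from in-distribution,
checked by a two-sample KS test). The pre-clamp score is
scale·(α·interaction + σ·ε) + offset, clamped to [−100, 75]; prevalence is
controlled by offset/α/σ and can be computed by Monte Carlo
(`planted_prevalence`, 100k draws by default). Sensitivities are
100·σ(⟨a_k, b_c⟩ + noise) ∈ [0, 100], matching relative-inhibition
magnitudes, and are written with three decimals so prompts are compact and
stable.

Three interaction mechanisms:

* `product` ⟨a_i ⊙ a_j, b_c⟩ — pair-specific synergy an additive CF can
  only approximate (the realistic, misspecified regime);
* `additive` ⟨a_i + a_j, b_c⟩ — exactly the CF functional form
  (recoverable regime), and, because the sensitivities are monotone in
  ⟨a_k, b_c⟩, largely readable from the two printed RI values;
* `ri_linear` — synergy depends only on ri1 + ri2 (an easy planted rule
  for tree learners).

All mechanisms are symmetric under swapping the pair. What the generator
does **not** emulate: pharmacological dose-response surfaces, real
DrugComb marginals, replicate structure, or names with literature priors —
so passing simulation studies demonstrates the *protocol and optimization
machinery*, not chemistry; with a pretrained backbone the text route could
additionally exploit prior knowledge about real drug names, which no
synthetic screen can test.

## Simulation studies (problem sizes)

The packaged studies (`promptsyn.experiments`) fix their own conditions;
sizes are chosen for a single CPU:

* **CF recovery** — additive mechanism, 30 drugs, 20 cells, n = 5000,
  α = 2.5, σ = 0.1; held-out AUROC of CF (d = 32, 400 steps).
* **Null calibration** — α = 0, σ = 1 (prevalence ≈ 0.4), n = 2000; CF,
  XGBoost, the attention baseline and a head-probed tiny LM are all
  expected near chance. Model capacities are reduced (100 boosting
  rounds, 8 epochs) since under the null the AUROC distribution does not
  depend on capacity.
* **Distribution shift** — two common tissues (n = 4000) plus an
  unshifted and a 150°-shifted rare tissue (n = 300 each); CF trained on
  common tissues is evaluated on both.
* **Warm-up benefit** — additive mechanism, 12 drugs, two common tissues
  (n = 1200 total), one in-distribution rare tissue (n = 240), equal-width
  tissue names; the warmed tiny classifier (4 epochs full fine-tuning at
  lr 3e-3, batch 16) is compared with a cold one at k ∈ {0, 8, 32}, both
  arms sharing the same nested shot sets and head-probe settings
  (lr 0.02, 30 epochs) for k > 0.

## Numerical choices and degenerate inputs

* float32 parameters and activations for the transformer; the autodiff
  engine itself is dtype-preserving and is tested in float64.
* The fused attention softmax clamps exponent arguments away from the
  subnormal range and assigns exactly zero probability to masked keys; a
  fully masked row (a padding query) yields a zero attention output.
* Quota and split rounding is round-half-up throughout; repair order is
  deterministic (majority class absorbs adjustments).
* Incomplete CSV rows (any of the seven fields missing or unparseable) are
  dropped and counted, never imputed. Records are not deduplicated and the
  drug order is preserved as read.
* Single-class fine-tuning data warns but proceeds (the optimization is
  well-defined); single-class fitting for CF/GBT/Tab and single-class
  metric evaluation are errors.
* Seeds: every stochastic component (generator, splits, shot sampling,
  initialization, batch order) takes an explicit seed; grid cells derive
  per-tissue seeds from (seed, tissue name) by CRC so adding a tissue does
  not reshuffle the others.
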