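# Methods note

This note records the model, its parameters, the synthetic data design, and
the numerical choices made in this implementation, so results can be
interpreted and reproduced without reading the source.

## 1. The cognitive model

### 1.1 Instance-based learning core

Memory holds instances `i = (attributes, utility u_i, occurrence times T_i)`.
At decision time `t` the activation of instance `i` against a queried option
`k` is

```
A_i(t) = ln( Σ_{t'∈T_i} (t − t')^(−d) )
       + μ · Σ_{j ∈ attrs(i) ∩ attrs(k)} ω_j (S_ij − 1)
       + σ·ξ
```

* The first term is power-law recency/frequency decay with decay rate `d`.
* The second is partial matching: `S_ij ∈ [0,1]` is the similarity between
  the instance's and the query's value on attribute `j`, `μ` the mismatch
  penalty, `ω_j` the attribute weight. **The sum runs over attributes present
  in both the instance and the query** (intersection rule). This lets
  instances recorded under a sparser schema — e.g. shape-only trials from an
  early transfer phase — match later, richer queries without penalty for
  attributes they never carried, which is what makes cross-phase transfer
  possible at all.
* `ξ` is transient noise. Following common IBL-library convention the
  default draw is logistic via `ln((1−u)/u)`, `u ~ Uniform(0,1)`; a standard
  normal is available through `noise_dist="normal"`.

Retrieval probability is a temperature-`τ` soft-max over activations
(computed max-shifted for numerical stability), and the blended value of
option `k` is `V_k = Σ_i P_i u_i`.

The decision clock counts choices: it starts at 0, prepopulated instances
live at `t' = 0`, and the trial being decided is evaluated at
`clock + 1`, so every stored occurrence is strictly in the past and
`(t − t')^(−d)` is always finite. Re-observing an identical
(attributes, utility) event appends a new occurrence to the existing
instance rather than duplicating it, which is what produces the `ln m`
frequency bonus for an event seen `m` times at equal lags.

All instances live in a single pooled store. Options are differentiated at
query time by partial matching, not by per-option partitions; this is what
lets an agent generalize across the unique option combinations that the
bandit presents on every trial.

### 1.2 Default parameters

| Parameter | Default | Role |
|-----------|---------|------|
| `d`       | 0.5     | memory decay |
| `μ`       | 1.0     | mismatch penalty |
| `ω_j`     | 1.0     | attribute weights (scalar or per-attribute) |
| `σ`       | 0.25    | activation noise scale |
| `τ`       | `σ·√2`  | soft-max temperature |
| prepopulation utility | 1.0 | optimistic initial instance at `t'=0` |

Prepopulation at the tasks' maximum reward makes unexplored options look
good, inducing exploration without an explicit exploration bonus. All
ablation agents run with these same defaults (zero fitted parameters), so
BIC comparisons use `k = 0` and reduce to a monotone transform of mean RSS.

### 1.3 Generative-model similarity (`Sim_GM`)

* **Diagonal-Gaussian β-VAE posteriors** `N(μ, diag(σ²))`:
  `Sim_GM(p, q) = exp(−KL_sym(p, q)/λ)` with the symmetrized KL
  `KL_sym = ½(KL(p‖q) + KL(q‖p))` computed in closed form, scale `λ = 1`.
  This maps `[0, ∞)` divergence into `(0, 1]` with self-similarity 1.
* **Text embeddings**: cosine similarity, clamped to `[−1, 1]`; an optional
  `(1+cos)/2` rescale maps it into `[0, 1]`.

### 1.4 The four ablation agents

* **IBL** — hand-crafted features only (shape/color/texture values, or the
  six binary expert email features plus the candidate action), exact-match
  similarities.
* **GER** — adds the generative representation as one more memory attribute
  whose similarity is `Sim_GM`; everything else identical to IBL.
* **GIN** — maintains an internal IBL *teacher* updated with every observed
  outcome, and a utility network (multilayer perceptron over the
  representation vector) periodically refit to the teacher's current blended
  values on the options seen so far ("train to match"). Action values come
  from the network, so at decision time only the generative representation
  is consulted.
* **GINGER** — runs GIN and GER side by side on the same experience stream
  and averages their value tables with exact weights 0.5/0.5.

Utility-network presets: two 64-unit ReLU layers over the 9-dim latent
posterior mean for visual tasks; two 128-unit layers over the email
embedding with a 2-dim one-hot of the candidate action appended for the
phishing task (the network must be action-conditional to rank the two
categorizations of one email). Output layers are zero-initialized so an
untrained network predicts 0 everywhere rather than noise.

## 2. Tasks and synthetic data

No human datasets, trained checkpoints, or proprietary embedding services
are available offline, so every data source is synthesized from seeds. The
generators are designed so the *structure* that the models exploit is
present by construction, while everything incidental is random.

* **Contextual bandit.** Three options per trial; within each of the three
  dimensions (shape, color, texture; 3 values each) the values are a random
  permutation over the three screen positions, so all 9 features appear
  exactly once per trial and each feature identifies exactly one option.
  One "feature of interest" per episode; choosing the option carrying it
  pays 1 with probability 0.75, otherwise 0.25. Episode lengths are uniform
  on {20,…,25}; the feature of interest changes between episodes (no
  immediate repeat).
* **Transfer of learning.** Three 15-trial phases (45 trials): shape-only,
  then shape+color, then shape+color+texture. Each phase's rewarded feature
  lives in the newest dimension, so earlier dimensions become distractors
  and prior instances help only through partial matching.
* **Phishing.** A 239-email synthetic corpus, half phishing. Each email has
  six binary expert-style features (mismatched sender, credential request,
  urgency, offer, suspicious subject, link mismatch) whose incidence is
  `0.5 ± effect/2` depending on the label (default effect 0.4), and an
  embedding built as a linear map of the centered feature flags plus
  label-independent nuisance coordinates plus Gaussian noise — so embeddings
  carry class signal (a logistic read-out exceeds 60% held-out accuracy)
  without being trivially separable. 10% of the corpus (round half up:
  24 of 239) is set aside, in seeded order, for pretraining: the correct
  categorization is recorded with reward 1 and the incorrect with reward 0.
* **Stimulus images.** 32×32 RGB renders of the 39 factor combinations
  (3 shapes, ×3 colors, ×3 textures). The β-VAE (latent dimension 9, β = 1,
  64-unit hidden layer) is trained once per experiment on all renders;
  posteriors are cached.

## 3. Numerical choices

* **numpy-only neural networks.** No GPU/autograd framework is assumed.
  The MLP and β-VAE use hand-written backpropagation with Adam; gradients
  were verified against central finite differences during development.
* **β-VAE centering.** With a sigmoid output and uncentered images, the
  decoder bias absorbs the mean image and the encoder receives almost no
  gradient — posteriors collapse to the prior. The implementation therefore
  centers inputs on the training-set mean and uses a *linear* decoder
  output (reconstructions add the mean back and clip to [0,1]). Training is
  mini-batched (batch 8, learning rate 2e-3, 200 epochs by default). With
  these choices distinct stimuli get clearly distinct posteriors
  (symmetrized KL ≈ 8–170) and the information-bottleneck effect of β is
  measurable (reconstruction error increases monotonically over β = 0, 1, 4).
* **Soft-max stability.** Retrieval probabilities and network losses use
  max-shifted exponentials.
* **Seed discipline.** One master seed; every stream (agent noise, task
  schedule, VAE init, corpus) gets an independent child seed via numpy
  `SeedSequence(entropy=master, spawn_key=path)`. Identical configurations
  reproduce output files byte for byte (CSV floats are formatted to 10
  significant digits).
* **BIC.** `BIC = n·ln(RSS/n) + k·ln(n)` with `k = 0` (no fitted
  parameters). A perfect fit (RSS = 0) is reported as −∞ with a warning.

## 4. Limitations

* All behavioral references are synthetic. The default comparison curve is
  a saturating exponential (chance → 0.85), not human data; RSS/BIC numbers
  therefore validate the *machinery*, not any empirical claim about people.
  External reference curves can be supplied as CSV.
* The transfer task's per-phase reward contingencies are one reasonable
  design (newest-dimension targets, 75/25 scheme); other readings are
  possible and the scheme is isolated behind `TransferTaskSpec`.
* Email embeddings are a seeded linear-plus-noise surrogate, not the output
  of a large language model; absolute phishing accuracies are not
  comparable to results obtained with real embedding services, though the
  agent ordering is structurally driven by the same mechanism (embedding
  similarity of same-class emails).
* The β-VAE is small (single hidden layer, 32×32 inputs) and trained on 39
  images; it is a faithful miniature of the representation pipeline, not a
  vision model.
* Utility networks retrain on the full experience buffer at a fixed cadence;
  no replay subsampling or early stopping is implemented, which bounds the
  practical stream length (hundreds of trials, as used here).
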