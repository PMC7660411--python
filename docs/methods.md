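# Methods

## Model and procedure

`perturbgen` implements a targeted adversarial-perturbation model for
transcriptomes. A frozen softmax classifier `f` defines the state space
(tissue or tumor classes); a generator `G` learns an additive per-gene
perturbation `P = G(x)` such that `x_adv = x + P` is (i) classified as a
chosen target class `t` by `f`, (ii) indistinguishable from real
target-class samples to a least-squares discriminator `D`, (iii) small in
L2 norm, and (iv) anchored in L1 to random draws `r_t ~ N(μ_t, Σ_t)` from
the target class's empirical distribution. The four terms are summed with
unit weights by default. Training alternates one discriminator step and
one generator step per minibatch; the classifier is trained beforehand
(categorical cross-entropy, the only standard choice for a softmax
classifier) and its weights are never touched afterwards — a test asserts
they are bitwise unchanged.

The whole stack is written against an in-package NumPy layer library
(dense, batch norm, ReLU/leaky-ReLU/tanh, residual blocks, Adam) with
hand-derived backpropagation; a central-difference test validates the
composite generator gradient through both frozen networks.

## Data model and normalization

Expression matrices are held samples × genes with a tracked normalization
state. The preprocessing chain for raw FPKM-like input is log2(v+1)
(pseudocount +1, the field convention for FPKM zeros), quantile
normalization across samples (rank-based, ties receive the mean of the
reference values at their occupied ranks), optional GMT gene-set
subsetting, then per-gene min-max scaling to [0, 1]. Min-max scaling is
fitted on the full assembled matrix by default — patient samples should be
appended before normalization so they share the reference scale — and the
fitted scaler is retained for projecting later samples and for inverse
mapping. Constant genes map to 0 rather than being dropped, keeping gene
indexing aligned with gene sets. Quantile normalization is refit jointly
by default when new samples are appended; projecting onto a frozen
reference distribution can be had by normalizing the reference once and
reusing its scaler.

## Key numerical choices

* **L_td reduction.** The target-distribution term is the raw L1 distance
  `Σ_g |x_adv,g − r_t,g|` (the formula as defined), averaged over the
  minibatch only. This makes L_td the dominant term at realistic gene
  counts, which is what pulls adversarial samples tightly into the target
  distribution and produces near-perfect attack rates; a per-gene-mean
  reduction is available (`LossWeights(td_reduction="mean")`) for
  gene-set-size-independent loss balance, but in our experiments it
  equilibrates visibly short of perfect validity (~96–97% on the standard
  benchmark versus 100% for the raw sum).
* **Margin loss on logits.** The targeted margin `max(max_{i≠t} z_i − z_t,
  κ)` operates on pre-softmax logits (following its source formulation),
  κ = 0; `adv_on_probs=True` switches to softmax probabilities.
* **Σ_t diagonal.** With genes ≫ samples the full class covariance is
  singular; target vectors are drawn gene-wise from the diagonal. Full-
  covariance sampling (eigenvalues floored at zero) exists behind
  `class_stats(..., full_cov=True)`. Draws are not clipped to [0, 1]: the
  anchor is a regression target, not a sample.
* **Variance convention.** Population (divide by n) everywhere: class
  statistics and the significance rule's SD.
* **Residual blocks.** Two width-128 dense+BN stages, identity skip added
  before the final ReLU (the block structure is otherwise unconstrained).
  The generator's output layer carries neither batch norm nor ReLU — batch
  norm there would fight the tanh bound.
* **Batch norm.** Momentum 0.9 for running statistics (desk-scale runs are
  a few hundred minibatches, so slowly-adapting statistics would lag);
  inference always uses frozen running statistics, making perturbation
  generation deterministic for a trained model. During generator steps the
  discriminator is evaluated with batch statistics but without updating
  its running averages.
* **Splits.** Stratified: 90/10 for the classifier, 80/20 for the GAN,
  floor(fraction·n) per class clamped to [1, n−1]; singleton classes go to
  training with a warning. "Epoch" means one shuffled pass over the
  training samples, reshuffled per epoch from the master seed.
* **Discriminator real pool.** Real samples shown to D are exclusively
  target-class training samples (drawn with replacement per minibatch), so
  D scores membership in the target distribution — consistent with L_td's
  anchoring.
* **Significance rule.** Mean and SD are computed over the genes of the
  single sample's raw perturbation vector P = G(x) (not the clipped
  effective change; `x_adv − x` can be substituted by the caller), with
  strict inequalities at mean ± k·SD. Tie-breaks in ranked gene lists are
  lexicographic by gene id, making outputs deterministic.

## Synthetic benchmarks

The simulator emulates the strong class signal of large expression
compendia directly on the [0, 1] scale the networks consume: each class
draws a per-gene mean uniformly (default bounds 0.1–0.9, so additive
Gaussian noise of sd 0.05 rarely hits the clip), and samples are mean +
noise, clipped to [0, 1]. The standard multi-class benchmark is 10 classes
× 50 samples × 200 genes, noise sd 0.05 — large enough for the fixed
optimization budget (30 classifier epochs at batch 32; 150 GAN epochs at
batch 128), small enough to train in about a minute on one CPU.

The paired tumor/normal benchmark plants known programs: tumor mean equals
normal mean with +δ on 10 "up" genes and −δ on 10 "down" genes (δ = 0.4),
baseline means drawn mid-range (0.3–0.7) so the planted shifts are mostly
realizable within the clip, 250 samples per class (a TCGA-scale cohort,
which also gives the generator the same ~600-minibatch budget as the
multi-class benchmark at the fixed epoch count). Training tumor→normal and
applying the 2-SD rule to held-out tumor samples recovers the planted
programs with mean precision and recall well above 0.9 and the correct
tumor-relative direction labels; perturbations of held-out *normal*
samples have a far tighter distribution (the null contrast), and the
median |P| on unplanted genes is far below that on planted genes.

What these simulations do **not** capture: count-based noise (negative
binomial overdispersion), correlated gene modules, batch effects, and
class imbalance. Passing the benchmarks therefore demonstrates the
correctness of the optimization and the significance machinery under clean
separable signal, not performance on real cohort data — on real data the
attack rate and the stability of the gene lists must be re-established
per dataset.

## Reproducibility

Every stage derives its generator from a single integer seed
(`numpy.random.SeedSequence` chains; the CLI hashes the master seed with
the stage name so stages can be rerun independently). Training twice from
the same data, config and seed yields bitwise-identical weights. Batched
and single-sample inference may differ at ~1e-15 (BLAS summation order);
tests compare at 1e-12.

## Known limitations

* Gradient-based training in float64 NumPy is single-threaded-CPU bound;
  the architecture widths (512/1024) are kept from the reference design
  even though they are generous for 200-gene inputs.
* The adversarial margin with κ = 0 stops pushing exactly at the decision
  boundary; validity of borderline samples then rests on the L_td anchor.
* `DGETable` consumes externally computed cohort statistics; no DGE model
  is fitted here, and no multiple-testing machinery is applied beyond the
  pre-adjusted p-values.
* t-SNE embeddings are library-delegated visualization only; nothing is
  asserted about them.
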