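# Methods

## Model

Given M omics blocks X^1 … X^M measured on the same n samples and a class
label per sample, each block is mapped to a kernel matrix
K^m_ij = k(x^m_i, x^m_j).  Two kernels are implemented: linear
(K = X Xᵀ) and Gaussian RBF with the *inverse kernel width* convention

    k(x, y) = exp(−σ ‖x − y‖²),

so larger σ means a narrower kernel.  Features are standardized to zero
mean and unit variance using training-set statistics before any kernel
computation (switchable via `scale=False`); this makes a single σ
meaningful across omics with very different native scales.  Constant
features receive a unit divisor and therefore contribute nothing to
distances.

The fused meta-kernel is the convex combination K* = Σ β_m K^m with β on
the probability simplex.  Weight strategies:

* **naive** — β_m = 1/M.
* **STATIS-UMKL consensus** — compute the M × M matrix C of pairwise
  Frobenius cosines ⟨K_m, K_m'⟩_F / (‖K_m‖_F ‖K_m'‖_F); β is the leading
  eigenvector of C rescaled to sum to one (not unit ℓ2 norm, so the simplex
  constraint holds exactly).  For entrywise-nonnegative C the
  Perron–Frobenius theorem guarantees a nonnegative eigenvector up to sign;
  mixed signs after sign-fixing raise an error.  Before computing C the
  kernels are double-centered and cosine-normalized so that the cosines
  compare shape rather than scale; consequently the weights are invariant
  to positive rescaling of any input kernel.
* **SimpleMKL** — minimize the SVM dual value J(β) over the simplex.  By
  Danskin's theorem ∂J/∂β_m = −½ α*ᵀ diag(y) K_m diag(y) α* at the current
  dual optimum α*.  Each iteration projects β − s·grad (gradient normalized
  for a scale-free step) back onto the simplex and accepts the step under
  an Armijo condition on J, halving s up to 30 times; weights reaching zero
  are clamped by the projection.  Initialization 1/M, tolerance 1e-4 on the
  ℓ∞ weight change, at most 200 iterations; a vanishing projected gradient
  (e.g. duplicate kernels, where any simplex point is optimal) returns the
  current iterate with the convergence flag set.
* **SEMKL** — alternate an SVM dual solve with the closed-form group-lasso
  update β_m ← ‖w_m‖ / Σ_h ‖w_h‖, ‖w_m‖² = β_m² α*ᵀ diag(y) K_m diag(y) α*.
  Blocks with vanishing margin contribution get weight zero (the limit of
  the update).  Same initialization/tolerance/iteration cap.

Both supervised strategies are defined for binary labels only and raise on
multiclass input; naive and STATIS accept any task.  The SVM cost C is held
fixed during weight iterations and tuned jointly in the outer
cross-validation.

Weight optimization operates on centered, cosine-normalized copies of the
kernels (comparability); the SVM itself is trained on the raw fused kernels
— for Gaussian kernels cosine normalization is the identity anyway, since
the diagonal is one.  Both preprocessing switches are exposed.

## SVM layer

Classification uses a C-SVM on the precomputed meta-kernel (scikit-learn's
libsvm backend).  Multiclass tasks use one-vs-one voting, the standard
reduction for precomputed kernels.  At test time per-block cross-kernels
are computed with the *training* kernel parameters and standardization
statistics and fused with the *training* weights before the dual expansion.
AUC uses raw decision scores (no probability calibration).  The
early-integration baseline `concat` applies one Gaussian kernel to the
feature-wise concatenation of the standardized blocks.

Hyperparameter tuning is a stratified k-fold (default 5) grid search.  The
paper-scale ranges C ∈ [1, 25] and σ ∈ [5·10⁻⁵, 5·10⁻³] are discretized as
C ∈ {1, 5, 10, 15, 20, 25} and σ ∈ {5e-5, 1e-4, 5e-4, 1e-3, 5e-3}
(log-ish coverage); ties break deterministically to the smallest C, then
the smallest σ (prefer stronger regularization).  All per-fold computation
— standardization, kernels, weight optimization — uses fold-training rows
only; `GridSearchResult.fold_kernel_hashes` fingerprints every fold-training
kernel so leakage from validation folds is detectable by construction (and
is tested by poisoning validation rows with a label-correlated feature).

## Deep kernel fusion

Each omic's uncentered Gaussian kernel is double-centered and
eigendecomposed; the top-d components give the kernel-PCA embedding
z_il = √λ_l · v_il.  Test points are projected by centering the test×train
cross-kernel with the stored training means and applying v_l/√λ_l.  Fewer
than d strictly positive eigenvalues raise an error.  Embedding scores keep
their √λ scale (no per-component rescaling) by default.

The multi-modal network runs one subnetwork of three fully connected
blocks per omic, each block ordered Linear → LeakyReLU(0.01) → Dropout →
BatchNorm.  Fusion is concatenation, sum, or weighted sum with M learnable
scalars initialized at one (so `sum` equals `weighted_sum` at
initialization, a tested identity).  The head is one further block plus a
plain linear output layer producing class logits; batch norm and dropout
are not applied after the output layer, which must deliver unnormalized
logits.  The cross-modal variant inserts, per ordered omic pair, one
dedicated cross-layer carrying the source omic's third-layer output into
the target omic's fourth block, whose input is the concatenation of its own
and all cross outputs — the minimal wiring that lets information flow
between modalities before fusion.

Training minimizes cross-entropy with Adam (β₁ = 0.9, β₂ = 0.999), batch
size 32, no early stopping — the epoch count is an ordinary tuned
hyperparameter (CV-fold variability makes early-stopping criteria
unreliable at these sample sizes).  No class weighting is applied; class
imbalance is surfaced through the weighted/macro F1 metrics instead.  All
randomness (He-style initialization, batch shuffling, dropout masks) flows
from the config seed; training twice with the same seed yields bit-identical
weights, and eval-mode forward passes use running batch-norm statistics, so
they are deterministic and batch-size independent.  A non-finite loss
aborts with a diagnostic rather than silently diverging.  Hyperparameters
(σ, number of components, epochs, dropout) are tuned by random-search
5-fold CV; when the budget covers the whole grid the search is exhaustive.

## Biomarker discovery

Step 1 — Integrated Gradients on the trained network, inputs being the
kernel principal components.  Baseline is the zero vector (the natural
origin of centered KPCA scores), target the logit of each sample's
predicted class, path integral a composite trapezoidal rule with `steps`
intervals (default 50).  A component's score is the mean absolute
attribution over samples; components are ranked per omic and the top k
(default 3) selected.  The quadrature error stems from LeakyReLU kinks
along the path and shrinks like 1/steps; the completeness identity
Σ_j IG_j = F(x) − F(0) holds to < 1 % mean relative error at 200 steps.

Step 2 — KPCA-IG.  For each selected component l the projection function is
f_l(x) = Σ_i a_i^l k̃(x, x_i) with a^l = v_l/√λ_l; differentiating the
centered expansion gives ∂f_l/∂x = Σ_i (a_i^l − ā^l) ∂k(x, x_i)/∂x with
the exact Gaussian derivative −2σ (x_j − x_ij) k(x, x_i).  Feature j's
score is the mean over training points of the norm across selected
components of ∂f_l/∂x_j.  With equal component weights this is the plain
Euclidean norm (the cited definition, and the default of
`kpca_ig_scores`); the two-step pipeline (`rank_features`) instead weights
each component's squared derivative by its normalized step-1 attribution.
The rationale: when fewer than k components carry class signal, the
equal-weight norm lets irrelevant components' derivatives swamp the
informative one — on the informative-vs-noise scenario equal weighting
drops planted-feature recovery to ~0.2 while attribution weighting reaches
1.0 — and quantifying per-component relevance is precisely what step 1
contributes.  The weighting is a recorded option, normalized so both modes
share the same overall scale.  σ must match the embedding kernel's σ, which
is enforced.

## Evaluation protocol and metrics

Five stratified splits with 30 % training fraction (seeds 0–4 by default;
"30/70" is read as 30 % train and is configurable), tuning confined to
each training partition, metrics on the held-out 70 %.  Binary: accuracy,
F1 (positive class = second class in the recorded class order), AUC —
which equals the Mann–Whitney pair-ordering statistic with ties counted ½,
and is invariant under strictly increasing score transforms.  Multiclass:
accuracy, support-weighted F1 and macro F1.  Weighted F1 uses weights
support_i / n that sum to one — the standard support-weighted average; a
printed variant of this formula that carries an extra 1/C factor would make
the weights sum to 1/C and contradict its own verbal definition, so it is
treated as a typographical artifact.  F1 with a zero denominator is defined
as 0.  A failing method in a benchmark run is recorded as an error cell;
the run continues.

## Feature preselection

For raw (unreduced) cohorts: features are ranked by one-way ANOVA F
(constant features get F = 0 and sort last; ties keep original order), then
the kept prefix is the smallest length k — scanned over a grid, default
{50, 100, …, p} — whose first principal component on standardized data
explains at least 50 % of the variance.  If no prefix reaches the
threshold, the grid argmax is returned with a warning.  Standardization
before the PC1 check avoids covariance-PCA degeneracy across mixed-scale
omics.  Inside cross-validation, preselection uses training data only.

## Synthetic data generator

`mokl.simulate` draws M blocks over one shared sample axis.  Labels follow
largest-remainder apportionment of the class proportions, then a seeded
shuffle.  Per block: `p_informative` features with class structure plus
`p_noise` pure-noise features ~ N(0, sd²).  Geometries: `linear_shift`
(informative means shifted by class_index · effect, in sd units) and
`radial` (class c near a shell of radius 1 + c · effect in the informative
subspace with 0.1·sd jitter — identical class means, so linearly
inseparable but Gaussian-kernel separable).  One root `SeedSequence` spawns
per-block child generators, so runs are bit-reproducible and adding blocks
does not perturb earlier ones.  Presets: A (one informative block at effect
2, two noise blocks, n = 200, balanced binary), B (all-radial, n = 400),
C (three classes at proportions 0.1/0.6/0.3, n = 300, graded block
informativeness), D (a small two-class cohort at roughly 1/10 scale with a
169:182 imbalance).  The generator targets the geometric and noise
structure these methods respond to; it does not mimic omics marginal
distributions (negative-binomial counts, beta-valued methylation), batch
effects, or feature correlation structure, so passing tests demonstrate
method correctness and recovery behaviour, not expected performance on
real cohorts.

## Numerical choices

* Kernel matrices are symmetrized (½(K + Kᵀ)) on construction; asymmetry
  beyond 1e-10 is an error.
* PSD checks use a relative tolerance of 1e-8 on the smallest eigenvalue.
* KPCA keeps eigenvalues above max(λ)·1e-12; requesting more components
  than there are positive eigenvalues raises.
* Weights are clipped at zero and renormalized on construction, so every
  strategy's output satisfies the simplex constraints exactly.
* Batch norm uses ε = 1e-5 and momentum 0.1; batches with fewer than two
  rows are skipped (batch statistics undefined).
* The libsvm stopping tolerance (1e-3) bounds reproducibility of SVM
  decision values; tests compare against it accordingly.

## Problem sizes

The test-suite and acceptance computations run on the synthetic scenarios:
n = 200–400 samples, 20–50 features per block, networks of width 32/32/16
with 8 kernel-PC components, 100 epochs.  These sizes exercise every code
path end to end in minutes on a single CPU; the same interfaces scale to
cohort-sized inputs (hundreds of samples, thousands of features) without
modification.

## Known limitations

* Supervised weight optimization (SimpleMKL/SEMKL) is binary-only, as
  specified; a multiclass extension would need a different inner solver.
* Only linear and Gaussian kernels are provided; polynomial, sigmoid or
  structured-data kernels are out of scope.
* The deep model's performance degrades at small n (deep architectures are
  data-hungry); at scenario sizes the SVM-family models are the stronger
  and much cheaper choice.
* Kernel-weight interpretability is at block level; feature-level
  attribution requires the two-step ranking, which presupposes a trained
  deep model and Gaussian kernels.
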