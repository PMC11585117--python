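# mokl — multiple kernel learning for multi-omics classification

`mokl` integrates several sample-aligned omics matrices (e.g. mRNA
expression, DNA methylation, miRNA counts for the same patients) into a
single predictive model through **multiple kernel learning (MKL)**, and
traces predictions back to candidate biomarkers.

Each omic block is represented by an n × n similarity (kernel) matrix
K^m — Gaussian RBF `k(x, y) = exp(−σ‖x−y‖²)` or linear — so heterogeneous
data types become commensurable.  The blocks are fused by a convex
combination (the *meta-kernel*)

```
K* = Σ_{m=1}^{M} β_m K^m ,   β_m ≥ 0,  Σ β_m = 1
```

with the simplex weights β chosen by one of four strategies:

| strategy | idea | supervision |
|---|---|---|
| `naive` | β_m = 1/M | none |
| `statis` | STATIS-UMKL consensus: β ∝ leading eigenvector of the M × M matrix of pairwise Frobenius cosines between kernels | none |
| `simplemkl` | SimpleMKL: minimize the SVM dual objective J(β) over the simplex by projected reduced-gradient descent with Armijo line search | binary labels |
| `semkl` | SEMKL: alternate SVM dual solves with the closed-form group-lasso update β_m ← ‖w_m‖ / Σ_h ‖w_h‖ | binary labels |

A C-SVM on the precomputed meta-kernel performs classification (one-vs-one
for multiclass); `concat`, a Gaussian kernel on the feature-wise
concatenation, serves as the early-integration baseline.

Alternatively, **deep kernel fusion**: each omic's kernel is embedded by
kernel PCA (top-d eigencomponents of the double-centered Gram matrix) and
the per-omic embeddings feed a multi-modal feedforward network — three
fully connected blocks (Linear → LeakyReLU → Dropout → BatchNorm) per omic,
fusion by concatenation / sum / learnable weighted sum, and a two-layer
classification head.  A cross-modal variant routes each omic's intermediate
representation into the other subnetworks through dedicated cross-layers
before fusion.

For **biomarker discovery** a two-step procedure first ranks each omic's
kernel principal components by Integrated-Gradients attribution of the
predicted-class logit (zero baseline, Riemann/trapezoid path integral),
then ranks original features by the KPCA-IG statistic — the mean norm of
the partial derivatives ∂f_l/∂x_j of the selected components' projection
functions, using the exact Gaussian-kernel derivative
∂k(x, x_i)/∂x_j = −2σ (x_j − x_ij) k(x, x_i).

A seeded synthetic-data generator (`mokl.simulate`) produces multi-block
fixtures with planted informative features, class imbalance and an optional
radial (linearly inseparable) geometry, so every pipeline stage is testable
without downloads.

## Worked example

```bash
python examples/01_kernel_fusion_svm.py
```

```
3 blocks, n=200, informative: ['block1_f0', 'block1_f1', 'block1_f2']...
     naive: beta=[0.333 0.333 0.333]  train_acc=1.000
    statis: beta=[0.325 0.334 0.34 ]  train_acc=1.000
 simplemkl: beta=[1. 0. 0.]  train_acc=1.000
     semkl: beta=[1. 0. 0.]  train_acc=1.000
```

Only the first simulated block carries class signal; the supervised
strategies discover this and assign it (essentially) all of the kernel
weight, while the unsupervised strategies spread weight by construction or
by inter-kernel similarity.  The other examples cover the multi-seed
benchmark protocol (`02`), deep kernel fusion on a radial geometry where a
linear baseline sits at chance (`03`), and biomarker recovery, where the
two-step ranking retrieves 10/10 planted features (`04`).

The command-line interface mirrors the library:

```bash
mokl simulate -s A -n 0 -o data/        # write a synthetic scenario
mokl benchmark -c cfg.yaml              # multi-seed 30/70 protocol
mokl explain -c cfg.yaml --top 15,10,10 # biomarker table
```

## Evaluation protocol

`mokl.evaluation.run_benchmark` reproduces the standard comparison
protocol: five stratified 30 % train / 70 % test splits (seeds 0–4), 5-fold
grid-search cross-validation on each training partition only (C ∈ [1, 25],
σ ∈ [5·10⁻⁵, 5·10⁻³]), refit, test-set metrics — accuracy, F1 and AUC for
binary tasks; accuracy, weighted F1 and macro F1 for multiclass — reported
as mean ± sd over the splits.

## Layout

```
src/mokl/      io, kernels, fusion, svm, deep, interpret, preprocess,
               evaluation, simulate, cli
examples/      one narrative script per capability
tests/         unit, property and acceptance tests (pytest)
docs/          methods note
```
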