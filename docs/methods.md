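# Methods

## Model

`scziva` models a cells × genes raw count matrix `X` (N cells, G genes)
with a variational autoencoder whose observation model is the
Zero-Inflated Negative Binomial (ZINB) distribution. For every entry the
decoder emits a triplet `(π_ij, μ_ij, θ_ij)`: a dropout (zero-inflation)
probability, an NB mean, and an NB inverse dispersion, so that

    P(X_ij = 0)        = π_ij + (1 − π_ij) · NB(0; μ_ij, θ_ij)
    P(X_ij = x), x > 0 = (1 − π_ij) · NB(x; μ_ij, θ_ij).

The encoder first permutes genes so that strongly co-expressed genes are
adjacent (leaf order of an average-linkage clustering of genes under the
distance `1 − |corr|`, computed on log2(1+x) columns), then applies a 1-D
convolution along the gene axis (kernel `k`, stride `s`, no padding,
filters shared across cells), a rectified-linear nonlinearity, a fully
connected hidden layer, and two linear heads producing the mean and
log-variance of a diagonal-Gaussian posterior over a latent vector `z`.
Sampling uses the reparameterization `z = μ_z + σ_z ⊙ ε`. The decoder is
a rectified-linear hidden layer followed by a linear layer of width `3G`,
split into the three parameter blocks and mapped through sigmoid
(π) and softplus (μ, θ).

Training minimizes, with Adam,

    L = L_ZINB + L_KL + λ · L_MSE + λ_reg (λ − 1)²

where `L_ZINB` is the negative ZINB log-likelihood summed over all
entries, `L_KL` the KL divergence of the posterior from `N(0, I)` summed
over cells, and `L_MSE = Σ_{(i,j): x_ij > 0} ((1 − π_ij) μ_ij − x_ij)²`
an auxiliary anchor that ties the ZINB mean to the observed counts on the
non-zero entries only. The weight `λ` is itself a trained scalar,
initialized at 1 and projected into [0.5, 1.5] after every optimizer
step; the quadratic penalty (coefficient `λ_reg`) keeps it near 1.

After training, imputation is selective and deterministic (latent code =
posterior mean): a zero entry is replaced by the ZINB mean
`(1 − π_ij) μ_ij` only if `π_ij > τ`; all non-zero entries and all zeros
with `π_ij ≤ τ` are passed through unchanged.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `kernel_size` | 64 | Conv1D window along the (reordered) gene axis; shrunk to G with a warning when G < 64 |
| `stride` | 1 | convolution step |
| `out_channels` | 1 | number of convolution filters (single filter, as in the printed transform) |
| `hidden_dim` | 128 | encoder/decoder hidden width |
| `latent_dim` | 64 | latent dimensionality |
| `epochs` | 200 | fixed training length (no early stopping) |
| `learning_rate` | 1e-3 | Adam step size, default betas |
| `batch_size` | full batch ≤ 2048 cells, else 256 | gradient granularity (the target datasets are small) |
| `lambda_init`, `lambda_bounds`, `lambda_reg` | 1.0, [0.5, 1.5], 1e-3 | adaptive MSE weight and its constraint |
| `tau` | 1e-3 | dropout-probability threshold for selective imputation |

## Numerical choices

* All likelihood math is done in log space via log-gamma. `π` is clamped
  to `[1e-8, 1 − 1e-8]`, `μ` and `θ` floored at `1e-8`; the zero branch
  is a log-sum-exp of `{log π, log(1−π) + θ(log θ − log(θ+μ))}`.
* Loss reductions are sums (not means) over cells and genes; the KL term
  is likewise summed over the batch.
* Gradients come from reverse-mode automatic differentiation over the
  numpy parameter arrays; a finite-difference check on a small fixture
  guards every parameter block (relative error < 1e-4 per block in
  float64).
* `λ` is constrained by projection (clipping after each Adam step) rather
  than a smooth reparameterization — the simplest mechanism that keeps it
  inside its interval; the MSE gradient flows through both `π` and `μ`.
* Gene reordering uses plain dendrogram leaf order (no optimal-leaf-order
  refinement) computed once on the training matrix and stored with the
  model; correlations are computed on log2(1+x) values because raw-count
  covariance is dominated by the few highest-expressed genes. Constant
  genes get distance 1 to all others; ties in the linkage are resolved
  deterministically by scipy.
* Determinism: every stochastic source (initialization, reparameterization
  draws, mini-batch shuffling, simulation) flows from generators derived
  from the configured seed; identical seed + data + config reproduce the
  loss history and the imputed matrix bit-for-bit.
* Degenerate inputs: all-zero gene columns are dropped before training and
  passed through imputation unchanged; cells with zero library size are
  left unscaled by the normalizer (with a warning); an all-zero matrix is
  rejected.

## Design choices where the design was open

* **Model input scale.** The network consumes raw, zero-filled counts;
  the ZINB likelihood is defined on counts. Feeding log-scaled inputs to
  the encoder is supported in principle but off by default; in our
  benchmarks it changed masked-entry accuracy only marginally.
* **Inference.** Imputation uses the posterior mean (`ε = 0`) rather than
  a stochastic draw: a production imputer should be deterministic, and
  repeated runs must agree.
* **Normalization recipe.** Where a log/normalized view is needed
  (metrics, clustering), we scale each cell's library to the median
  library size and apply log2(1 + x). The ZINB model itself never sees
  normalized data.
* **Metric scale.** RMSE/MAE/PCC compare the two matrices after an
  identical transform: per-cell scale factors computed from the
  ground-truth matrix are applied to both, then log2(1 + x). A raw-scale
  option exists. Masked-only scope (metrics restricted to entries where
  dropout was injected) is the primary benchmark surface; the ground
  truth certifies nothing about entries that were never masked.
* **Ablations.** `no_cnn` replaces the convolutional front end with a
  fully connected layer applied directly to the gene vector (reordering
  is still applied; it is harmless without convolution). `no_mse` removes
  the weighted MSE term from the total while still logging the component.

## Synthetic data: what it emulates, and what it does not

The generator draws per-gene base means from a log-normal (natural-log
mean 0, sd 1), assigns cells to groups, scales a `de_prob = 0.2` fraction
of genes by `de_factor = 3` (up or down) in one group, multiplies blocks
of 20 consecutive genes by a shared per-cell log-normal factor
(sd 0.6, mean 1) to plant co-expression structure, draws counts from a
Negative Binomial with inverse dispersion 2, and finally shuffles gene
columns so the on-disk order carries no information. Dropout is injected
by zeroing an exact, uniformly random fraction of the *non-zero* entries
and recording the mask, which makes the realized missing rate exact and
the ground truth unambiguous. An expression-independent uniform mask is a
deliberate simplification: real dropout is biased toward low-expression
genes, and Splatter-style simulators model library-size variation,
batch effects and expression-dependent dropout that this generator omits.
Passing benchmarks here therefore demonstrates correct mechanics and
relative method behaviour under controlled conditions, not performance on
real tissue data.

## Benchmark protocol and problem sizes

The standard synthetic suite used by the tests and by
`scripts/acceptance.py` is 500 cells × 300 genes with 3 groups, one
complete matrix with graded masking at rates 0.2–0.9, three training
seeds per rate at the headline rates {0.2, 0.5, 0.8}; ablation
comparisons run on a 300 × 200 instance at rates {0.6, 0.8} over five
seeds. Benchmark fits train for 60 epochs — at 300 genes the loss curve
is essentially flat well before that, and this keeps the full suite
cheap to re-run; the 200-epoch default remains the recommendation for
real data.

## Known limitations

* Selective imputation replaces a zero by the *unconditional* ZINB mean
  `(1 − π) μ`. Under a benchmark that masks only non-zero entries, the
  truth at a masked position is distributed as an NB value conditioned on
  being positive, whose mean `μ / (1 − NB(0; μ, θ))` exceeds `μ`; the
  imputed value is therefore biased low by roughly the factor
  `(1 − π)(1 − NB(0))`. The acceptance benchmark quantifies this with an
  oracle that imputes the true generative means: under these conditions
  that oracle only ties per-gene non-zero-mean filling on masked-entry
  MAE (within 0.001 of it at every rate), so any mean-based imputer with
  additional shrinkage necessarily scores below that baseline there.
  Whole-matrix (all-entries) metrics, where selectivity pays off because
  biological zeros are left untouched, favour the model far more
  strongly.
* With only a few hundred genes, the network (hidden 128, latent 64) has
  enough capacity to partially memorize which input entries are zero and
  to lower its reconstruction exactly there; this weakens masked-entry
  accuracy most at *low* masking rates, where more of the matrix is
  available to memorize. The effect shrinks as the gene dimension grows
  toward realistic sizes (thousands of genes per 64-dim latent).
* No batch-effect covariates, size-factor offsets in `μ`, or
  per-gene-shared dispersion; one stochastic latent draw per step.
* Training is CPU-bound dense linear algebra; very large matrices
  (tens of thousands of cells) are outside the intended envelope.
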