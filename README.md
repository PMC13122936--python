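# scziva

Selective imputation of dropout zeros in single-cell RNA-seq count
matrices with a zero-inflated negative binomial (ZINB) variational
autoencoder, plus the simulation-and-masking harness needed to benchmark
it against known ground truth.

scRNA-seq matrices are riddled with *technical* zeros (transcripts present
in the cell but missed by capture/amplification) mixed with *biological*
zeros (genes genuinely silent). Blanket smoothing recovers the former at
the cost of erasing the latter. `scziva` instead:

1. reorders genes so co-expressed genes are adjacent (average-linkage
   clustering of genes under the distance `1 − |corr|`), giving a 1-D
   convolutional encoder meaningful local receptive fields;
2. trains a VAE whose decoder emits per-entry ZINB parameters
   `(π_ij, μ_ij, θ_ij)` — dropout probability, mean, inverse dispersion —
   with the loss `L_ZINB + L_KL + λ·L_MSE + λ_reg(λ−1)²`, where the MSE
   term anchors the ZINB mean `(1−π)μ` to the observed counts on non-zero
   entries and its weight `λ` is learned inside [0.5, 1.5];
3. imputes **selectively**: a zero entry is replaced by `(1−π_ij)μ_ij`
   only when `π_ij > τ` (default `τ = 1e-3`); non-zero entries and
   low-dropout-probability zeros are never touched.

The package is a library first (`import scziva`), with narrative scripts
under `examples/` and a thin `scziva` command-line front end
(`simulate` / `train` / `impute` / `evaluate`).

## Worked example

```python
from scziva import (SimConfig, TrainConfig, simulate_counts, apply_dropout,
                    fit, impute, compute_metrics)

complete, labels = simulate_counts(SimConfig(n_cells=200, n_genes=150,
                                             n_groups=3, seed=1))
observed, mask = apply_dropout(complete, rate=0.5, seed=1)

model = fit(observed, TrainConfig(kernel_size=32, epochs=60, seed=1))
result = impute(model, observed)                      # tau = 1e-3
report = compute_metrics(complete, result, scope="masked_only", mask=mask)
print(result.n_imputed, round(report.mae, 4), round(report.pcc, 4))
```

prints

```
19869 0.7873 0.3133
```

meaning: 19,869 of the 22,571 observed zeros were judged likely technical
dropouts and filled in; at the 7,428 entries where dropout was injected,
the imputed values sit on average 0.79 log2-units from the true
pre-dropout counts, with Pearson correlation 0.31 to them. Leaving the
zeros in place scores MAE 1.66 at the same entries (`examples/03` prints
the side-by-side comparison, including a per-gene-mean baseline).

The same workflow from the shell:

```bash
scziva simulate --cells 200 --genes 150 --groups 3 --rates 0.5 --seed 1 --out-dir sim/
scziva train   --input sim/observed_50.mtx --epochs 60 --kernel 32 --seed 1 --out model.zip
scziva impute  --model model.zip --input sim/observed_50.mtx --out imputed.mtx
scziva evaluate --truth sim/complete.mtx --imputed imputed.mtx \
                --mask sim/mask_50.tsv --scope masked_only
```

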