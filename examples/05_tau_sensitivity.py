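"""Sweep the dropout-probability threshold tau.

tau controls how aggressively zeros are imputed: tau = 0 fills every zero
the model assigns any dropout probability, large tau preserves almost all
zeros. The imputed-entry count is non-increasing in tau; masked-entry
metrics show the accuracy trade-off.
"""

from scziva import SimConfig, TrainConfig, apply_dropout, fit, simulate_counts, tau_sweep

complete, labels = simulate_counts(SimConfig(n_cells=200, n_genes=150, n_groups=3, seed=1))
observed, mask = apply_dropout(complete, rate=0.5, seed=1)
model = fit(observed, TrainConfig(kernel_size=32, epochs=60, seed=1))

taus = [0.0, 1e-4, 1e-3, 1e-2, 0.1, 0.3, 0.5, 0.9]
df = tau_sweep(model, observed, taus, mask=mask, complete=complete)
print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nimputed-entry count shrinks as tau rises; the default tau=1e-3 "
      "imputes nearly every zero while leaving confidently biological zeros alone")
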