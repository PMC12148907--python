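"""Train the tabular VAE on a cohort and sample a synthetic pool.

The synthesizer trains jointly on the 14 model inputs and the 6 binary
group labels (so the synthetic rows carry their own labels), then samples
200 rows under the training-envelope constraints.
"""

from attenurank import CohortConfig, TVAEConfig, TVAESynthesizer, compute_labels, generate_cohort
from attenurank.pipeline import build_synthesis_table

cohort = generate_cohort(CohortConfig(n_athletes=41, seed=1))
labels, _ = compute_labels(cohort)
train = build_synthesis_table(cohort, labels)
print(f"training table: {train.shape[0]} rows x {train.shape[1]} columns "
      "(14 inputs + 6 group labels)")

synthesizer = TVAESynthesizer(TVAEConfig(seed=7))  # 128-dim latent, 500 epochs
synthesizer.fit(train, categorical_columns=[c for c in train.columns if c.startswith("group_")])
print(f"ELBO loss (to minimize): {synthesizer.loss_trace[0]:.2f} (epoch 1) -> "
      f"{synthesizer.loss_trace[-1]:.2f} (epoch {len(synthesizer.loss_trace)})")

synthetic = synthesizer.sample(200)
print(f"\nsampled {len(synthetic)} synthetic athletes")
inside = all(
    synthetic[c].min() >= train[c].min() and synthetic[c].max() <= train[c].max()
    for c in train.columns if not c.startswith("group_")
)
print("all continuous values inside the training envelope:", inside)
print("group_cmj balance  train: %.3f  synthetic: %.3f"
      % (train["group_cmj"].mean(), synthetic["group_cmj"].mean()))
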