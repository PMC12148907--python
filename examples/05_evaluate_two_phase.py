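"""Two-phase evaluation of synthetic-data utility.

Benchmarks the best real-data-only classifier per target, then runs a
hybrid-augmentation sweep (Phase 1) and a train-synthetic-test-real sweep
(Phase 2), reporting relative effect sizes against the benchmark.

Uses strong-signal study conditions and reduced grids/sweeps so the script
finishes in about a minute; pass full GridSpec() and the default
PhaseConfig sweeps for the complete experiment.
"""

from attenurank import (
    CohortConfig, GridSpec, PhaseConfig, TVAEConfig, TVAESynthesizer,
    benchmark_real, compute_labels, generate_cohort, phase1_hybrid,
    phase2_pure_synthetic, select_optima,
)
from attenurank.cohort import INPUT_COLUMNS
from attenurank.pipeline import build_synthesis_table
from attenurank.ranking import labels_wide

conditions = dict(correlation_strength=0.9, attenuation_effect=2.0, noise_sd=0.3)
cohort = generate_cohort(CohortConfig(n_athletes=41, seed=1, **conditions))
labels, _ = compute_labels(cohort)
features = cohort[list(INPUT_COLUMNS)].reset_index(drop=True)
targets = labels_wide(labels).drop(columns=["athlete_id"])
targets.columns = [c.removeprefix("group_") for c in targets.columns]

train = build_synthesis_table(cohort, labels)
synthesizer = TVAESynthesizer(TVAEConfig(seed=7)).fit(
    train, categorical_columns=[c for c in train.columns if c.startswith("group_")]
)
synthetic = synthesizer.sample(200)
synth_features = synthetic[list(INPUT_COLUMNS)]
synth_targets = synthetic[[c for c in synthetic.columns if c.startswith("group_")]].copy()
synth_targets.columns = [c.removeprefix("group_") for c in synth_targets.columns]

grids = GridSpec(grids={
    "random_forest": {"n_estimators": [50, 100], "max_depth": [None, 10]},
    "adaboost": {"n_estimators": [50, 100], "learning_rate": [0.1, 1.0]},
})
eval_targets = ["cmj", "ck"]

bench = benchmark_real(features, targets, grids,
                       PhaseConfig(phase="benchmark", seed=3), targets=eval_targets)
print("real-data benchmark (best model per target):")
for t, r in bench.items():
    print(f"  {t:<4} {r.model:<14} acc {r.accuracy:.2f}  f1 {r.f1:.2f}  {r.best_params}")

p1 = phase1_hybrid(features, targets, synth_features, synth_targets, grids,
                   PhaseConfig(phase="hybrid", seed=3, proportions=(20, 50, 100)),
                   benchmark=bench, targets=eval_targets)
print("\nPhase 1 optima (real training split + synthetic rows):")
for t, r in select_optima(p1).items():
    print(f"  {t:<4} {r.model:<14} +{r.synthetic_proportion}% synthetic  "
          f"acc {r.accuracy:.2f}  effect {r.effect_size_pct:+.1f}% vs benchmark")

p2 = phase2_pure_synthetic(features, targets, synth_features, synth_targets, grids,
                           PhaseConfig(phase="pure_synthetic", seed=3, proportions=(40, 100)),
                           benchmark=bench, targets=eval_targets)
print("\nPhase 2 optima (trained on synthetic only, tested on all real rows):")
for t, r in select_optima(p2).items():
    print(f"  {t:<4} {r.model:<14} {r.synthetic_proportion}% of pool  "
          f"acc {r.accuracy:.2f}  effect {r.effect_size_pct:+.1f}% vs benchmark")
print("\nEffect size = 100 * (accuracy - benchmark accuracy) / benchmark accuracy.")
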