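"""Deconvolve in-silico DNA mixtures with reference-based NNLS.

Simulates pure profiles for 5 cell types, builds the marker-CpG
reference matrix of per-type mean beta values, mixes the reference
profiles with known Dirichlet proportions plus measurement noise
(SD 0.02), and recovers the fractions by non-negative least squares
with post-hoc normalisation. Also runs a two-type incremental
gradient, the classic titration design for validating deconvolution.
"""

from cpgdeconv import (
    SimulationConfig,
    build_reference,
    deconvolve,
    evaluate_mixtures,
    gradient_proportions,
    simulate_mixtures,
    simulate_pure_profiles,
)

cfg = SimulationConfig(seed=7)
matrix, annotation, truth = simulate_pure_profiles(cfg)
types = sorted(annotation["cell_type"].unique())
markers = [c for t in types for c in truth.markers_of(t)]
reference = build_reference(matrix, annotation, markers, types)
print(f"reference: {len(reference.marker_cpgs)} marker CpGs x "
      f"{len(reference.cell_types)} cell types "
      f"(condition number {reference.condition_number:.1f})")

mixtures, mix_truth = simulate_mixtures(reference.data, n_mixtures=50, cfg=cfg)
estimate = deconvolve(mixtures, reference)
metrics = evaluate_mixtures(mix_truth.proportions, estimate)
print(f"\n50 random mixtures, measurement SD {cfg.measurement_sd}:")
print("  per-type MAE:", metrics["mae_per_cell_type"].round(4).to_dict())
print(f"  RMSE {metrics['rmse']:.4f}, Pearson r {metrics['pearson_r']:.4f}")

grad = gradient_proportions(types, varied="type01", other="type02")
grad_mix, grad_truth = simulate_mixtures(reference.data, cfg=cfg, proportions=grad)
grad_est = deconvolve(grad_mix, reference)
print("\ntwo-type gradient (true vs estimated type01 fraction):")
for s in grad.index:
    print(f"  {grad_truth.proportions.loc[s, 'type01']:.2f}  ->  "
          f"{grad_est.proportions.loc[s, 'type01']:.3f}")
print("\nEstimates track the mixed fractions; residual noise reflects the "
      "simulated measurement error on the marker beta values.")
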