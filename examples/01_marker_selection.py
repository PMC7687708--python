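"""Select cell-type-specific marker CpGs on a synthetic benchmark.

Generates beta profiles for 5 cell types (10 samples each) with 10
planted hypomethylated marker CpGs per type among 500 background CpGs,
then ranks candidates for one target type by stratified 5-fold
cross-validation: per-fold dMean/sVar screening under the adaptive
parabola gate, AUPR scoring on held-out folds scaled by |dMean|, and
fold-frequency weighting.
"""

from cpgdeconv import (
    SimulationConfig,
    rank_markers,
    simulate_selection_benchmark,
    stratified_folds,
)

cfg = SimulationConfig(seed=42)
matrix, annotation, truth = simulate_selection_benchmark(cfg)
print(f"matrix: {matrix.shape[0]} CpGs x {matrix.shape[1]} samples")

target = "type01"
labels = annotation.set_index("sample_id")["cell_type"]
plan = stratified_folds(labels, k=5, seed=42)
ranking = rank_markers(matrix, annotation, target, plan)

top = ranking.top("hypo", 5)
print(f"\ntop 5 hypomethylated candidates for {target}:")
print(top[["final_score", "selection_frequency", "mean_metric", "mean_dmean"]]
      .round(3).to_string())

planted = set(truth.markers_of(target))
n_recovered = sum(c in planted for c in top.index)
print(f"\n{n_recovered}/5 of the top candidates are planted markers.")
print("final_score = mean(AUPR x |dMean| over selected folds) x selection "
      "frequency; a perfect, always-selected marker scores ~|dMean| (~0.75 "
      "here, the planted beta gap between 0.85 and 0.10).")
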