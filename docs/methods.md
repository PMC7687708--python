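# Methods

## Data model

A `BetaMatrix` is a CpG × sample table of methylation beta values
(methylated fraction, unitless, in [0, 1]) backed by a pandas DataFrame.
Input files are delimited text with one key column and one header row;
the delimiter follows the file extension (`.csv` → comma, otherwise
tab). Pyrosequencing percentages are divided by 100; under `scale=auto`
rescaling triggers when any finite value exceeds 1.5 rather than 1.0, so
minor >1 artifacts in genuine beta matrices (e.g. from normalisation
overshoot) do not silently rescale the whole matrix, while real percent
data (which always contains values far above 1.5 in practice) is caught.
Values within 1e-9 of the [0, 1] boundary are snapped onto it; anything
further out is an error, never clipped. Missing tokens are the empty
string and case-insensitive `NA`/`NaN` (configurable). Writing uses
`%.17g`, which round-trips doubles exactly.

Probe filtering is deliberately list-driven: platform manifests are not
parsed. Restricting to the probes shared between array platforms and
excluding sex-chromosome probes are both expressed as user-supplied
keep/drop lists (`ProbeFilterSpec`), which preserves the filter
semantics without a manifest dependency; `drop_missing` removes any CpG
with at least one missing value, the usual "probes shared across all
samples" rule. Keep is applied before drop; the filter is idempotent.

## Marker selection

For target type *C_i* vs the pooled rest *C_other*, each CpG gets, per
cross-validation fold,

- `dMean = mean(beta | target) − mean(beta | other)` ∈ [−1, 1],
- `sVar = var(beta | target) + var(beta | other)` ≥ 0,

with unbiased (n−1) variances — the conventional estimator; this is the
reason every fold needs at least two samples per group. Folds are
stratified by cell type (per-class fold sizes differ by at most one;
classes smaller than k are spread over distinct folds) and fully
determined by a single integer seed — the only random element in
selection.

The screen is the adaptive parabola `sVar < (a · dMean)²`, starting at
a = 0.1 and stepping by 0.1 until at least 10 hypermethylated and 10
hypomethylated CpGs pass. A cap at a = 10.0 prevents infinite escalation
on pathological inputs (everything passing at the cap is returned with a
warning). The per-fold protocol follows the literal reading of
"for a given fold": statistics and gate on the samples *of* that fold,
metric evaluation on the samples of the remaining k−1 folds. Scores are
oriented so that higher always means more target-like: hypomethylated
candidates are scored with 1 − beta (equivalent to −beta by monotone
invariance of rank metrics).

AUPR is computed as average precision — at each distinct threshold,
precision times recall increment, tied scores sharing one threshold —
and best-F1 maximises F1 over thresholds of the rule `score ≥ t`. Both
are implemented in-package because the scaled metric is part of the
ranking contribution; scikit-learn's `average_precision_score` serves
only as an independent cross-check in the test suite.

The final score is `mean(metric × |dMean|, over the folds where the CpG
passed the gate) × (fraction of folds where it passed)`. Averaging only
over selected folds is the natural choice — the metric is never computed
in folds where a CpG failed the gate — and rarity is already penalised
by the frequency factor. With metric ≤ 1, |dMean| ≤ 1 and frequency ≤ 1
the score lies in [0, 1]; a CpG never selected scores exactly 0. Ties
are broken by larger |mean dMean|, then lexicographic CpG id, making
rankings bit-reproducible. Hyper- and hypomethylated candidates are
ranked separately.

## FibroScore

`score = beta(cg18096962) − beta(cg18005280)`, range [−1, 1]. Samples
lacking either CpG are flagged missing, never silently dropped; if
neither CpG is in the matrix the call errors. The classification
threshold defaults to 0 — the natural symmetric cutoff for a difference
score — with `best_threshold` available to derive an
accuracy-maximising cutoff from a labelled training set; boundary ties
classify as fibroblast. Group comparison uses Welch's t-test (unequal
variances), two-sided; when both groups are degenerate (zero variance)
the limit is returned directly (p = 0 for different means, 1 for equal).

## Deconvolution

`build_reference` takes the arithmetic mean beta of each marker CpG over
the training samples of each cell type. The condition number and a
full-column-rank flag are computed on construction and an
ill-conditioning warning is logged above 1e6, because near-collinear
cell types destabilise the fit.

Per sample, NNLS (`scipy.optimize.nnls`, Lawson–Hanson active set)
minimises ‖Rw − b‖₂ subject to w ≥ 0. Sum-to-one is enforced by
post-hoc normalisation w/Σw rather than a constrained solver — the
standard practice for this kind of minimal-signature estimator — and the
raw weights are reported alongside for transparency. An all-zero
solution is flagged `degenerate` with NaN proportions rather than being
coerced to uniform: fabricating proportions silently would be worse
than an explicit QC failure.

Missing markers: under the default `exclude` policy a sample missing any
marker CpG is skipped with the reason recorded — the conservative
behaviour for a fixed signature. `drop_rows` instead drops the missing
rows from both R and b (with a warning), refusing when fewer rows than
cell types would remain, for exploratory use.

`evaluate_mixtures` reports per-cell-type MAE, overall RMSE and the
Pearson correlation of mixed vs estimated fractions pooled over all
entries (NaN when either pooled vector is constant).

## Synthetic data

The generator emulates the geometry targeted methylation signatures
rely on: each cell type hypomethylated at its own markers (mean beta
0.10) and hypermethylated at other types' markers (0.85), background
CpGs sharing one per-CpG mean (uniform in [0.2, 0.8]) across all types
so their expected dMean is 0 and planted markers are the only true
signal. Pure-profile noise is a Beta distribution reparameterised by
(mean, SD) — support stays in [0, 1] by construction; the
parameterisation requires SD² < mean·(1 − mean) and errors otherwise.
Mixtures are convex combinations of mean profiles plus Gaussian
measurement noise truncated to [0, 1] by clipping (bias negligible at
the default SD); mixing weights come from a symmetric Dirichlet or are
supplied explicitly, e.g. the two-type incremental gradient used for
titration-style validation.

Defaults: 5 cell types × 10 samples, 10 markers/type, 500 background
CpGs, within-type SD 0.05 (typical biological spread of pure sorted
populations on arrays), measurement SD 0.02 (targeted-assay technical
precision), Dirichlet α = 1 (uniform over the simplex). What the
generator does *not* emulate: probe-level artifacts (cross-reactive or
polymorphic probes), batch effects between studies, correlated noise
across neighbouring CpGs, and intermediate methylation states of
partially differentiated cells — so passing tests demonstrate
correctness of the algorithms under the assumed signal geometry, not
robustness to every failure mode of real array data.

## Benchmark sizes and numerical choices

The planted-marker benchmark runs 20 seeds × 5 targets at the default
matrix size with k = 5 folds. Five folds (not the k = 10 used for large
training cohorts) is the appropriate choice at 10 samples per type:
per-fold statistics need at least two target samples for a variance,
which k = 10 cannot provide at this cohort size. The NNLS grid oracle
uses a 0.01-step simplex grid with closed-form non-negative scaling
along each grid direction, so the grid covers all total weights rather
than only sum-to-one solutions. KKT conditions of the NNLS solution are
checked to 1e-8 in tests; noiseless convex combinations of
full-column-rank references are recovered to 1e-8; seeded runs are
byte-reproducible end to end.

## Known limitations

- The selection protocol evaluates candidates chosen on a *single* fold
  against the rest; the alternative (select on k−1, evaluate on 1) would
  give lower-variance per-fold statistics but is not what the per-fold
  screening design specifies.
- The default eight-CpG signature ships as CpG *identifiers*; reference
  mean values must be computed from the user's training data (or the
  simulator), since trained means are data-dependent.
- NNLS proportions are compositional estimates, not absolute cell
  counts; ill-conditioned references (collinear cell types) inflate the
  variance of individual components even when the fit residual is small.
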