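# cpgdeconv

Targeted DNA-methylation analysis of cell-type composition: selection of
individual cell-type-specific CpG markers from labelled beta-value
matrices, the two-CpG **FibroScore** for fibroblast/MSC content, and
reference-based **NNLS deconvolution** of cell mixtures from a minimal CpG
signature — plus a synthetic-data generator with planted ground truth so
every stage can be exercised offline.

## Who this is for

DNA methylation at a CpG site is reported as a beta value — the methylated
fraction, between 0 and 1 — and is highly cell-type specific, which makes
it well suited to estimating the cellular composition of bulk tissue.
Classical methylation deconvolution uses signatures of thousands of CpGs
from genome-wide BeadChip arrays. This package implements the opposite
regime: *individual* marker CpGs that can be measured by targeted assays
such as bisulfite pyrosequencing, enabling cheap, fast composition
estimates (fibrosis staging, tumour stroma content, mixture QC) from a
handful of loci. It works equally on BeadChip exports (fractions) and
pyrosequencing tables (percentages).

## The methods

**Marker selection.** For a target cell type *C<sub>i</sub>* against all
others *C<sub>other</sub>*, every CpG gets two statistics per stratified
k-fold CV fold: *dMean* (difference of group means, target minus rest) and
*sVar* (sum of within-group variances). CpGs passing the adaptive parabola
gate *sVar < (a · dMean)²* — with *a* starting at 0.1 and growing by 0.1
until at least 10 hypermethylated (dMean > 0) and 10 hypomethylated
(dMean < 0) CpGs pass — are scored as single-feature classifiers on the
held-out folds by the area under the precision-recall curve (AUPR; best F1
as an alternative), scaled by |dMean|. The final score is the mean scaled
metric over the folds where the CpG was selected, multiplied by the
selection frequency, so good markers are those selected in many folds with
high AUPR and large |dMean|. Hyper- and hypomethylated candidates are
ranked separately.

**FibroScore.** `score = beta(cg18096962) − beta(cg18005280)` — one CpG
hypermethylated and one hypomethylated in fibroblasts/MSCs. Samples with
score ≥ 0 classify as fibroblast-like; Welch's t-test compares score
distributions between groups (e.g. fibrotic vs healthy tissue).

**Deconvolution.** A reference matrix *R* (marker CpGs × cell types) of
mean training beta values is fitted to each sample's beta vector *b* by
non-negative least squares, min<sub>w≥0</sub> ‖Rw − b‖₂ (Lawson–Hanson),
and the weights normalised to proportions w/Σw. The default eight-CpG
signature uses one hypomethylated marker per cell type: cg23068797
(fibroblasts), cg10673833 (leukocytes), cg06631999 (epithelial cells),
cg27197524 (hepatocytes), cg06421238 (endothelial cells), cg27309098
(glia), cg09998451 (neurons), cg21548464 (iPSCs). Samples missing a marker
CpG are excluded (flagged, with the reason) rather than silently fitted.

## Worked example

`examples/03_deconvolution.py` simulates pure profiles for five cell
types, builds the marker reference, mixes the reference profiles with
known proportions plus measurement noise (SD 0.02) and deconvolves:

```
reference: 50 marker CpGs x 5 cell types (condition number 4.7)

50 random mixtures, measurement SD 0.02:
  per-type MAE: {'type01': 0.0048, 'type02': 0.0063, 'type03': 0.0071, 'type04': 0.0062, 'type05': 0.0062}
  RMSE 0.0076, Pearson r 0.9990

two-type gradient (true vs estimated type01 fraction):
  0.00  ->  0.000
  0.10  ->  0.091
  ...
  1.00  ->  1.000
```

The estimated fractions deviate from the mixed ones by well under one
percentage point on average, and the two-type titration is recovered
linearly — the behaviour a practitioner should expect from a
well-conditioned reference at targeted-assay noise levels. The other
examples cover marker selection (`01_marker_selection.py`, where the top
five ranked CpGs are all planted markers) and the FibroScore
(`02_fibroscore.py`, 100% threshold-0 accuracy and t ≈ 139 between
groups).

## Command line

```bash
cpgdeconv simulate --seed 1 --out-dir sim/           # synthetic dataset + truth
cpgdeconv select --matrix sim/matrix.tsv --annotation sim/annotation.tsv \
    --target type01 --k 5 --seed 1 --out ranking.tsv
cpgdeconv fibroscore --matrix betas.tsv --out scores.tsv
cpgdeconv deconvolve --matrix mixtures.tsv --reference ref.tsv --out proportions.tsv
```

All commands accept `--log-level`, read TSV/CSV by extension, and are
deterministic given their seed and config.

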