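"""Cross-validated selection of cell-type-specific marker CpGs.

A marker CpG for a cell type is one whose beta value separates that
type (the target group) from all other types. Candidates are screened
per cross-validation fold with two statistics — dMean, the difference
of group means (target minus rest), and sVar, the sum of within-group
variances — and a CpG passes the screen when it falls below an
adaptive parabola, sVar < (a * dMean)^2. Surviving candidates are
scored as single-feature classifiers on the held-out samples (area
under the precision-recall curve, or best F1), scaled by |dMean|, and
aggregated over folds into a final ranking that favours CpGs selected
in many folds with high scores.

Hypermethylated (dMean > 0) and hypomethylated (dMean < 0) candidates
are ranked separately; hypomethylated markers are the usual geometry
for differentiated cell types.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import BetaMatrix

logger = logging.getLogger(__name__)


@dataclass
class ParabolaGate:
    """Adaptive parabola screen in the (dMean, sVar) plane.

    A CpG passes when sVar < (a * dMean)^2. Starting at ``a_init``,
    ``a`` grows by ``a_step`` until at least ``min_hyper``
    hypermethylated and ``min_hypo`` hypomethylated CpGs pass, or
    ``a_max`` is reached (then everything passing at ``a_max`` is
    returned with a warning).
    """

    a_init: float = 0.1
    a_step: float = 0.1
    min_hyper: int = 10
    min_hypo: int = 10
    a_max: float = 10.0


@dataclass
class FoldPlan:
    """Stratified assignment of samples to cross-validation folds."""

    k: int
    seed: int
    assignment: dict[str, int]

    def fold_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


@dataclass
class MarkerRanking:
    """Per-CpG selection statistics and the final ranking.

    ``table`` has one row per CpG: direction, selection_frequency,
    mean_metric, mean_scaled_metric, mean_dmean, final_score and rank
    (ranks are assigned within each direction; unselected CpGs rank
    after all selected ones). The ``per_fold_*`` frames hold the
    fold-level detail (NaN where a CpG was not selected in a fold).
    """

    table: pd.DataFrame
    per_fold_selected: pd.DataFrame
    per_fold_metric: pd.DataFrame
    per_fold_dmean: pd.DataFrame
    metric: str = "aupr"

    def top(self, direction: str, n: int = 10) -> pd.DataFrame:
        sub = self.table[self.table["direction"] == direction]
        return sub.sort_values("rank").head(n)


def stratified_folds(
    labels: Mapping[str, str] | pd.Series, k: int, seed: int
) -> FoldPlan:
    """Assign samples to k folds, stratified by cell-type label.

    Within every label class the fold sizes differ by at most one;
    classes with fewer than k samples are spread over distinct folds.
    Deterministic for a given seed.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in sorted(set(labels.values())):
        members = sorted(s for s, lab in labels.items() if lab == cls)
        order = rng.permutation(len(members))
        offset = int(rng.integers(k))
        for i, j in enumerate(order):
            assignment[members[j]] = (offset + i) % k
    return FoldPlan(k=k, seed=seed, assignment=assignment)


def cpg_stats(
    m: BetaMatrix,
    ann: pd.DataFrame,
    target: str,
    sample_subset: set[str] | None = None,
) -> pd.DataFrame:
    """Per-CpG dMean and sVar for target vs all-other-types groups.

    dMean = mean(beta | target) - mean(beta | other);
    sVar = var(beta | target) + var(beta | other), with unbiased
    (n-1) variances, computed on ``sample_subset`` when given.
    Returns a frame indexed by CpG id with columns dMean, sVar,
    direction ('hyper' if dMean > 0 else 'hypo').
    """
    lab = ann.set_index("sample_id")["cell_type"]
    samples = [s for s in m.sample_ids if s in lab.index]
    if sample_subset is not None:
        samples = [s for s in samples if s in sample_subset]
    is_target = np.array([lab[s] == target for s in samples])
    n_t, n_o = int(is_target.sum()), int((~is_target).sum())
    if n_t < 2 or n_o < 2:
        raise ValueError(
            f"need >= 2 samples per group for variance; got {n_t} target, {n_o} other"
        )
    vals = m.data[samples].to_numpy(dtype=float)
    tv, ov = vals[:, is_target], vals[:, ~is_target]
    dmean = tv.mean(axis=1) - ov.mean(axis=1)
    svar = tv.var(axis=1, ddof=1) + ov.var(axis=1, ddof=1)
    return pd.DataFrame(
        {
            "dMean": dmean,
            "sVar": svar,
            "direction": np.where(dmean > 0, "hyper", "hypo"),
        },
        index=pd.Index(m.cpg_ids, name="cpg_id"),
    )


def parabola_select(
    stats: pd.DataFrame, gate: ParabolaGate = ParabolaGate()
) -> tuple[list[str], list[str], float]:
    """Select CpGs under the adaptive parabola gate.

    Returns (hyper ids, hypo ids, a_final). CpGs with dMean exactly 0
    belong to neither side.
    """
    if len(stats) == 0:
        raise ValueError("empty statistics table")
    dmean = stats["dMean"].to_numpy(dtype=float)
    svar = stats["sVar"].to_numpy(dtype=float)
    n_steps = 0
    while True:
        a = gate.a_init + n_steps * gate.a_step
        passing = svar < (a * dmean) ** 2
        n_hyper = int((passing & (dmean > 0)).sum())
        n_hypo = int((passing & (dmean < 0)).sum())
        if (n_hyper >= gate.min_hyper and n_hypo >= gate.min_hypo) or a >= gate.a_max:
            break
        n_steps += 1
    if n_hyper < gate.min_hyper or n_hypo < gate.min_hypo:
        warnings.warn(
            f"parabola gate hit a_max={gate.a_max} with only {n_hyper} hyper- and "
            f"{n_hypo} hypomethylated CpGs selected",
            stacklevel=2,
        )
    idx = stats.index.to_numpy()
    hyper = list(idx[passing & (dmean > 0)])
    hypo = list(idx[passing & (dmean < 0)])
    return hyper, hypo, a


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (average precision).

    ``scores`` are real-valued with higher meaning more target-like;
    ``labels`` are binary target membership. Tied scores share one
    threshold. Computed as the sum over distinct thresholds of
    precision times the recall increment.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present to compute AUPR")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # threshold boundaries: positions where the next score is strictly smaller
    boundary = np.flatnonzero(np.diff(s) != 0)
    cut = np.append(boundary, s.size - 1)
    tp = np.cumsum(y)[cut]
    pred_pos = cut + 1
    precision = tp / pred_pos
    recall = tp / n_pos
    d_recall = np.diff(np.concatenate(([0.0], recall)))
    return float(np.sum(precision * d_recall))


def f1_best(scores, labels) -> float:
    """Best F1 over all thresholds of the rule score >= t -> target."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present to compute F1")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    boundary = np.flatnonzero(np.diff(s) != 0)
    cut = np.append(boundary, s.size - 1)
    tp = np.cumsum(y)[cut]
    pred_pos = cut + 1
    # F1 = 2 TP / (predicted positives + actual positives); no division by zero
    f1 = 2.0 * tp / (pred_pos + n_pos)
    return float(f1.max())


_METRICS = {"aupr": aupr, "f1": f1_best}


def rank_markers(
    m: BetaMatrix,
    ann: pd.DataFrame,
    target: str,
    plan: FoldPlan,
    gate: ParabolaGate = ParabolaGate(),
    metric: str = "aupr",
    scale_by_dmean: bool = True,
) -> MarkerRanking:
    """Rank candidate marker CpGs for ``target`` by cross-validated score.

    For each fold: dMean/sVar are computed on that fold's samples and
    the parabola gate applied; every selected CpG is then scored as a
    one-feature classifier on the samples of the remaining folds
    (hypomethylated candidates use 1 - beta so that higher scores are
    always more target-like), optionally scaled by the fold's |dMean|.
    The final score is the mean scaled metric over the folds where the
    CpG was selected, multiplied by the fraction of folds selecting it,
    so a CpG never selected scores 0. Ties are broken by larger
    |mean dMean|, then CpG id.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}, got {metric!r}")
    metric_fn = _METRICS[metric]
    lab = ann.set_index("sample_id")["cell_type"]
    planned = [s for s in m.sample_ids if s in plan.assignment and s in lab.index]
    cpgs = pd.Index(m.cpg_ids, name="cpg_id")
    k = plan.k

    selected = pd.DataFrame(False, index=cpgs, columns=range(k))
    fold_metric = pd.DataFrame(np.nan, index=cpgs, columns=range(k))
    fold_scaled = pd.DataFrame(np.nan, index=cpgs, columns=range(k))
    fold_dmean = pd.DataFrame(np.nan, index=cpgs, columns=range(k))

    for f in range(k):
        in_fold = {s for s in planned if plan.assignment[s] == f}
        held_out = [s for s in planned if plan.assignment[s] != f]
        try:
            stats = cpg_stats(m, ann, target, sample_subset=in_fold)
        except ValueError as exc:
            raise ValueError(
                f"fold {f} has too few samples per group ({exc}); "
                "use fewer folds or more samples per cell type"
            ) from exc
        hyper, hypo, _ = parabola_select(stats, gate)
        fold_dmean[f] = stats["dMean"]
        y = np.array([lab[s] == target for s in held_out])
        beta = m.data[held_out]
        for cpg_set, hypo_side in ((hyper, False), (hypo, True)):
            for cpg in cpg_set:
                b = beta.loc[cpg].to_numpy(dtype=float)
                score = 1.0 - b if hypo_side else b
                val = metric_fn(score, y)
                selected.loc[cpg, f] = True
                fold_metric.loc[cpg, f] = val
                scale = abs(stats.loc[cpg, "dMean"]) if scale_by_dmean else 1.0
                fold_scaled.loc[cpg, f] = val * scale

    frequency = selected.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean_metric = fold_metric.mean(axis=1)
        mean_scaled = fold_scaled.mean(axis=1)
    mean_dmean = fold_dmean.mean(axis=1)
    final = (mean_scaled * frequency).fillna(0.0)

    table = pd.DataFrame(
        {
            "direction": np.where(mean_dmean > 0, "hyper", "hypo"),
            "selection_frequency": frequency,
            "mean_metric": mean_metric,
            "mean_scaled_metric": mean_scaled,
            "mean_dmean": mean_dmean,
            "final_score": final,
        },
        index=cpgs,
    )
    table["rank"] = -1
    for direction in ("hyper", "hypo"):
        mask = table["direction"] == direction
        sub = table.loc[mask].copy()
        sub["abs_dmean"] = sub["mean_dmean"].abs()
        sub = sub.sort_values(
            by=["final_score", "abs_dmean", "cpg_id"],
            ascending=[False, False, True],
            kind="stable",
        )
        table.loc[sub.index, "rank"] = np.arange(1, len(sub) + 1)
    return MarkerRanking(
        table=table,
        per_fold_selected=selected,
        per_fold_metric=fold_metric,
        per_fold_dmean=fold_dmean,
        metric=metric,
    )
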