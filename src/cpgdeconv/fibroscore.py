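"""The two-CpG FibroScore for estimating fibroblast/MSC content.

The score is the difference of beta values at one CpG that is
hypermethylated in fibroblasts (cg18096962, near the lncRNA
RP11-60A8.1) and one that is hypomethylated (cg18005280, in LRIG1):

    FibroScore = beta(hyper CpG) - beta(hypo CpG)

so fibroblast-like samples score high (near +1) and everything else
low (near -1). The score ranges over [-1, 1]; samples at or above a
threshold (default 0, the symmetric cutoff for a difference score)
are classified as fibroblast/MSC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

FIBROBLAST_LABEL = "fibroblast"
OTHER_LABEL = "other"


@dataclass
class FibroScoreConfig:
    hyper_cpg: str = "cg18096962"
    hypo_cpg: str = "cg18005280"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.hyper_cpg == self.hypo_cpg:
            raise ValueError("hyper_cpg and hypo_cpg must differ")


def fibro_score(m, cfg: FibroScoreConfig = FibroScoreConfig()) -> pd.DataFrame:
    """Score every sample; samples lacking either CpG are flagged missing.

    Returns a frame indexed by sample id with columns ``score`` (NaN
    when missing) and ``missing`` (bool).
    """
    have_hyper = cfg.hyper_cpg in m.data.index
    have_hypo = cfg.hypo_cpg in m.data.index
    if not have_hyper and not have_hypo:
        raise ValueError(
            f"neither {cfg.hyper_cpg!r} nor {cfg.hypo_cpg!r} present in the matrix"
        )
    idx = pd.Index(m.sample_ids, name="sample_id")
    if have_hyper and have_hypo:
        score = (
            m.data.loc[cfg.hyper_cpg].astype(float)
            - m.data.loc[cfg.hypo_cpg].astype(float)
        )
        score.index = idx
    else:
        score = pd.Series(np.nan, index=idx)
    missing = score.isna()
    return pd.DataFrame({"score": score, "missing": missing})


def classify_fibro(result: pd.DataFrame, threshold: float = 0.0) -> pd.Series:
    """Label samples: score >= threshold -> fibroblast, else other.

    Missing scores stay missing (NaN). Boundary ties go to fibroblast.
    """
    score = result["score"]
    labels = pd.Series(
        np.where(score >= threshold, FIBROBLAST_LABEL, OTHER_LABEL),
        index=score.index,
        dtype=object,
    )
    labels[score.isna()] = np.nan
    return labels


def accuracy(predicted, truth) -> float:
    """Fraction of exact label matches; missing predictions count as wrong."""
    predicted = pd.Series(predicted).reset_index(drop=True)
    truth = pd.Series(truth).reset_index(drop=True)
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if truth.isna().any():
        raise ValueError("truth labels must not be missing")
    return float((predicted == truth).mean())


def best_threshold(scores, truth, positive_label: str = FIBROBLAST_LABEL) -> float:
    """Accuracy-maximising cutoff on a labelled training set.

    Candidate cutoffs are the observed scores (rule: score >= t ->
    positive). Among equally accurate cutoffs the smallest is returned.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(pd.Series(truth) == positive_label)
    candidates = np.unique(scores)
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = float(((scores >= t) == y).mean())
        if acc > best_acc:
            best_t, best_acc = t, acc
    return float(best_t)


def compare_groups(scores_a, scores_b) -> tuple[float, float]:
    """Welch two-sample t-test between two groups of scores (two-sided).

    When both groups are degenerate (zero variance) the limit is
    returned directly: p = 0 if the means differ, p = 1 if equal.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
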