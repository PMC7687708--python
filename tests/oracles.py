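"""Independent brute-force oracles used to validate the implementation.

Everything here is written the slow, obvious way (explicit threshold
enumeration, dense grid search, textbook formulas) and shares no code
with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps


def brute_force_average_precision(scores, labels) -> float:
    """AP by explicit enumeration of every distinct threshold.

    At each threshold t (descending), predict positive where
    score >= t; AP = sum over thresholds of precision * recall
    increment. Tied scores naturally share a threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & labels).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def brute_force_best_f1(scores, labels) -> float:
    """Best F1 over every distinct threshold of score >= t -> positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    best = 0.0
    for t in sorted(set(scores)):
        pred = scores >= t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum())
        if tp:
            f1 = 2 * tp / (2 * tp + fp + fn)
            best = max(best, f1)
    return best


def simplex_grid(n_parts: int, step_denominator: int = 100) -> np.ndarray:
    """All weight vectors on the unit simplex with the given grid step."""
    pts = [
        np.array(c, dtype=float) / step_denominator
        for c in _compositions(step_denominator, n_parts)
    ]
    return np.array(pts)


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first, *rest)


def grid_search_nnls_residual(R: np.ndarray, b: np.ndarray, grid: np.ndarray) -> float:
    """Best achievable residual over grid directions with optimal scaling.

    Each grid point is a direction on the simplex; the non-negative
    scale minimising ||c R d - b|| is solved in closed form, so the
    grid covers all total weights, not just sum-to-one solutions.
    """
    RD = R @ grid.T  # (m, n_grid)
    num = b @ RD
    den = (RD**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.clip(num / den, 0.0, None)
    c = np.nan_to_num(c)
    res2 = b @ b - 2 * c * num + c**2 * den
    return float(np.sqrt(max(res2.min(), 0.0)))


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Textbook Welch t statistic, Welch-Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def parabola_passing_set(dmean, svar, a: float):
    """CpG positions passing svar < (a*dmean)^2, split by sign of dmean."""
    dmean = np.asarray(dmean, dtype=float)
    svar = np.asarray(svar, dtype=float)
    passing = svar < (a * dmean) ** 2
    hyper = set(np.flatnonzero(passing & (dmean > 0)))
    hypo = set(np.flatnonzero(passing & (dmean < 0)))
    return hyper, hypo
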