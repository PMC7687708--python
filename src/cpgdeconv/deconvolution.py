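"""Reference-based NNLS deconvolution of cell-type proportions.

The reference matrix holds, for a small set of marker CpGs, the mean
training beta value of each cell type. A bulk sample's beta vector b
over the same markers is then modelled as a non-negative combination
of the reference columns R:

    minimise ||R w - b||_2  subject to  w >= 0

solved with the Lawson-Hanson active-set algorithm; the weights are
normalised post hoc to proportions w / sum(w). The default eight-CpG
signature uses one hypomethylated marker per cell type (fibroblasts,
leukocytes, epithelial cells, hepatocytes, endothelial cells, glia,
neurons, iPSCs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from .data import BetaMatrix, _sep_for

logger = logging.getLogger(__name__)

#: Hypomethylated marker CpG per cell type in the default signature.
DEFAULT_SIGNATURE = {
    "fibroblast": "cg23068797",
    "leukocyte": "cg10673833",
    "epithelial": "cg06631999",
    "hepatocyte": "cg27197524",
    "endothelial": "cg06421238",
    "glia": "cg27309098",
    "neuron": "cg09998451",
    "iPSC": "cg21548464",
}

CONDITION_WARN_THRESHOLD = 1e6


@dataclass
class ReferenceMatrix:
    """Marker-CpG x cell-type matrix of mean training beta values.

    ``data`` has marker CpG ids as rows and cell-type labels as
    columns; ``n_samples`` records how many training samples each
    column mean is based on.
    """

    data: pd.DataFrame
    n_samples: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("reference matrix must not contain missing values")
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValueError("reference matrix values must lie in [0, 1]")
        cond = np.linalg.cond(vals) if min(vals.shape) > 0 else np.inf
        if cond > CONDITION_WARN_THRESHOLD:
            logger.warning(
                "reference matrix is ill-conditioned (cond=%.3g); "
                "near-collinear cell types destabilise NNLS",
                cond,
            )
        rank = np.linalg.matrix_rank(vals) if vals.size else 0
        self.full_column_rank = bool(rank == vals.shape[1])
        self.condition_number = float(cond)

    @property
    def marker_cpgs(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DeconvolutionResult:
    """Per-sample NNLS proportions plus raw weights and QC flags.

    ``proportions`` rows sum to 1 for non-excluded, non-degenerate
    samples; ``excluded`` flags samples skipped for missing marker
    CpGs (with the reason in ``exclusion_reason``); ``degenerate``
    flags an all-zero NNLS solution, whose proportions stay NaN.
    """

    proportions: pd.DataFrame
    raw_weights: pd.DataFrame
    residual: pd.Series
    excluded: pd.Series
    exclusion_reason: pd.Series
    degenerate: pd.Series


def build_reference(
    m: BetaMatrix,
    ann: pd.DataFrame,
    marker_cpgs: list[str],
    cell_types: list[str],
) -> ReferenceMatrix:
    """Mean beta per (marker CpG, cell type) over the annotated samples."""
    missing = [c for c in marker_cpgs if c not in m.data.index]
    if missing:
        raise ValueError(f"marker CpG(s) absent from matrix: {missing}")
    lab = ann.set_index("sample_id")["cell_type"]
    data = {}
    counts = {}
    for ct in cell_types:
        members = [s for s in m.sample_ids if s in lab.index and lab[s] == ct]
        if not members:
            raise ValueError(f"cell type {ct!r} has no annotated samples")
        data[ct] = m.data.loc[marker_cpgs, members].mean(axis=1)
        counts[ct] = len(members)
    ref = pd.DataFrame(data, index=pd.Index(marker_cpgs, name="cpg_id"))
    return ReferenceMatrix(ref, n_samples=pd.Series(counts))


def nnls_solve(R: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares: w >= 0 minimising ||R w - b||_2.

    Thin wrapper over the Lawson-Hanson active-set solver; returns the
    weight vector and the residual norm.
    """
    R = np.asarray(R, dtype=float)
    b = np.asarray(b, dtype=float)
    if R.ndim != 2 or b.ndim != 1 or R.shape[0] != b.shape[0]:
        raise ValueError(
            f"dimension mismatch: R is {R.shape}, b has length {b.shape}"
        )
    w, rnorm = scipy.optimize.nnls(R, b)
    return w, float(rnorm)


def deconvolve(
    m: BetaMatrix,
    R: ReferenceMatrix,
    missing_policy: str = "exclude",
) -> DeconvolutionResult:
    """Estimate cell-type proportions for every sample of ``m``.

    Each sample's beta values at the reference marker CpGs are fitted
    by NNLS against the reference columns and the weights normalised
    to proportions. Samples missing a marker CpG are excluded under
    ``missing_policy='exclude'`` (the conservative default); under
    ``'drop_rows'`` the missing markers are dropped from both sides,
    refusing when fewer markers than cell types would remain.
    """
    if missing_policy not in ("exclude", "drop_rows"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    markers = R.marker_cpgs
    types = R.cell_types
    samples = m.sample_ids
    Rv = R.data.to_numpy(dtype=float)

    proportions = pd.DataFrame(
        np.nan, index=pd.Index(samples, name="sample_id"), columns=types
    )
    raw = proportions.copy()
    residual = pd.Series(np.nan, index=proportions.index, name="residual")
    excluded = pd.Series(False, index=proportions.index, name="excluded")
    reason = pd.Series("", index=proportions.index, name="exclusion_reason")
    degenerate = pd.Series(False, index=proportions.index, name="degenerate")

    present = [c for c in markers if c in m.data.index]
    absent = [c for c in markers if c not in m.data.index]
    for s in samples:
        b_all = pd.Series(np.nan, index=markers, dtype=float)
        if present:
            b_all[present] = m.data.loc[present, s].astype(float)
        missing = list(b_all.index[b_all.isna()])
        if missing:
            if missing_policy == "exclude":
                excluded[s] = True
                reason[s] = f"missing marker CpG(s): {','.join(missing)}"
                continue
            keep = ~b_all.isna().to_numpy()
            if int(keep.sum()) < len(types):
                excluded[s] = True
                reason[s] = (
                    f"only {int(keep.sum())} marker(s) left after dropping "
                    f"missing rows, fewer than {len(types)} cell types"
                )
                continue
            logger.warning(
                "sample %s: dropping %d missing marker row(s) %s", s, len(missing), missing
            )
            w, rnorm = nnls_solve(Rv[keep], b_all.to_numpy()[keep])
        else:
            w, rnorm = nnls_solve(Rv, b_all.to_numpy())
        raw.loc[s] = w
        residual[s] = rnorm
        total = w.sum()
        if total == 0.0:
            degenerate[s] = True
            continue
        proportions.loc[s] = w / total
    if excluded.all():
        raise ValueError(
            "every sample was excluded for missing marker CpGs; "
            "check the matrix against the reference markers"
        )
    if absent:
        logger.warning(
            "marker CpG(s) %s absent from the matrix for all samples", absent
        )
    return DeconvolutionResult(
        proportions=proportions,
        raw_weights=raw,
        residual=residual,
        excluded=excluded,
        exclusion_reason=reason,
        degenerate=degenerate,
    )


def evaluate_mixtures(truth: pd.DataFrame, est: DeconvolutionResult) -> dict:
    """Agreement between true and estimated mixture fractions.

    ``truth`` has samples as rows, cell types as columns. Reports the
    per-cell-type mean absolute error, the overall RMSE, and the
    Pearson correlation of mixed vs estimated fractions pooled over
    all entries (NaN when either pooled vector is constant). Only
    samples with estimates (not excluded/degenerate) are compared.
    """
    est_p = est.proportions
    if set(truth.columns) != set(est_p.columns):
        raise ValueError(
            f"cell-type mismatch: truth has {sorted(truth.columns)}, "
            f"estimate has {sorted(est_p.columns)}"
        )
    usable = [s for s in truth.index if s in est_p.index and not est_p.loc[s].isna().any()]
    if not usable:
        raise ValueError("no samples with both truth and estimates")
    t = truth.loc[usable, est_p.columns].to_numpy(dtype=float)
    e = est_p.loc[usable].to_numpy(dtype=float)
    err = e - t
    mae = pd.Series(np.abs(err).mean(axis=0), index=est_p.columns)
    rmse = float(np.sqrt((err**2).mean()))
    tf, ef = t.ravel(), e.ravel()
    if np.ptp(tf) == 0.0 or np.ptp(ef) == 0.0:
        r = float("nan")
    else:
        r = float(np.corrcoef(tf, ef)[0, 1])
    return {
        "mae_per_cell_type": mae,
        "rmse": rmse,
        "pearson_r": r,
        "n_samples": len(usable),
    }


def load_reference_matrix(path: str | Path) -> ReferenceMatrix:
    """Read a reference matrix TSV/CSV: first column marker CpG id, header = cell types."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ReferenceMatrix(df.astype(float))


def write_reference_matrix(R: ReferenceMatrix, path: str | Path) -> None:
    path = Path(path)
    R.data.to_csv(path, sep=_sep_for(path), float_format="%.17g")
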