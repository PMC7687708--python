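"""Data model and I/O for CpG methylation beta-value matrices.

Beta values are methylation fractions in [0, 1], one per CpG site and
sample. BeadChip exports report them as fractions; pyrosequencing
instruments report percentages (0-100). Both are accepted; percentages
are rescaled to the unit interval on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens treated as missing values on input (case-insensitive match for "na"/"nan").
DEFAULT_MISSING_TOKENS = ("", "NA", "na", "Na", "nA", "NaN", "nan", "NAN")

#: Values above this are taken as evidence the matrix is on a percent scale.
PERCENT_DETECTION_THRESHOLD = 1.5

#: Values may exceed [0, 1] by at most this much before load refuses them.
RANGE_TOLERANCE = 1e-9


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation beta values.

    ``data`` has CpG ids as the row index and sample ids as columns;
    every non-missing entry lies in [0, 1]. ``scale_note`` records
    whether the source file was rescaled from percentages.
    """

    data: pd.DataFrame
    scale_note: str = "unit"

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate CpG id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (
            finite.min() < -RANGE_TOLERANCE or finite.max() > 1.0 + RANGE_TOLERANCE
        ):
            bad = finite[(finite < -RANGE_TOLERANCE) | (finite > 1.0 + RANGE_TOLERANCE)][0]
            raise ValueError(
                f"beta value {bad!r} outside [0, 1]; pass scale='percent' for 0-100 data"
            )
        # values within numerical tolerance of the boundary are snapped onto it
        self.data = self.data.clip(lower=0.0, upper=1.0)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(cpg_ids)], scale_note=self.scale_note)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.data[list(sample_ids)], scale_note=self.scale_note)


@dataclass
class ProbeFilterSpec:
    """Probe-level filters applied to a :class:`BetaMatrix`.

    ``keep_list`` restricts to a probe universe (e.g. CpGs shared
    between BeadChip platforms), ``drop_list`` removes probes (e.g. on
    sex chromosomes), and ``drop_missing`` removes any CpG with at
    least one missing value. Drop is applied after keep.
    """

    keep_list: set[str] | None = None
    drop_list: set[str] | None = None
    drop_missing: bool = False


def load_beta_matrix(
    path: str | Path,
    orientation: str = "cpg_rows",
    scale: str = "auto",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> BetaMatrix:
    """Read a delimited beta-value matrix (TSV or CSV by extension).

    Parameters
    ----------
    orientation:
        ``cpg_rows`` (default) if rows are CpGs, ``sample_rows`` if the
        file is transposed.
    scale:
        ``unit`` for values already in [0, 1], ``percent`` for 0-100
        data, or ``auto`` to rescale by 1/100 whenever any finite value
        exceeds 1.5.
    """
    path = Path(path)
    if orientation not in ("cpg_rows", "sample_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if scale not in ("auto", "unit", "percent"):
        raise ValueError(f"unknown scale {scale!r}")
    raw = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    tokens = {t.lower() for t in missing_tokens}
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cleaned = raw[col].str.strip()
        is_missing = cleaned.str.lower().isin(tokens)
        parsed = pd.to_numeric(cleaned.where(~is_missing), errors="coerce")
        bad = parsed.isna() & ~is_missing
        if bad.any():
            row_id = raw.index[bad][0]
            raise ValueError(
                f"unparseable cell {raw.loc[row_id, col]!r} at row {row_id!r}, column {col!r}"
            )
        numeric[col] = parsed
    if orientation == "sample_rows":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)

    scale_note = "unit"
    vals = numeric.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if scale == "percent" or (
        scale == "auto" and finite.size and finite.max() > PERCENT_DETECTION_THRESHOLD
    ):
        numeric = numeric / 100.0
        scale_note = "percent"
    return BetaMatrix(numeric, scale_note=scale_note)


def write_beta_matrix(m: BetaMatrix, path: str | Path) -> None:
    """Write a matrix as delimited text, CpGs as rows, full precision."""
    path = Path(path)
    m.data.to_csv(path, sep=_sep_for(path), float_format="%.17g", na_rep="NA")


REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "cell_type")
VALID_SPLITS = ("train", "validation")


def load_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table.

    Requires columns ``sample_id`` and ``cell_type``; ``study_id`` and
    ``split`` (train/validation) are optional.
    """
    path = Path(path)
    ann = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in REQUIRED_ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ValueError(f"annotation file {path} is missing required column {col!r}")
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in annotation: {dup!r}")
    if "split" in ann.columns:
        given = set(ann.loc[ann["split"] != "", "split"])
        invalid = given - set(VALID_SPLITS)
        if invalid:
            raise ValueError(
                f"invalid split value(s) {sorted(invalid)}; expected one of {VALID_SPLITS}"
            )
    return ann.reset_index(drop=True)


def load_probe_list(path: str | Path) -> set[str]:
    """Read a plain-text probe list, one CpG id per line; '#' starts a comment."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids


def filter_probes(m: BetaMatrix, spec: ProbeFilterSpec) -> BetaMatrix:
    """Apply keep/drop/missing-value probe filters, preserving CpG order.

    Mirrors the common preprocessing of restricting to a cross-platform
    probe universe, excluding sex-chromosome probes and dropping probes
    with missing data in any sample.
    """
    keep = m.data.index
    if spec.keep_list is not None:
        keep = keep[keep.isin(spec.keep_list)]
    if spec.drop_list is not None:
        keep = keep[~keep.isin(spec.drop_list)]
    out = m.data.loc[keep]
    if spec.drop_missing and out.shape[1] > 0:
        out = out.loc[~out.isna().any(axis=1)]
    if out.shape[0] == 0:
        raise ValueError(
            "probe filtering removed every CpG; inspect keep/drop lists and missingness"
        )
    return BetaMatrix(out, scale_note=m.scale_note)


def align_samples(
    m: BetaMatrix, ann: pd.DataFrame
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Restrict matrix and annotation to their shared samples, matrix order."""
    ann_ids = set(ann["sample_id"])
    shared = [s for s in m.sample_ids if s in ann_ids]
    if not shared:
        raise ValueError("no samples shared between matrix and annotation")
    dropped_m = sorted(set(m.sample_ids) - set(shared))
    dropped_a = sorted(ann_ids - set(shared))
    if dropped_m:
        logger.warning("dropping %d matrix sample(s) without annotation: %s", len(dropped_m), dropped_m)
    if dropped_a:
        logger.warning("dropping %d annotated sample(s) absent from matrix: %s", len(dropped_a), dropped_a)
    out_ann = ann.set_index("sample_id").loc[shared].reset_index()
    return m.subset_samples(shared), out_ann
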