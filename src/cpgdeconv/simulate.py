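"""Synthetic beta-value data with planted markers and known mixtures.

Emulates the structure that targeted methylation deconvolution
assumes: each cell type is hypomethylated at its own marker CpGs
(beta around 0.10) and hypermethylated at the markers of every other
type (around 0.85), while background CpGs share one methylation level
across all types. Pure profiles draw beta values from a Beta
distribution reparameterised by (mean, SD), which keeps the support
in [0, 1]; in-silico DNA mixtures are convex combinations of pure
mean profiles plus truncated Gaussian measurement noise, mimicking
technical error of array or pyrosequencing readings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import BetaMatrix


@dataclass
class SimulationConfig:
    """Parameters of the synthetic methylation world.

    Defaults give five cell types, ten samples each, ten planted
    hypomethylated marker CpGs per type among 500 background CpGs,
    within-type biological noise SD 0.05 on beta, and mixture
    measurement noise SD 0.02.
    """

    n_cell_types: int = 5
    samples_per_type: int = 10
    n_marker_cpgs_per_type: int = 10
    n_background_cpgs: int = 500
    marker_low_mean: float = 0.10
    marker_high_mean: float = 0.85
    within_type_sd: float = 0.05
    measurement_sd: float = 0.02
    dirichlet_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("marker_low_mean", "marker_high_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("within_type_sd", "measurement_sd"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "n_cell_types",
            "samples_per_type",
            "n_marker_cpgs_per_type",
            "n_background_cpgs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted.

    ``cpg_roles`` maps each CpG id to ``marker:<cell type>`` or
    ``background``; ``proportions`` (mixtures only) holds the true
    per-sample mixing fractions, each row summing to 1.
    """

    cpg_roles: pd.Series
    proportions: pd.DataFrame | None = None

    def markers_of(self, cell_type: str) -> list[str]:
        role = f"marker:{cell_type}"
        return list(self.cpg_roles.index[self.cpg_roles == role])


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, sd: float, shape) -> np.ndarray:
    """Beta-distribution draws with the given mean and SD.

    Requires SD^2 < mean * (1 - mean) for every mean; SD = 0 returns
    the mean itself. mean of exactly 0 or 1 is returned as-is (the
    distribution degenerates there).
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), shape)
    if sd == 0.0:
        return mean.copy()
    interior = (mean > 0.0) & (mean < 1.0)
    bound = mean * (1.0 - mean)
    if np.any(sd**2 >= bound[interior]):
        worst = mean[interior][np.argmin(bound[interior])]
        raise ValueError(
            f"infeasible Beta parameterisation: need SD^2 < mean*(1-mean); "
            f"SD={sd} is too large for mean={worst:.4g}"
        )
    out = mean.copy()
    nu = bound[interior] / sd**2 - 1.0
    a = mean[interior] * nu
    b = (1.0 - mean[interior]) * nu
    out[interior] = rng.beta(a, b)
    return out


def _type_names(n: int) -> list[str]:
    return [f"type{t + 1:02d}" for t in range(n)]


def simulate_pure_profiles(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Generate pure cell-type profiles with planted marker CpGs.

    Each sample of type t draws its own markers around
    ``marker_low_mean``, other types' markers around
    ``marker_high_mean``, and background CpGs around a per-CpG mean
    shared by all types (uniform in [0.2, 0.8]). Deterministic for a
    given seed. Returns (matrix, annotation, ground truth).
    """
    rng = np.random.default_rng(cfg.seed)
    types = _type_names(cfg.n_cell_types)
    marker_ids = [
        f"cg_marker_{t}_{j + 1:03d}"
        for t in types
        for j in range(cfg.n_marker_cpgs_per_type)
    ]
    background_ids = [f"cg_bg_{i + 1:05d}" for i in range(cfg.n_background_cpgs)]
    cpgs = marker_ids + background_ids
    samples = [
        f"{t}_s{i + 1:03d}" for t in types for i in range(cfg.samples_per_type)
    ]

    # per-CpG target mean for each cell type
    bg_means = rng.uniform(0.2, 0.8, size=cfg.n_background_cpgs)
    mean_by_type = np.empty((len(cpgs), cfg.n_cell_types))
    for tj, t in enumerate(types):
        col = np.full(len(marker_ids), cfg.marker_high_mean)
        own = slice(
            tj * cfg.n_marker_cpgs_per_type, (tj + 1) * cfg.n_marker_cpgs_per_type
        )
        col[own] = cfg.marker_low_mean
        mean_by_type[:, tj] = np.concatenate([col, bg_means])

    values = np.empty((len(cpgs), len(samples)))
    for tj in range(cfg.n_cell_types):
        cols = slice(tj * cfg.samples_per_type, (tj + 1) * cfg.samples_per_type)
        means = mean_by_type[:, tj][:, None]
        values[:, cols] = _beta_draw(
            rng, means, cfg.within_type_sd, (len(cpgs), cfg.samples_per_type)
        )

    matrix = BetaMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(cpgs, name="cpg_id"),
            columns=pd.Index(samples, name="sample_id"),
        )
    )
    ann = pd.DataFrame(
        {
            "sample_id": samples,
            "cell_type": [s.rsplit("_s", 1)[0] for s in samples],
        }
    )
    roles = pd.Series(
        [f"marker:{c.split('_')[2]}" for c in marker_ids]
        + ["background"] * cfg.n_background_cpgs,
        index=pd.Index(cpgs, name="cpg_id"),
        name="role",
    )
    return matrix, ann, GroundTruth(cpg_roles=roles)


def simulate_selection_benchmark(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Benchmark for marker selection: planted markers are the only signal.

    Identical to :func:`simulate_pure_profiles` — background CpGs
    already share one distribution across cell types, so their
    expected dMean is 0 and the planted markers are the only true
    cell-type signal.
    """
    return simulate_pure_profiles(cfg)


def simulate_mixtures(
    pure_means: pd.DataFrame,
    n_mixtures: int | None = None,
    cfg: SimulationConfig = SimulationConfig(),
    proportions: pd.DataFrame | None = None,
) -> tuple[BetaMatrix, GroundTruth]:
    """In-silico DNA mixtures of pure mean profiles with known fractions.

    ``pure_means`` is a CpG x cell-type frame of mean beta values (a
    reference matrix works directly). Mixing weights come from
    ``proportions`` (samples x cell types, rows summing to 1) when
    given — supporting e.g. an incremental two-type gradient — or are
    drawn from a symmetric Dirichlet(``cfg.dirichlet_alpha``).
    Each mixture beta is sum_t w_t * mean_t plus Normal(0,
    ``cfg.measurement_sd``) noise truncated to [0, 1] by clipping.
    """
    rng = np.random.default_rng(cfg.seed)
    types = list(pure_means.columns)
    if proportions is not None:
        sums = proportions.sum(axis=1).to_numpy(dtype=float)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = proportions.index[np.abs(sums - 1.0) > 1e-9][0]
            raise ValueError(f"proportions for sample {bad!r} do not sum to 1")
        if list(proportions.columns) != types:
            proportions = proportions[types]
        W = proportions.to_numpy(dtype=float)
        sample_ids = [str(s) for s in proportions.index]
    else:
        if n_mixtures is None:
            raise ValueError("either n_mixtures or proportions must be given")
        W = rng.dirichlet(np.full(len(types), cfg.dirichlet_alpha), size=n_mixtures)
        sample_ids = [f"mix{i + 1:03d}" for i in range(n_mixtures)]

    M = pure_means.to_numpy(dtype=float)
    clean = M @ W.T
    noisy = clean + rng.normal(0.0, cfg.measurement_sd, size=clean.shape)
    noisy = np.clip(noisy, 0.0, 1.0)
    matrix = BetaMatrix(
        pd.DataFrame(
            noisy,
            index=pure_means.index.astype(str).rename("cpg_id"),
            columns=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = GroundTruth(
        cpg_roles=pd.Series(
            "mixture_marker", index=matrix.data.index, name="role"
        ),
        proportions=pd.DataFrame(
            W, index=pd.Index(sample_ids, name="sample_id"), columns=types
        ),
    )
    return matrix, truth


def gradient_proportions(
    types: list[str], varied: str, other: str, steps: np.ndarray | None = None
) -> pd.DataFrame:
    """Two-type incremental gradient: ``varied`` goes 0..1, ``other`` fills up.

    Mirrors in-vitro two-component DNA titrations (e.g. neuron/glia
    mixes in incremental proportions). Remaining types stay at 0.
    """
    if steps is None:
        steps = np.linspace(0.0, 1.0, 11)
    rows = []
    for w in steps:
        row = dict.fromkeys(types, 0.0)
        row[varied] = float(w)
        row[other] = 1.0 - float(w)
        rows.append(row)
    idx = pd.Index([f"grad{i + 1:02d}" for i in range(len(steps))], name="sample_id")
    return pd.DataFrame(rows, index=idx)[types]
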