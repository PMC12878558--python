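"""Genotype-environment association by redundancy analysis (RDA).

Centred (mean-imputed) SNP dosages are regressed on standardized
environmental predictors; the eigen-decomposition of the fitted values
gives the constrained axes.  Outlier loci are those whose loadings on the
tested axes sit more than ``outlier_sd`` standard deviations from the mean,
and per-variable significance comes from a marginal permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from popg.variants import GenotypeMatrix, MISSING

__all__ = [
    "GEAConfig",
    "RDAResult",
    "collinearity_filter",
    "rda_fit",
    "rda_outliers",
    "marginal_permutation_test",
]


@dataclass
class GEAConfig:
    spearman_threshold: float = 0.7
    outlier_sd: float = 3.0
    n_perm: int = 100
    axes: tuple[int, ...] = (1, 2)

    def validate(self) -> None:
        if not (0.0 < self.spearman_threshold <= 1.0):
            raise ValueError("spearman_threshold must be in (0, 1]")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")


@dataclass
class RDAResult:
    samples: list[str]
    env_vars: list[str]
    scores: np.ndarray        # samples x axes (constrained)
    loadings: np.ndarray      # SNPs x axes
    eigenvalues: np.ndarray
    explained: np.ndarray     # share of total genotype variance per axis
    snp_ids: list[str] = field(default_factory=list)


def collinearity_filter(
    env: pd.DataFrame, threshold: float = 0.7
) -> list[str]:
    """Greedy Spearman collinearity pruning of environment variables.

    While any pair exceeds ``|rho| > threshold``, the member of the worst
    pair with the larger mean absolute correlation to all other variables
    is dropped.  Constant variables are dropped up front with a warning.
    Returns the retained column names in their original order.
    """
    import warnings

    cols = list(env.columns)
    values = env.to_numpy(dtype=float)
    keep = []
    for i, c in enumerate(cols):
        if np.nanstd(values[:, i]) == 0:
            warnings.warn(f"environment variable {c!r} is constant; dropped")
        else:
            keep.append(c)
    if len(keep) < 2:
        return keep

    data = env[keep]
    stat = spearmanr(data.to_numpy(dtype=float)).statistic
    if np.isscalar(stat):  # scipy collapses the 2-variable case to a float
        rho = np.array([[1.0, stat], [stat, 1.0]])
    else:
        rho = np.asarray(stat)
    np.fill_diagonal(rho, 0.0)
    rho = np.abs(rho)
    active = list(range(len(keep)))
    while True:
        sub = rho[np.ix_(active, active)]
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[worst] <= threshold:
            break
        a, b = worst
        mean_a = sub[a].sum() / (len(active) - 1)
        mean_b = sub[b].sum() / (len(active) - 1)
        drop = a if mean_a >= mean_b else b
        del active[drop]
        if len(active) < 2:
            break
    return [keep[i] for i in active]


def _prepare(matrix: GenotypeMatrix, env: pd.DataFrame):
    dos = matrix.dosage.astype(np.float64)
    miss = matrix.missing_mask()
    if miss.any():
        n_obs = np.maximum((~miss).sum(axis=0), 1)
        col_mean = np.where(~miss, dos, 0.0).sum(axis=0) / n_obs
        dos = np.where(miss, col_mean[None, :], dos)
    y = dos - dos.mean(axis=0)[None, :]
    x = env.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    return y, x


def rda_fit(
    matrix: GenotypeMatrix,
    env: pd.DataFrame,
    config: GEAConfig | None = None,
) -> RDAResult:
    """Redundancy analysis of dosages constrained by environment variables.

    The env frame must be indexed/ordered like the matrix samples.  Raises
    when the number of predictors reaches the number of samples
    (unidentifiable regression).
    """
    config = config or GEAConfig()
    config.validate()
    n, m = matrix.n_samples, matrix.n_sites
    if env.shape[0] != n:
        raise ValueError("environment rows must match matrix samples")
    if env.shape[1] >= n:
        raise ValueError("need fewer environment variables than samples")
    y, x = _prepare(matrix, env)

    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(x.shape[1], len(s))
    eig = (s**2) / (n - 1)
    total_var = (y * y).sum() / (n - 1)
    scores = u[:, :n_axes] * s[:n_axes]
    loadings = vt[:n_axes].T
    for a in range(n_axes):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return RDAResult(
        samples=list(matrix.samples),
        env_vars=list(env.columns),
        scores=scores,
        loadings=loadings,
        eigenvalues=eig[:n_axes],
        explained=eig[:n_axes] / total_var if total_var > 0 else eig[:n_axes] * 0,
        snp_ids=matrix.site_ids(),
    )


def rda_outliers(
    result: RDAResult,
    axes: tuple[int, ...] = (1, 2),
    sd: float = 3.0,
) -> pd.DataFrame:
    """Loci with |loading - mean| > sd * SD on any tested axis (1-based).

    Degenerate axes (zero SD) yield no outliers.  Returns a frame with
    snp, axis, loading and z columns (one row per flagged axis).
    """
    rows = []
    for ax in axes:
        if ax < 1 or ax > result.loadings.shape[1]:
            continue
        lo = result.loadings[:, ax - 1]
        mu, sigma = lo.mean(), lo.std()
        if sigma == 0:
            continue
        z = (lo - mu) / sigma
        for j in np.where(np.abs(z) > sd)[0]:
            rows.append(
                {"snp": result.snp_ids[j], "snp_index": int(j),
                 "axis": ax, "loading": float(lo[j]), "z": float(z[j])}
            )
    return pd.DataFrame(rows, columns=["snp", "snp_index", "axis", "loading", "z"])


def _constrained_ss(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    return float((fitted * fitted).sum())


def marginal_permutation_test(
    matrix: GenotypeMatrix,
    env: pd.DataFrame,
    variable: str,
    n_perm: int = 100,
    seed: int = 0,
) -> float:
    """Marginal significance of one predictor given all others.

    The statistic is the drop in constrained sum of squares when the focal
    variable is removed; the null permutes the focal variable's sample
    labels and refits.  p = (#{perm >= obs} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if variable not in env.columns:
        raise KeyError(f"variable {variable!r} not in environment table")
    y, x = _prepare(matrix, env)
    focal = list(env.columns).index(variable)
    others = [j for j in range(x.shape[1]) if j != focal]

    full = _constrained_ss(y, x)
    reduced = _constrained_ss(y, x[:, others]) if others else 0.0
    observed = full - reduced

    rng = np.random.default_rng(seed)
    count = 0
    xp = x.copy()
    for _ in range(n_perm):
        xp[:, focal] = x[rng.permutation(len(y)), focal]
        stat = _constrained_ss(y, xp) - reduced
        if stat >= observed - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(p)
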