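"""Population structure: PCA, IBS/allele-sharing distances, NJ, MRM.

Distance matrices are plain symmetric numpy arrays wrapped with their sample
ids; genetic distance is allele sharing on dosages (0 identical, 0.5 for a
one-step difference, 1 for opposite homozygotes), geographic distance is the
haversine great circle with Earth radius 6371 km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from popg.variants import GenotypeMatrix, MISSING, VariantTable

__all__ = [
    "DistanceMatrix",
    "PCAResult",
    "MRMResult",
    "pca",
    "ibs_distance",
    "allele_sharing_distance",
    "haversine_matrix",
    "mrm",
    "nj_tree",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match samples")

    def validate(self) -> None:
        v = self.values
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if np.nanmin(v) < -1e-12:
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        """Lower-triangle vectorization (row-major, i > j)."""
        iu = np.triu_indices(len(self.samples), k=1)
        return self.values[iu]


@dataclass
class PCAResult:
    samples: list[str]
    scores: np.ndarray       # samples x axes
    eigenvalues: np.ndarray
    explained: np.ndarray    # proportion of total variance per axis
    loadings: np.ndarray     # sites x axes
    n_sites_used: int


@dataclass
class MRMResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_permutations: int


def pca(
    matrix: GenotypeMatrix,
    max_missing: float = 0.01,
    n_axes: int = 10,
) -> PCAResult:
    """PCA of centred dosages with site-mean imputation of missing calls.

    Sites with missingness above ``max_missing`` are dropped first; columns
    are centred but not scaled.  Axis signs are fixed by making the
    largest-magnitude loading of each axis positive.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    dos = matrix.dosage.astype(np.float64)
    miss = matrix.missing_mask()
    keep = miss.mean(axis=0) <= max_missing
    if not keep.any():
        raise ValueError("no sites pass the PCA missingness filter")
    x = dos[:, keep]
    m = miss[:, keep]
    with np.errstate(invalid="ignore"):
        col_mean = np.where(
            (~m).sum(axis=0) > 0,
            np.where(~m, x, 0).sum(axis=0) / np.maximum((~m).sum(axis=0), 1),
            0.0,
        )
    x = np.where(m, col_mean[None, :], x)
    x -= x.mean(axis=0)[None, :]

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    eig = s**2 / (n - 1)
    total = eig.sum()
    k = min(n_axes, len(s))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    # deterministic sign: largest |loading| positive per axis
    for a in range(k):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    explained = eig[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(
        samples=list(matrix.samples),
        scores=scores,
        eigenvalues=eig[:k],
        explained=explained,
        loadings=loadings,
        n_sites_used=int(keep.sum()),
    )


def _pairwise_sharing(dosage: np.ndarray) -> np.ndarray:
    """Mean |dosage difference|/2 over mutually non-missing sites."""
    n = dosage.shape[0]
    out = np.zeros((n, n))
    called = dosage != MISSING
    d = dosage.astype(np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            ok = called[i] & called[j]
            if not ok.any():
                out[i, j] = out[j, i] = np.nan
                continue
            dist = np.abs(d[i, ok] - d[j, ok]).mean() / 2.0
            out[i, j] = out[j, i] = dist
    return out


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS distance over variant sites (0 same, 0.5 het-vs-hom, 1 opposite)."""
    return DistanceMatrix(list(matrix.samples), _pairwise_sharing(matrix.dosage))


def allele_sharing_distance(table: VariantTable) -> DistanceMatrix:
    """Per-site allele-sharing distance over ALL sites (invariant included).

    Equivalent to the p-distance on IUPAC-coded sequences for bi-allelic
    diploid data under the 0.5-heterozygote convention; used as NJ input.
    """
    return DistanceMatrix(list(table.samples), _pairwise_sharing(table.gt.T))


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    for lat in (lat1, lat2):
        if abs(lat) > 90:
            raise ValueError(f"latitude {lat} out of range")
    for lon in (lon1, lon2):
        if abs(lon) > 180:
            raise ValueError(f"longitude {lon} out of range")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def haversine_matrix(coords) -> DistanceMatrix:
    """Pairwise haversine distances from a coords frame (sample, lat, lon)."""
    samples = list(coords["sample"])
    lat = coords["lat"].to_numpy(dtype=float)
    lon = coords["lon"].to_numpy(dtype=float)
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(samples, out)


def mrm(
    response: DistanceMatrix,
    predictor: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MRMResult:
    """Regression of one distance matrix on another with matrix permutation.

    OLS on the vectorized upper triangles; significance from jointly
    permuting the rows/columns of the response matrix and recomputing R^2;
    p = (#{permuted R^2 >= observed} + 1) / (n_perm + 1).
    """
    if response.samples != predictor.samples:
        raise ValueError("distance matrices must share the same samples")
    y = response.condensed()
    x = predictor.condensed()
    ok = np.isfinite(y) & np.isfinite(x)

    def _fit(yv, xv):
        xm, ym = xv.mean(), yv.mean()
        sxx = ((xv - xm) ** 2).sum()
        if sxx == 0:
            return 0.0, ym, 0.0
        b = ((xv - xm) * (yv - ym)).sum() / sxx
        a = ym - b * xm
        resid = yv - (a + b * xv)
        syy = ((yv - ym) ** 2).sum()
        r2 = 1.0 - resid @ resid / syy if syy > 0 else 0.0
        return b, a, r2

    slope, intercept, r2_obs = _fit(y[ok], x[ok])
    rng = np.random.default_rng(seed)
    n = len(response.samples)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = response.values[np.ix_(perm, perm)][iu]
        okp = np.isfinite(yp) & np.isfinite(x)
        _, _, r2p = _fit(yp[okp], x[okp])
        if r2p >= r2_obs - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MRMResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2_obs),
        p_value=float(p),
        n_permutations=n_perm,
    )


def nj_tree(dist: DistanceMatrix) -> str:
    """Neighbour-joining (Saitou-Nei) tree as a Newick string.

    Ties in the Q matrix break towards the lowest (i, j) index pair;
    negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  Exact on additive distance matrices.
    """
    n = len(dist.samples)
    if n < 3:
        raise ValueError("NJ needs at least 3 samples")
    dist.validate()
    d = dist.values.astype(np.float64).copy()
    nodes = [_escape(s) for s in dist.samples]
    active = list(range(n))

    while len(active) > 2:
        r = len(active)
        sub = d[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among ties
        flat = np.round(q, 12)
        best = np.min(flat)
        ii, jj = np.argwhere(flat == best)[0]
        if ii > jj:
            ii, jj = jj, ii
        a, b = active[ii], active[jj]
        dij = sub[ii, jj]
        la = 0.5 * dij + (sums[ii] - sums[jj]) / (2 * (r - 2))
        lb = dij - la
        # clamp negatives, compensating on the sister branch
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        new_label = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g})"
        # distances from the new node u to every other active node
        du = 0.5 * (d[a, :] + d[b, :] - dij)
        d[a, :] = du
        d[:, a] = du
        d[a, a] = 0.0
        nodes[a] = new_label
        active.remove(b)

    a, b = active
    la = d[a, b]
    newick = f"({nodes[a]}:{la / 2:.10g},{nodes[b]}:{la / 2:.10g});"
    return newick


def _escape(name: str) -> str:
    if any(c in name for c in "(),:; \t"):
        return "'" + name.replace("'", "''") + "'"
    return name
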