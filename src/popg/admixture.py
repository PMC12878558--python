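"""Ancestry estimation by masked-cross-validation nonnegative factorization.

Genotypes are expanded to allele-frequency form (dosage / 2 in [0, 1]) and
factorized as ``X ~ Q @ G`` with ``Q`` (samples x K) on the probability
simplex per sample and ``G`` (K x sites) in [0, 1], by alternating
projected least squares on the observed, unmasked entries.  Model choice
uses the masked cross-entropy: a fraction of entries is hidden during
fitting and scored afterwards; ``select_k`` picks the K with the smallest
mean cross-entropy over runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from popg.variants import GenotypeMatrix, MISSING

__all__ = ["AdmixtureResult", "admixture_nmf", "select_k"]

_EPS = 1e-6


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray                 # samples x K, rows sum to 1
    G: np.ndarray                 # K x sites, in [0, 1]
    cross_entropy: float          # best run's masked cross-entropy
    cross_entropies: list[float]  # one per run
    n_iter: int
    samples: list[str] = field(default_factory=list)


def _masked_ce(x, pred, mask):
    y = x[mask]
    p = np.clip(pred[mask], _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _solve_rows(A, X, W):
    """Row-wise weighted least squares: find B with B A ~ X under weights W.

    Solves, for each row i, ``B[i] = argmin || W[i] * (X[i] - b A) ||^2``.
    A: (K, m); X, W: (n, m).  Returns (n, K).
    """
    K = A.shape[0]
    n = X.shape[0]
    out = np.empty((n, K))
    # normal equations per row: (A W_i A^T) b = A W_i x_i
    AW = A[None, :, :] * W[:, None, :]            # (n, K, m)
    lhs = AW @ A.T                                 # (n, K, K)
    rhs = (AW * X[:, None, :]).sum(axis=2)         # (n, K)
    lhs += 1e-9 * np.eye(K)[None, :, :]
    try:
        out = np.linalg.solve(lhs, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        for i in range(n):
            out[i] = np.linalg.lstsq(lhs[i], rhs[i], rcond=None)[0]
    return out


def _simplex_nnls(G, x, w, penalty=10.0):
    """Per-sample ancestry rows: NNLS with a soft sum-to-one penalty.

    Solves ``min_{q >= 0} ||w * (x - q G)||^2 + penalty * (sum(q) - 1)^2``
    for each row, then renormalizes exactly onto the simplex.  Unlike
    clip-and-renormalize this handles degenerate rows (e.g. all-reference
    samples) correctly.
    """
    from scipy.optimize import nnls

    K, m = G.shape
    n = x.shape[0]
    out = np.empty((n, K))
    ones = np.full((1, K), np.sqrt(penalty))
    for i in range(n):
        sw = np.sqrt(w[i])
        A = np.vstack([(G * sw[None, :]).T, ones])
        b = np.concatenate([x[i] * sw, [np.sqrt(penalty)]])
        q, _ = nnls(A, b)
        s = q.sum()
        out[i] = q / s if s > 0 else np.full(K, 1.0 / K)
    return out


def _fit_once(x, observed, rng, K, tol, max_iter):
    n, m = x.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    w = observed.astype(np.float64)
    xo = np.where(observed, x, 0.0)
    G = rng.uniform(0.05, 0.95, size=(K, m))
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # G update: least squares per site column, boxed into [0, 1]
        G = _solve_rows(Q.T, xo.T, w.T).T
        np.clip(G, 0.0, 1.0, out=G)
        # Q update: simplex-constrained nonnegative least squares per sample
        Q = _simplex_nnls(G, xo, w)
        resid = np.where(observed, x - Q @ G, 0.0)
        rss = float((resid * resid).sum())
        if prev - rss < tol:
            break
        prev = rss
    return Q, G, it


def admixture_nmf(
    matrix: GenotypeMatrix,
    K: int,
    mask_fraction: float = 0.05,
    n_runs: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> AdmixtureResult:
    """Fit K ancestral components; keep the best of ``n_runs`` restarts.

    K = 1 has the closed form Q = 1, G = observed site means.  Raises when
    K exceeds the number of samples.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_samples:
        raise ValueError(f"K={K} exceeds {matrix.n_samples} samples")
    dos = matrix.dosage
    observed_all = dos != MISSING
    x = np.where(observed_all, dos, 0).astype(np.float64) / 2.0

    rng = np.random.default_rng(seed)
    best = None
    ces = []
    for _ in range(max(n_runs, 1)):
        mask = observed_all & (rng.random(dos.shape) < mask_fraction)
        observed = observed_all & ~mask
        if K == 1:
            denom = np.maximum(observed.sum(axis=0), 1)
            g = (np.where(observed, x, 0.0).sum(axis=0) / denom)[None, :]
            q = np.ones((matrix.n_samples, 1))
            it = 0
        else:
            q, g, it = _fit_once(x, observed, rng, K, tol, max_iter)
        score_mask = mask if mask.any() else observed_all
        ce = _masked_ce(x, q @ g, score_mask)
        ces.append(ce)
        if best is None or ce < best[0]:
            best = (ce, q, g, it)
    ce, q, g, it = best
    return AdmixtureResult(
        K=K,
        Q=q,
        G=g,
        cross_entropy=ce,
        cross_entropies=ces,
        n_iter=it,
        samples=list(matrix.samples),
    )


def select_k(results: dict[int, AdmixtureResult]) -> int:
    """Return the K whose mean masked cross-entropy over runs is smallest."""
    if not results:
        raise ValueError("no results to select from")
    means = {k: float(np.mean(r.cross_entropies)) for k, r in results.items()}
    return min(means, key=lambda k: (means[k], k))
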