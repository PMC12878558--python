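"""Genotype linkage disequilibrium: decay curves and LD pruning.

r^2 is the squared Pearson correlation between dosage vectors over
pairwise-complete samples (geno-r2 convention; unphased, no haplotypes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from popg.variants import GenotypeMatrix, MISSING

__all__ = ["pairwise_r2", "ld_decay", "ld_prune"]


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries (-1) are dropped pairwise.  Returns NaN when fewer than
    2 complete pairs remain or either vector is constant.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xv = x[ok].astype(np.float64)
    yv = y[ok].astype(np.float64)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_decay(
    matrix: GenotypeMatrix,
    max_dist: int = 10_000,
    bin_size: int = 5_000,
) -> pd.DataFrame:
    """Mean r^2 by pairwise distance bin, within contigs.

    All site pairs with 0 < distance <= max_dist are scored; pairs where r^2
    is undefined (constant vector, too few complete pairs) are skipped and
    counted.  Columns: bin_low, bin_high, bin_mid, mean_r2, n_pairs,
    n_skipped.
    """
    if matrix.n_sites < 2:
        raise ValueError("need at least 2 variant sites")
    n_bins = -(-max_dist // bin_size)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    skipped = np.zeros(n_bins, dtype=int)

    contigs = pd.unique(matrix.contig)
    for c in contigs:
        sel = np.where(matrix.contig == c)[0]
        pos = matrix.pos[sel]
        order = np.argsort(pos)
        sel, pos = sel[order], pos[order]
        for ii in range(len(sel)):
            for jj in range(ii + 1, len(sel)):
                d = pos[jj] - pos[ii]
                if d > max_dist:
                    break
                b = int((d - 1) // bin_size)
                r2 = pairwise_r2(matrix.dosage[:, sel[ii]], matrix.dosage[:, sel[jj]])
                if np.isnan(r2):
                    skipped[b] += 1
                else:
                    sums[b] += r2
                    counts[b] += 1
    lows = np.arange(n_bins) * bin_size + 1
    highs = np.minimum((np.arange(n_bins) + 1) * bin_size, max_dist)
    return pd.DataFrame(
        {
            "bin_low": lows,
            "bin_high": highs,
            "bin_mid": (lows + highs) / 2.0,
            "mean_r2": np.where(counts > 0, sums / np.maximum(counts, 1), np.nan),
            "n_pairs": counts,
            "n_skipped": skipped,
        }
    )


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained site indices.

    Within each window of ``window`` consecutive SNPs (advancing by
    ``step``), every pair with r^2 > r2_max loses its later member
    (first-encountered kept); removal is global and permanent.  Undefined
    r^2 never triggers removal.
    """
    n = matrix.n_sites
    keep = np.ones(n, dtype=bool)
    if n == 0:
        return np.empty(0, dtype=np.intp)
    dosage = matrix.dosage
    start = 0
    while True:
        stop = min(start + window, n)
        live = [j for j in range(start, stop) if keep[j]]
        for a_i in range(len(live)):
            i = live[a_i]
            if not keep[i]:
                continue
            for b_i in range(a_i + 1, len(live)):
                j = live[b_i]
                if not keep[j]:
                    continue
                r2 = pairwise_r2(dosage[:, i], dosage[:, j])
                if not np.isnan(r2) and r2 > r2_max:
                    keep[j] = False
        if stop >= n:
            break
        start += step
    return np.where(keep)[0].astype(np.intp)
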