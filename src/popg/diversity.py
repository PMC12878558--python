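"""Missing-data-aware windowed diversity and divergence statistics.

All estimators are "all-sites" style: numerators and denominators are
counted per site and aggregated as ratios of sums over each window, so
invariant sites enter the denominators and missing genotypes shrink them.
Windows are fixed-width, 1-based inclusive ``[k*W+1, (k+1)*W]`` per contig.
Undefined values (no comparable sites, S = 0 for Tajima's D) are NaN,
never 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from popg.variants import GenotypeMatrix, MISSING, VariantTable

__all__ = [
    "windowed_pi",
    "windowed_theta_tajd",
    "windowed_dxy_fst",
    "sample_het_fis",
    "summarize_windows",
    "tajimas_d",
]

DEFAULT_WINDOW = 100_000


def _site_pair_counts(table: VariantTable, idx: np.ndarray):
    """Per-site within-population (n_diff, n_comp) allele-pair counts.

    At a site with ``k`` non-missing alleles of which ``a`` are alt,
    ``n_comp = k(k-1)/2`` and ``n_diff = a(k-a)``.
    """
    ac, an = table.allele_counts(idx)
    n_comp = an * (an - 1) // 2
    n_diff = ac * (an - ac)
    return n_diff, n_comp, ac, an


def _window_frame(table: VariantTable, window: int):
    """Window id per site plus the frame skeleton (contig/start/end)."""
    win = (table.pos - 1) // window
    # unique (contig, window) pairs in order of appearance
    key = table.contig_idx.astype(np.int64) * (2**32) + win
    uniq, inverse = np.unique(key, return_inverse=True)
    contig_names = np.asarray(table.contig_names, dtype=object)
    u_contig = contig_names[(uniq // (2**32)).astype(np.int64)]
    u_win = uniq % (2**32)
    frame = pd.DataFrame(
        {
            "contig": u_contig,
            "start": u_win * window + 1,
            "end": (u_win + 1) * window,
        }
    )
    return inverse, frame


def _pop_index(table: VariantTable, population) -> np.ndarray:
    if population is None:
        return np.arange(table.n_samples)
    names = list(population)
    if not names:
        raise ValueError("population has no samples")
    return table.sample_index(names)


def windowed_pi(
    table: VariantTable,
    population: list[str] | None = None,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Windowed nucleotide diversity pi for one population.

    pi per window = sum(n_diff) / sum(n_comp) over sites in the window;
    invariant sites contribute comparisons with zero differences.
    Columns: contig, start, end, pi, n_sites (sites with >= 1 comparable
    pair), n_snps, n_diff, n_comp.
    """
    idx = _pop_index(table, population)
    n_diff, n_comp, ac, an = _site_pair_counts(table, idx)
    inverse, frame = _window_frame(table, window)
    nw = len(frame)
    sum_diff = np.bincount(inverse, weights=n_diff, minlength=nw)
    sum_comp = np.bincount(inverse, weights=n_comp, minlength=nw)
    seg = (ac > 0) & (ac < an)
    frame["pi"] = np.where(sum_comp > 0, sum_diff / np.where(sum_comp > 0, sum_comp, 1), np.nan)
    frame["n_sites"] = np.bincount(inverse, weights=(n_comp > 0), minlength=nw).astype(int)
    frame["n_snps"] = np.bincount(inverse, weights=seg, minlength=nw).astype(int)
    frame["n_diff"] = sum_diff
    frame["n_comp"] = sum_comp
    return frame


def _harmonic(k: np.ndarray | float) -> np.ndarray:
    """a_k = sum_{j=1}^{k-1} 1/j, supporting non-integer k via interpolation."""
    k = np.asarray(k, dtype=np.float64)
    out = np.zeros_like(k)
    kk = np.floor(k).astype(int)
    maxk = int(kk.max(initial=1))
    table = np.concatenate([[0.0, 0.0], np.cumsum(1.0 / np.arange(1, maxk))])
    frac = k - kk
    lo = table[np.clip(kk, 0, maxk)]
    hi = np.where(kk >= 1, lo + 1.0 / np.maximum(kk, 1), lo)
    return lo + frac * (hi - lo)


def tajimas_d(pi_sum: float, S: int, n: float) -> float:
    """Tajima's (1989) D from summed per-site pi, S and sample size n.

    ``n`` may be fractional (harmonic-mean allele count under missingness).
    Returns NaN when S = 0 or n < 2.
    """
    if S == 0 or n < 2:
        return float("nan")
    a1 = float(_harmonic(n))
    a2 = float(np.sum(1.0 / np.arange(1, int(np.floor(n))) ** 2)) if n >= 2 else 0.0
    # fractional tail for a2 (same linear interpolation as a1)
    nf = int(np.floor(n))
    if n > nf and nf >= 1:
        a2 += (n - nf) / nf**2
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - S / a1) / np.sqrt(var)


def windowed_theta_tajd(
    table: VariantTable,
    population: list[str] | None = None,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Watterson's theta and Tajima's D per window.

    theta per window = sum over segregating sites of 1/a_{k_i}, divided by
    the count of comparable sites (>= 2 non-missing alleles).  Tajima's D
    uses summed per-site pi and S with the harmonic-mean allele count of
    the window's segregating sites; NaN when S = 0.
    """
    idx = _pop_index(table, population)
    n_diff, n_comp, ac, an = _site_pair_counts(table, idx)
    inverse, frame = _window_frame(table, window)
    nw = len(frame)

    comparable = an >= 2
    seg = (ac > 0) & (ac < an) & comparable
    inv_a = np.zeros(len(ac))
    inv_a[seg] = 1.0 / _harmonic(an[seg])
    n_cmp_sites = np.bincount(inverse, weights=comparable, minlength=nw)
    theta_sum = np.bincount(inverse, weights=inv_a, minlength=nw)
    S = np.bincount(inverse, weights=seg, minlength=nw).astype(int)

    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = np.where(n_comp > 0, n_diff / np.where(n_comp > 0, n_comp, 1), 0.0)
    pi_sum = np.bincount(inverse, weights=np.where(seg, pi_site, 0.0), minlength=nw)
    # harmonic mean of allele counts over segregating sites
    inv_an = np.bincount(
        inverse, weights=np.where(seg, 1.0 / np.maximum(an, 1), 0.0), minlength=nw
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        n_hat = np.where(inv_an > 0, S / np.where(inv_an > 0, inv_an, 1), np.nan)

    frame["theta"] = np.where(
        n_cmp_sites > 0, theta_sum / np.where(n_cmp_sites > 0, n_cmp_sites, 1), np.nan
    )
    frame["tajd"] = [
        tajimas_d(p, int(s), nh) if s > 0 and np.isfinite(nh) else float("nan")
        for p, s, nh in zip(pi_sum, S, n_hat)
    ]
    frame["S"] = S
    frame["n_sites"] = n_cmp_sites.astype(int)
    return frame


def windowed_dxy_fst(
    table: VariantTable,
    pop_a: list[str],
    pop_b: list[str],
    window: int = DEFAULT_WINDOW,
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Between-population divergence D_xy and F_ST per window.

    D_xy = sum over sites of between-population allele-pair differences over
    the between-population pair count (invariant sites included).  F_ST is
    the Hudson estimator aggregated ratio-of-sums over the window's
    segregating sites; ``estimator="wc"`` switches to Weir & Cockerham.
    """
    ia, ib = _pop_index(table, pop_a), _pop_index(table, pop_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both populations must be non-empty")
    ac1, an1 = table.allele_counts(ia)
    ac2, an2 = table.allele_counts(ib)

    dxy_num = ac1 * (an2 - ac2) + (an1 - ac1) * ac2
    dxy_den = an1 * an2

    usable = (an1 >= 2) & (an2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(an1 > 0, ac1 / np.where(an1 > 0, an1, 1), 0.0)
        p2 = np.where(an2 > 0, ac2 / np.where(an2 > 0, an2, 1), 0.0)
    poly = usable & ((ac1 > 0) | (ac2 > 0)) & ((ac1 < an1) | (ac2 < an2))

    if estimator == "hudson":
        with np.errstate(divide="ignore", invalid="ignore"):
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / np.maximum(an1 - 1, 1)
                - p2 * (1 - p2) / np.maximum(an2 - 1, 1)
            )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    elif estimator == "wc":
        num, den = _weir_cockerham_components(ac1, an1, ac2, an2)
    else:
        raise ValueError(f"unknown F_ST estimator {estimator!r}")
    num = np.where(poly, num, 0.0)
    den = np.where(poly, den, 0.0)

    inverse, frame = _window_frame(table, window)
    nw = len(frame)
    s_dxy_n = np.bincount(inverse, weights=dxy_num, minlength=nw)
    s_dxy_d = np.bincount(inverse, weights=dxy_den, minlength=nw)
    s_num = np.bincount(inverse, weights=num, minlength=nw)
    s_den = np.bincount(inverse, weights=den, minlength=nw)
    frame["dxy"] = np.where(s_dxy_d > 0, s_dxy_n / np.where(s_dxy_d > 0, s_dxy_d, 1), np.nan)
    frame["fst"] = np.where(s_den > 0, s_num / np.where(s_den > 0, s_den, 1), np.nan)
    frame["n_sites"] = np.bincount(inverse, weights=(dxy_den > 0), minlength=nw).astype(int)
    frame["n_snps"] = np.bincount(inverse, weights=poly, minlength=nw).astype(int)
    return frame


def _weir_cockerham_components(ac1, an1, ac2, an2):
    """Weir & Cockerham (1984) two-population a and a+b+c per site."""
    n1 = an1 / 2.0
    n2 = an2 / 2.0
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(an1 > 0, ac1 / np.maximum(an1, 1), 0.0)
        p2 = np.where(an2 > 0, ac2 / np.maximum(an2, 1), 0.0)
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        # no heterozygosity term (allele-count formulation, hbar = 0 variant)
        hbar = 0.0
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    return a, a + b + c


def summarize_windows(frame: pd.DataFrame, stats: list[str]) -> pd.DataFrame:
    """Genome-wide summary of windowed statistics.

    For ratio-of-sums statistics (pi, dxy, fst) the genome-wide value is
    recomputed from the summed components when available; the SE is always
    the SD across windows divided by sqrt(number of non-NaN windows).
    """
    rows = []
    for stat in stats:
        vals = frame[stat].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        n = int(ok.sum())
        if stat == "pi" and {"n_diff", "n_comp"}.issubset(frame.columns):
            comp = frame["n_comp"].sum()
            mean = frame["n_diff"].sum() / comp if comp > 0 else np.nan
        else:
            mean = float(np.nanmean(vals)) if n else np.nan
        se = float(np.nanstd(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"stat": stat, "mean": mean, "se": se, "n_windows": n})
    return pd.DataFrame(rows)


def sample_het_fis(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample observed heterozygosity and inbreeding coefficient F_IS.

    Het = heterozygous / non-missing calls over variant sites.  F_IS =
    1 - O_het / E_het, with E_het summed over the sample's non-missing
    sites using cohort allele frequencies and the small-sample correction
    ``2 p q * k/(k-1)`` (k = non-missing allele count at the site).
    Samples with no calls get NaN for both.
    """
    dos = matrix.dosage
    called = dos != MISSING
    an = 2 * called.sum(axis=0)
    ac = np.where(called, dos, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        corr = np.where(an > 1, an / np.maximum(an - 1, 1), np.nan)
    e_het_site = 2.0 * p * (1.0 - p) * corr

    rows = []
    for i, s in enumerate(matrix.samples):
        ok = called[i] & np.isfinite(e_het_site)
        n_called = int(ok.sum())
        if n_called == 0:
            rows.append({"sample": s, "het": np.nan, "fis": np.nan, "n_sites": 0})
            continue
        o_het = float((dos[i, ok] == 1).sum())
        e_het = float(e_het_site[ok].sum())
        het = o_het / n_called
        fis = 1.0 - o_het / e_het if e_het > 0 else np.nan
        rows.append({"sample": s, "het": het, "fis": fis, "n_sites": n_called})
    df = pd.DataFrame(rows)
    return df
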