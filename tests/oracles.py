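"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the implementation paths it checks:
statistics are computed by explicit enumeration over alleles, pairs and
subsets, at small n, with no shared helper code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ----------------------------------------------------------------- diversity

def site_alleles(gt_codes, sample_idx):
    """Expand genotype codes to an explicit allele list for a population."""
    alleles = []
    for j in sample_idx:
        c = gt_codes[j]
        if c == -1:
            continue
        alleles.extend({0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(c)])
    return alleles


def brute_pi(gt_matrix, sample_idx):
    """(sum_diff, sum_comp) over sites by explicit pairwise allele loops."""
    total_diff = 0
    total_comp = 0
    for row in gt_matrix:
        alleles = site_alleles(row, sample_idx)
        for a, b in itertools.combinations(alleles, 2):
            total_comp += 1
            if a != b:
                total_diff += 1
    return total_diff, total_comp


def brute_dxy(gt_matrix, idx_a, idx_b):
    """(sum_diff, sum_comp) over between-population allele pairs."""
    total_diff = 0
    total_comp = 0
    for row in gt_matrix:
        aa = site_alleles(row, idx_a)
        bb = site_alleles(row, idx_b)
        for a in aa:
            for b in bb:
                total_comp += 1
                if a != b:
                    total_diff += 1
    return total_diff, total_comp


def tajima_d_reference(pi_sum, S, n):
    """Tajima (1989) D with the published constants; n may be fractional."""
    if S == 0 or n < 2:
        return float("nan")

    def harm(x, power):
        k = int(math.floor(x))
        s = sum(1.0 / j**power for j in range(1, k))
        if x > k and k >= 1:
            s += (x - k) / k**power
        return s

    a1 = harm(n, 1)
    a2 = harm(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - S / a1) / math.sqrt(var)


# ----------------------------------------------------------------- filtering

def brute_filter(sites, min_qual=20.0, ab=(0.25, 0.75), min_dp=3,
                 sd_mult=3.0, max_missing=0.10):
    """Reapply the filter cascade by direct per-site loops.

    ``sites`` is a list of dicts with keys: qual, variant (bool), and lists
    gt, dp, ad (tuples) per sample.  Returns indices of surviving sites.
    """
    # per-sample depth bounds from every observed DP
    n_samp = len(sites[0]["gt"])
    bounds = []
    for j in range(n_samp):
        dps = [s["dp"][j] for s in sites if s["dp"][j] >= 0]
        mean = sum(dps) / len(dps)
        var = sum((d - mean) ** 2 for d in dps) / len(dps)
        bounds.append(mean + sd_mult * math.sqrt(var))

    survivors = []
    for i, s in enumerate(sites):
        if s["variant"] and not math.isnan(s["qual"]) and s["qual"] < min_qual:
            continue
        gt = list(s["gt"])
        # allele balance masks het genotypes at variant sites
        if s["variant"]:
            for j in range(n_samp):
                if gt[j] == 1:
                    ar, aa = s["ad"][j]
                    tot = ar + aa
                    if ar < 0 or tot <= 0:
                        gt[j] = -1
                        continue
                    frac = aa / tot
                    if frac < ab[0] or frac > ab[1]:
                        gt[j] = -1
        # all-het variant sites removed
        called = [g for g in gt if g != -1]
        if s["variant"] and called and all(g == 1 for g in called):
            continue
        # depth masking
        for j in range(n_samp):
            d = s["dp"][j]
            if d >= 0 and (d < min_dp or d > bounds[j]):
                gt[j] = -1
        # missingness
        if sum(1 for g in gt if g == -1) / n_samp > max_missing:
            continue
        survivors.append(i)
    return survivors


# ----------------------------------------------------------------------- ROH

def brute_roh(genotypes, positions, min_snps=100, min_len=100_000,
              max_bp_per_snp=50_000):
    """All maximal homozygous runs (zero-het), checked one by one."""
    runs = []
    cur = []
    for g, p in zip(genotypes, positions):
        if g == -1:
            continue
        if g == 1:
            if cur:
                runs.append(cur)
            cur = []
        else:
            cur.append(p)
    if cur:
        runs.append(cur)
    out = []
    for run in runs:
        span = run[-1] - run[0] + 1
        n = len(run)
        if n >= min_snps and span >= min_len and span / n <= max_bp_per_snp:
            out.append((run[0], run[-1], n))
    return out


# ----------------------------------------------------------------------- SFS

def enumerate_projection(ac, an, n_proj):
    """P(i derived of n_proj) by enumeration of all subsampled allele draws."""
    alleles = [1] * ac + [0] * (an - ac)
    counts = np.zeros(n_proj + 1)
    total = 0
    for combo in itertools.combinations(range(an), n_proj):
        counts[sum(alleles[i] for i in combo)] += 1
        total += 1
    return counts / total


def brute_joint_sfs(gt_matrix, idx_a, idx_b, n1, n2):
    """Folded joint SFS by per-site enumeration of projections."""
    out = np.zeros((n1 + 1, n2 + 1))
    n_used = 0
    for row in gt_matrix:
        aa = site_alleles(row, idx_a)
        bb = site_alleles(row, idx_b)
        if len(aa) < n1 or len(bb) < n2:
            continue
        n_used += 1
        pa = enumerate_projection(sum(aa), len(aa), n1)
        pb = enumerate_projection(sum(bb), len(bb), n2)
        cell = np.outer(pa, pb)
        # fold
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                t = i + j
                if 2 * t < n1 + n2:
                    out[i, j] += cell[i, j]
                elif 2 * t > n1 + n2:
                    out[n1 - i, n2 - j] += cell[i, j]
                else:
                    out[i, j] += cell[i, j] / 2
                    out[n1 - i, n2 - j] += cell[i, j] / 2
    return out, n_used


# ------------------------------------------------------------------ distance

def brute_ibs(dosage):
    """Pairwise allele-sharing distances by explicit per-site scoring."""
    n = dosage.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = 0.0
            den = 0
            for k in range(dosage.shape[1]):
                a, b = dosage[i, k], dosage[j, k]
                if a == -1 or b == -1:
                    continue
                den += 1
                num += abs(int(a) - int(b)) / 2.0
            out[i, j] = out[j, i] = num / den if den else np.nan
    return out


def newick_patristic(newick, taxa):
    """Pairwise path distances in a Newick tree via scikit-bio."""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = dm[ids.index(taxa[i]), ids.index(taxa[j])]
    return out


# --------------------------------------------------------------- neutral SFS

def neutral_folded_sfs_weights(n):
    """Expected folded SFS shape for a constant-size population, n haploids.

    eta_i proportional to 1/i + 1/(n-i) for i < n/2 and to 1/i for the
    fold-axis class i = n/2 (even n); normalized to sum to 1.
    """
    w = []
    for i in range(1, n // 2 + 1):
        if 2 * i == n:
            w.append(1.0 / i)
        else:
            w.append(1.0 / i + 1.0 / (n - i))
    w = np.asarray(w)
    return w / w.sum()
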