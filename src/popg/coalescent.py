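"""Two-deme structured-coalescent simulator with infinite-sites mutation.

The engine simulates exact continuous-time genealogies for haploid lineages
sampled from two demes that merge into a single ancestral deme ``T_div``
generations in the past.  Before the merge, lineages coalesce within deme
``i`` at rate :math:`k_i(k_i-1)/2 \\cdot 1/(2 N_i)` per generation and hop
(backwards in time) from deme ``i`` to deme ``j`` at rate :math:`k_i m_{ij}`.
``T_div = 0`` collapses to a single panmictic population of size ``Ne_anc``.

Mutations are placed on branches as a Poisson process with rate
``mu * seq_length`` per generation and assigned uniform distinct positions
(infinite sites).  Diploid individuals are formed by random pairing of
haplotypes within a deme.  Loci are mutually independent and are laid out
end-to-end on synthetic contigs so windowed statistics and ROH have
genomic coordinates.

The per-genealogy kernels are compiled with numba; the same engine backs
both dataset generation and the expected-SFS computation used in
demographic fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from popg.variants import VariantTable

__all__ = ["SimulationConfig", "ConfigurationError", "simulate_coalescent_dataset"]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the two-deme isolation-with-migration simulation.

    Sizes are *diploid* effective sizes; ``m_12``/``m_21`` are backward
    per-generation migration probabilities (lineage now in deme 1 traces its
    ancestry to deme 2 at rate ``m_12``); ``mu`` is per site per generation.
    """

    n_samples_per_pop: int = 10
    Ne_anc: float = 5000.0
    Ne_1: float = 5000.0
    Ne_2: float = 5000.0
    T_div: float = 0.0
    m_12: float = 0.0
    m_21: float = 0.0
    mu: float = 1e-8
    seq_length: int = 10_000
    n_loci: int = 10
    loci_per_contig: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_pop <= 0:
            raise ConfigurationError("n_samples_per_pop must be > 0")
        for name in ("Ne_anc", "Ne_1", "Ne_2"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("m_12", "m_21"):
            m = getattr(self, name)
            if not (0.0 <= m < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if self.T_div < 0:
            raise ConfigurationError("T_div must be >= 0")
        if self.mu < 0:
            raise ConfigurationError("mu must be >= 0")
        if self.seq_length <= 0 or self.n_loci <= 0:
            raise ConfigurationError("seq_length and n_loci must be > 0")
        if self.loci_per_contig <= 0:
            raise ConfigurationError("loci_per_contig must be > 0")


@njit(cache=True)
def _seed_engine(seed):
    np.random.seed(seed)


@njit(cache=True)
def _sim_genealogy(n1, n2, ne1, ne2, ne_anc, t_div, m12, m21, parent, time):
    """Simulate one genealogy; fill parent/time arrays (size 2*(n1+n2)-1).

    Leaves 0..n1-1 sample deme 1, n1..n1+n2-1 deme 2.  Root has parent -1.
    Lineage slots are kept partitioned by deme (slots [0, k1) = deme 1,
    [k1, k) = deme 2) so every event is O(1) — heavy-migration histories
    would otherwise dominate the runtime.
    """
    n = n1 + n2
    active = np.empty(n, dtype=np.int64)
    for i in range(n):
        active[i] = i
        parent[i] = -1
        time[i] = 0.0
    for i in range(n, 2 * n - 1):
        parent[i] = -1
        time[i] = 0.0

    k = n
    k1 = n1
    t = 0.0
    nxt = n

    # island phase: two demes with migration, until t_div
    while k > 1 and t < t_div:
        k2 = k - k1
        rc1 = k1 * (k1 - 1) / 2.0 / (2.0 * ne1)
        rc2 = k2 * (k2 - 1) / 2.0 / (2.0 * ne2)
        rm1 = k1 * m12
        rm2 = k2 * m21
        total = rc1 + rc2 + rm1 + rm2
        if total <= 0.0:
            t = t_div
            break
        dt = np.random.exponential(1.0 / total)
        if t + dt >= t_div:
            t = t_div
            break
        t += dt
        u = np.random.random() * total
        if u < rc1 + rc2:
            # coalescence within deme d: slots [lo, lo+kd)
            if u < rc1:
                lo, kd = 0, k1
            else:
                lo, kd = k1, k2
            a = lo + np.random.randint(kd)
            b = lo + np.random.randint(kd - 1)
            if b >= a:
                b += 1
            node = nxt
            nxt += 1
            time[node] = t
            parent[active[a]] = node
            parent[active[b]] = node
            active[a] = node
            if u < rc1:
                # remove slot b from deme-1 block, shrink both blocks
                active[b] = active[k1 - 1]
                active[k1 - 1] = active[k - 1]
                k1 -= 1
            else:
                active[b] = active[k - 1]
            k -= 1
        elif u < rc1 + rc2 + rm1:
            # lineage hops deme 1 -> deme 2: swap to the boundary
            a = np.random.randint(k1)
            tmp = active[a]
            active[a] = active[k1 - 1]
            active[k1 - 1] = tmp
            k1 -= 1
        else:
            a = k1 + np.random.randint(k - k1)
            tmp = active[a]
            active[a] = active[k1]
            active[k1] = tmp
            k1 += 1

    # ancestral phase: single panmictic deme of size ne_anc
    while k > 1:
        rate = k * (k - 1) / 2.0 / (2.0 * ne_anc)
        t += np.random.exponential(1.0 / rate)
        a = np.random.randint(k)
        b = np.random.randint(k - 1)
        if b >= a:
            b += 1
        node = nxt
        nxt += 1
        time[node] = t
        parent[active[a]] = node
        parent[active[b]] = node
        active[a] = node
        active[b] = active[k - 1]
        k -= 1
    return nxt - 1  # root index


@njit(cache=True)
def _branch_config_lengths(n1, n2, ne1, ne2, ne_anc, t_div, m12, m21, n_sims):
    """Accumulate expected branch length per descendant configuration.

    Returns an ``(n1+1, n2+1)`` array: total branch length (summed over
    ``n_sims`` genealogies) carried by branches whose mutation would appear
    in ``i`` of the deme-1 and ``j`` of the deme-2 sampled haplotypes.
    """
    n = n1 + n2
    nn = 2 * n - 1
    parent = np.empty(nn, dtype=np.int64)
    time = np.empty(nn, dtype=np.float64)
    acc = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    d1 = np.empty(nn, dtype=np.int64)
    d2 = np.empty(nn, dtype=np.int64)
    for _ in range(n_sims):
        _sim_genealogy(n1, n2, ne1, ne2, ne_anc, t_div, m12, m21, parent, time)
        for i in range(nn):
            d1[i] = 1 if i < n1 else 0
            d2[i] = 1 if n1 <= i < n else 0
        # children precede parents in index order
        for i in range(nn):
            p = parent[i]
            if p >= 0:
                d1[p] += d1[i]
                d2[p] += d2[i]
                acc[d1[i], d2[i]] += time[p] - time[i]
    return acc


@njit(cache=True)
def _sim_dataset_kernel(n1, n2, ne1, ne2, ne_anc, t_div, m12, m21,
                        mu, L, n_loci, pairing, gt_out, var_out):
    """Simulate all loci, writing genotypes for mutated positions in place.

    ``gt_out`` is (n_loci * L, n_diploids) int8 zeros; row index is
    locus * L + (position - 1).  ``var_out`` marks mutated rows.
    """
    n = n1 + n2
    nn = 2 * n - 1
    n_dip = pairing.shape[0]
    parent = np.empty(nn, dtype=np.int64)
    time = np.empty(nn, dtype=np.float64)
    blen = np.empty(nn, dtype=np.float64)
    desc = np.zeros((nn, n), dtype=np.uint8)
    used = np.zeros(L, dtype=np.uint8)
    for locus in range(n_loci):
        _sim_genealogy(n1, n2, ne1, ne2, ne_anc, t_div, m12, m21,
                       parent, time)
        total = 0.0
        for i in range(nn):
            p = parent[i]
            blen[i] = time[p] - time[i] if p >= 0 else 0.0
            total += blen[i]
        lam = total * mu * L
        n_mut = np.random.poisson(lam) if lam > 0 else 0
        if n_mut == 0:
            continue
        if n_mut > L:
            n_mut = L
        # descendant indicator per branch (children precede parents)
        for i in range(nn):
            for j in range(n):
                desc[i, j] = 0
        for i in range(n):
            desc[i, i] = 1
        for i in range(nn):
            p = parent[i]
            if p >= 0:
                for j in range(n):
                    if desc[i, j]:
                        desc[p, j] = 1
        for pos in range(L):
            used[pos] = 0
        for _ in range(n_mut):
            # branch proportional to length
            r = np.random.random() * total
            cum = 0.0
            b = 0
            for i in range(nn):
                cum += blen[i]
                if r <= cum:
                    b = i
                    break
                if i == nn - 1:
                    b = i
            if b == nn - 1:  # float edge: never place mutations on the root
                b = nn - 2
            # infinite sites: distinct position within the locus
            while True:
                pos = np.random.randint(L)
                if used[pos] == 0:
                    used[pos] = 1
                    break
            row = locus * L + pos
            var_out[row] = True
            for d in range(n_dip):
                gt_out[row, d] = (
                    desc[b, pairing[d, 0]] + desc[b, pairing[d, 1]]
                )


@njit(cache=True)
def _branch_config_moments(n1, n2, ne1, ne2, ne_anc, t_div, m12, m21, n_sims):
    """Folded per-cell branch lengths: first and second moments.

    Accumulates, over ``n_sims`` genealogies, the per-genealogy *folded*
    cell lengths and their squares (plus total length and its square), so
    callers can estimate both the expected SFS and its Monte-Carlo
    variance per cell.
    """
    n = n1 + n2
    nn = 2 * n - 1
    parent = np.empty(nn, dtype=np.int64)
    time = np.empty(nn, dtype=np.float64)
    d1 = np.empty(nn, dtype=np.int64)
    d2 = np.empty(nn, dtype=np.int64)
    acc = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    acc2 = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    tmp = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    tot = 0.0
    tot2 = 0.0
    half = n1 + n2
    for _ in range(n_sims):
        _sim_genealogy(n1, n2, ne1, ne2, ne_anc, t_div, m12, m21, parent, time)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                tmp[i, j] = 0.0
        g_tot = 0.0
        for i in range(nn):
            d1[i] = 1 if i < n1 else 0
            d2[i] = 1 if n1 <= i < n else 0
        for i in range(nn):
            p = parent[i]
            if p >= 0:
                d1[p] += d1[i]
                d2[p] += d2[i]
                blen = time[p] - time[i]
                g_tot += blen
                a, b = d1[i], d2[i]
                t = a + b
                if 2 * t < half:
                    tmp[a, b] += blen
                elif 2 * t > half:
                    tmp[n1 - a, n2 - b] += blen
                else:
                    tmp[a, b] += 0.5 * blen
                    tmp[n1 - a, n2 - b] += 0.5 * blen
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                acc[i, j] += tmp[i, j]
                acc2[i, j] += tmp[i, j] * tmp[i, j]
        tot += g_tot
        tot2 += g_tot * g_tot
    return acc, acc2, tot, tot2


def _descendant_matrix(parent: np.ndarray, n_leaves: int) -> np.ndarray:
    """Boolean (n_nodes, n_leaves) matrix: leaf l descends from node r."""
    nn = len(parent)
    desc = np.zeros((nn, n_leaves), dtype=bool)
    desc[np.arange(n_leaves), np.arange(n_leaves)] = True
    for i in range(nn):
        p = parent[i]
        if p >= 0:
            desc[p] |= desc[i]
    return desc


def simulate_coalescent_dataset(config: SimulationConfig) -> VariantTable:
    """Simulate an all-sites diploid dataset under the two-deme model.

    Returns a :class:`VariantTable` covering every position of every locus
    (``seq_length * n_loci`` sites in total); positions without a mutation
    are invariant records.  Samples are named ``pop1_XX`` / ``pop2_XX`` and
    are diploids formed by random pairing of within-deme haplotypes.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    n_dip = config.n_samples_per_pop
    n1 = n2 = 2 * n_dip  # haploid sample sizes
    n = n1 + n2
    nn = 2 * n - 1

    _seed_engine(config.seed)
    rng = np.random.default_rng(config.seed)

    samples = [f"pop1_{i:02d}" for i in range(n_dip)] + [
        f"pop2_{i:02d}" for i in range(n_dip)
    ]

    # random haplotype pairing within each deme, fixed across loci
    pairing = np.concatenate(
        [rng.permutation(n1), n1 + rng.permutation(n2)]
    ).reshape(2 * n_dip, 2)

    L = config.seq_length
    n_contigs = -(-config.n_loci // config.loci_per_contig)
    contig_of_locus = np.arange(config.n_loci) // config.loci_per_contig
    offset_of_locus = (np.arange(config.n_loci) % config.loci_per_contig) * L
    loci_on_contig = np.bincount(contig_of_locus, minlength=n_contigs)
    contigs = {
        f"contig_{c:04d}": int(loci_on_contig[c] * L) for c in range(n_contigs)
    }

    total_sites = config.n_loci * L
    gt = np.zeros((total_sites, 2 * n_dip), dtype=np.int8)
    var_flag = np.zeros(total_sites, dtype=bool)
    if config.mu > 0:
        _sim_dataset_kernel(
            n1, n2,
            config.Ne_1, config.Ne_2, config.Ne_anc,
            config.T_div, config.m_12, config.m_21,
            config.mu, L, config.n_loci, pairing, gt, var_flag,
        )
    else:
        # still burn the genealogies so seeding semantics match mu > 0
        parent = np.empty(nn, dtype=np.int64)
        time = np.empty(nn, dtype=np.float64)
        for _ in range(config.n_loci):
            _sim_genealogy(
                n1, n2, config.Ne_1, config.Ne_2, config.Ne_anc,
                config.T_div, config.m_12, config.m_21, parent, time,
            )

    contig_idx = np.repeat(contig_of_locus, L).astype(np.int32)
    pos = (
        np.repeat(offset_of_locus, L)
        + np.tile(np.arange(1, L + 1, dtype=np.int64), config.n_loci)
    )
    alt = np.where(var_flag, "T", "")
    bases = np.array(["A", "C", "G", "T"])
    ref = bases[rng.integers(0, 4, size=total_sites)]
    ref[var_flag & (ref == "T")] = "A"

    table = VariantTable(
        samples=samples,
        contigs=contigs,
        contig_idx=contig_idx,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=np.full(total_sites, np.nan),
        gt=gt,
    )
    table.validate()
    return table


def expected_branch_sfs(
    n1: int,
    n2: int,
    Ne_1: float,
    Ne_2: float,
    Ne_anc: float,
    T_div: float,
    m_12: float,
    m_21: float,
    n_sims: int,
    seed: int,
) -> np.ndarray:
    """Monte-Carlo expected branch length per (deme1, deme2) derived count.

    Thin seeding wrapper around the numba kernel; returns the *mean* branch
    length per genealogy for each configuration cell, shape (n1+1, n2+1).
    """
    _seed_engine(seed)
    acc = _branch_config_lengths(
        n1, n2, Ne_1, Ne_2, Ne_anc, T_div, m_12, m_21, n_sims
    )
    return acc / n_sims
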