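import numpy as np
import pytest

from popg.variants import VariantTable


def make_table(gt, pos=None, contig_len=None, qual=None, variant=None,
               samples=None, dp=None, ad_ref=None, ad_alt=None, contigs=None,
               contig_idx=None):
    """Hand-build a small VariantTable from a genotype matrix (sites x samples)."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1)
    pos = np.asarray(pos, dtype=np.int64)
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    if variant is None:
        variant = np.array([bool((row > 0).any()) for row in gt])
    else:
        variant = np.asarray(variant, dtype=bool)
    alt = np.where(variant, "T", "").astype(object)
    ref = np.full(n_sites, "A", dtype=object)
    if qual is None:
        qual = np.full(n_sites, np.nan)
    if contigs is None:
        length = contig_len or int(pos.max())
        contigs = {"chr1": length}
        contig_idx = np.zeros(n_sites, dtype=np.int32)
    table = VariantTable(
        samples=list(samples),
        contigs=contigs,
        contig_idx=np.asarray(contig_idx, dtype=np.int32),
        pos=pos,
        ref=ref,
        alt=alt,
        qual=np.asarray(qual, dtype=np.float64),
        gt=gt,
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        ad_ref=None if ad_ref is None else np.asarray(ad_ref, dtype=np.int32),
        ad_alt=None if ad_alt is None else np.asarray(ad_alt, dtype=np.int32),
    )
    return table


def random_table(rng, n_sites=30, n_samples=6, p_invariant=0.4,
                 p_missing=0.1, with_depth=False):
    """Random small all-sites table for oracle-equality checks."""
    variant = rng.random(n_sites) > p_invariant
    gt = np.zeros((n_sites, n_samples), dtype=np.int8)
    for i in range(n_sites):
        if variant[i]:
            p = rng.uniform(0.05, 0.95)
            gt[i] = rng.binomial(2, p, size=n_samples).astype(np.int8)
    miss = rng.random((n_sites, n_samples)) < p_missing
    gt[miss] = -1
    # a "variant" flag requires an actual ALT column; keep sites labelled
    # variant even if the draw happened to be monomorphic
    kwargs = {}
    if with_depth:
        kwargs["dp"] = rng.poisson(20, size=(n_sites, n_samples)).astype(np.int32)
        ad_alt = np.zeros((n_sites, n_samples), dtype=np.int32)
        ad_ref = np.zeros((n_sites, n_samples), dtype=np.int32)
        het = gt == 1
        ad_alt[het] = rng.binomial(kwargs["dp"][het], 0.5)
        ad_ref[het] = kwargs["dp"][het] - ad_alt[het]
        ad_ref[gt == 0] = kwargs["dp"][gt == 0]
        ad_alt[gt == 2] = kwargs["dp"][gt == 2]
        kwargs["ad_ref"] = ad_ref
        kwargs["ad_alt"] = ad_alt
        kwargs["qual"] = rng.uniform(10, 90, size=n_sites)
    pos = np.sort(rng.choice(10 * n_sites, size=n_sites, replace=False)) + 1
    return make_table(gt, pos=pos, variant=variant, **kwargs)


@pytest.fixture(scope="session")
def two_pop_table():
    """Structured two-deme dataset shared across tests (deterministic)."""
    from popg.coalescent import SimulationConfig, simulate_coalescent_dataset

    cfg = SimulationConfig(
        n_samples_per_pop=8, Ne_anc=2000, Ne_1=2000, Ne_2=2000,
        T_div=4000, m_12=0.0, m_21=0.0, mu=5e-7,
        seq_length=2_000, n_loci=100, loci_per_contig=10, seed=42,
    )
    return simulate_coalescent_dataset(cfg)


@pytest.fixture(scope="session")
def panmictic_table():
    from popg.coalescent import SimulationConfig, simulate_coalescent_dataset

    # many short loci: with few shared genealogies even a panmictic sample
    # carries genealogical pseudo-structure that clustering methods find
    cfg = SimulationConfig(
        n_samples_per_pop=8, Ne_anc=2000, Ne_1=2000, Ne_2=2000,
        T_div=0.0, mu=5e-7, seq_length=1_000, n_loci=200,
        loci_per_contig=20, seed=43,
    )
    return simulate_coalescent_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
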