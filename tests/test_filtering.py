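"""Filter cascade: worked examples, brute-force oracle, properties."""

import math

import numpy as np
import pytest

import oracles
from conftest import make_table, random_table
from popg.filtering import FilterConfig, compute_depth_thresholds, filter_variants
from popg.variants import MISSING


def table_to_oracle_sites(t):
    sites = []
    variant = t.is_variant()
    for i in range(t.n_sites):
        sites.append(
            {
                "qual": float(t.qual[i]),
                "variant": bool(variant[i]),
                "gt": [int(g) for g in t.gt[i]],
                "dp": [int(d) for d in t.dp[i]],
                "ad": [
                    (int(t.ad_ref[i, j]), int(t.ad_alt[i, j]))
                    for j in range(t.n_samples)
                ],
            }
        )
    return sites


class TestDepthThresholds:
    def test_constant_depth_zero_sd(self):
        t = make_table([[0, 0]] * 5, dp=np.full((5, 2), 20),
                       ad_ref=np.full((5, 2), 20), ad_alt=np.zeros((5, 2)))
        bounds = compute_depth_thresholds(t)
        assert bounds.tolist() == [20.0, 20.0]

    def test_population_sd_convention(self):
        # DPs {10,20,30}: mean 20, population SD 8.1650, bound 44.495
        dp = np.array([[10, 5], [20, 5], [30, 5]])
        t = make_table([[0, 0]] * 3, dp=dp,
                       ad_ref=dp, ad_alt=np.zeros((3, 2)))
        bounds = compute_depth_thresholds(t)
        assert bounds[0] == pytest.approx(20 + 3 * 8.16496580927726, abs=1e-9)
        assert bounds[0] == pytest.approx(44.49489742783178, abs=1e-6)

    def test_single_site_sample(self):
        t = make_table([[0]], dp=[[7]], ad_ref=[[7]], ad_alt=[[0]])
        assert compute_depth_thresholds(t)[0] == 7.0

    def test_sample_without_dp_errors(self):
        t = make_table([[0, 0]], dp=[[5, -1]], ad_ref=[[5, 0]],
                       ad_alt=[[0, 0]])
        with pytest.raises(ValueError, match="s1"):
            compute_depth_thresholds(t)

    def test_above_bound_masked(self):
        # 100 sites at DP 20 and one at DP 30: bound ~ 23.1 < 30
        dp = np.full((101, 1), 20)
        dp[100, 0] = 30
        gt = np.zeros((101, 1), dtype=np.int8)
        gt[100, 0] = 2
        variant = [False] * 100 + [True]
        qual = [np.nan] * 100 + [50.0]
        t = make_table(gt, dp=dp, ad_ref=np.where(gt == 2, 0, dp),
                       ad_alt=np.where(gt == 2, 30, 0),
                       variant=variant, qual=qual)
        bounds = compute_depth_thresholds(t)
        mean = dp.mean()
        sd = math.sqrt(((dp - mean) ** 2).mean())
        assert bounds[0] == pytest.approx(mean + 3 * sd, rel=1e-9)
        out, rep = filter_variants(t, FilterConfig(max_site_missing=1.0))
        assert out.gt[100, 0] == MISSING  # DP 30 > bound
        assert rep.n_masked_depth == 1


class TestRules:
    def test_qual_removal(self):
        t = make_table([[1, 0], [1, 0]], qual=[10.0, 30.0],
                       variant=[True, True])
        out, rep = filter_variants(t, FilterConfig())
        assert rep.n_removed_qual == 1
        assert out.n_sites == 1

    def test_qual_not_applied_to_invariant(self):
        t = make_table([[0, 0]], qual=[5.0], variant=[False])
        out, rep = filter_variants(t, FilterConfig())
        assert out.n_sites == 1

    def test_allele_balance_masks_genotype(self):
        # het with AD=(2,8): alt fraction 0.8 > 0.75 -> masked
        # het with AD=(8,2): alt fraction 0.2 < 0.25 -> masked
        # het with AD=(5,5): kept
        gt = np.array([[1, 1, 1, 0]], dtype=np.int8)
        dp = np.full((1, 4), 10)
        ad_ref = np.array([[2, 8, 5, 10]])
        ad_alt = np.array([[8, 2, 5, 0]])
        t = make_table(gt, dp=dp, ad_ref=ad_ref, ad_alt=ad_alt,
                       qual=[50.0], variant=[True])
        out, rep = filter_variants(t, FilterConfig(max_site_missing=1.0))
        assert out.gt[0].tolist() == [MISSING, MISSING, 1, 0]
        assert rep.n_masked_ab == 2

    def test_ab_site_removal_mode(self):
        gt = np.array([[1, 0]], dtype=np.int8)
        t = make_table(gt, dp=np.full((1, 2), 10),
                       ad_ref=np.array([[9, 10]]), ad_alt=np.array([[1, 0]]),
                       qual=[50.0], variant=[True])
        out, rep = filter_variants(t, FilterConfig(ab_site_removal=True))
        assert out.n_sites == 0
        assert rep.n_removed_ab_site == 1

    def test_het_missing_ad_fails_conservatively(self):
        gt = np.array([[1, 0]], dtype=np.int8)
        t = make_table(gt, dp=np.full((1, 2), 10),
                       ad_ref=np.array([[-1, 10]]), ad_alt=np.array([[-1, 0]]),
                       qual=[50.0], variant=[True])
        out, rep = filter_variants(t, FilterConfig(max_site_missing=1.0))
        assert out.gt[0, 0] == MISSING
        assert rep.n_het_missing_ad == 1

    def test_all_het_site_removed(self):
        gt = np.vstack([np.ones((1, 10)), np.zeros((1, 10))]).astype(np.int8)
        t = make_table(gt, variant=[True, False])
        out, rep = filter_variants(t, FilterConfig())
        assert rep.n_removed_all_het == 1
        assert out.n_sites == 1

    def test_missingness_rule(self):
        # 40 samples, 5 missing -> 12.5% > 10% -> removed
        gt = np.zeros((1, 40), dtype=np.int8)
        gt[0, :5] = MISSING
        t = make_table(gt, variant=[False])
        out, rep = filter_variants(t, FilterConfig())
        assert out.n_sites == 0
        assert rep.n_removed_missing == 1
        # 4 of 40 = 10% exactly -> kept
        gt2 = np.zeros((1, 40), dtype=np.int8)
        gt2[0, :4] = MISSING
        out2, _ = filter_variants(make_table(gt2, variant=[False]),
                                  FilterConfig())
        assert out2.n_sites == 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_tables_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_sites=60, n_samples=8, with_depth=True,
                         p_missing=0.05)
        out, rep = filter_variants(t, FilterConfig())
        expected = oracles.brute_filter(table_to_oracle_sites(t))
        assert out.n_sites == len(expected)
        kept_pos = out.pos.tolist()
        assert kept_pos == t.pos[expected].tolist()

    def test_six_site_toy_table(self):
        # one site per rule plus two clean survivors
        gt = np.array(
            [
                [0, 1, 2, 0],   # clean variant
                [1, 0, 0, 0],   # low QUAL -> removed
                [1, 1, 1, 1],   # all het -> removed
                [1, 0, 2, 0],   # bad AB het at s0 -> masked, site kept
                [0, 0, 0, 0],   # clean invariant
                [2, 0, MISSING, MISSING],  # 50% missing -> removed
            ],
            dtype=np.int8,
        )
        dp = np.full((6, 4), 20)
        ad_alt = np.zeros((6, 4), dtype=int)
        ad_ref = np.zeros((6, 4), dtype=int)
        for i in range(6):
            for j in range(4):
                g = gt[i, j]
                if g == 1:
                    ad_alt[i, j] = 10
                    ad_ref[i, j] = 10
                elif g == 2:
                    ad_alt[i, j] = 20
                else:
                    ad_ref[i, j] = 20
        ad_alt[3, 0] = 19
        ad_ref[3, 0] = 1  # AB = 0.95
        qual = np.array([50.0, 10.0, 50.0, 50.0, np.nan, 50.0])
        variant = [True, True, True, True, False, True]
        t = make_table(gt, dp=dp, ad_ref=ad_ref, ad_alt=ad_alt,
                       qual=qual, variant=variant)
        out, rep = filter_variants(t, FilterConfig(max_site_missing=0.25))
        survivors = oracles.brute_filter(
            table_to_oracle_sites(t), max_missing=0.25
        )
        assert out.pos.tolist() == t.pos[survivors].tolist()
        assert rep.n_removed_qual == 1
        assert rep.n_removed_all_het == 1
        assert rep.n_masked_ab == 1
        assert rep.n_removed_missing == 1
        assert out.n_sites == 3


class TestProperties:
    def test_idempotence(self, rng):
        t = random_table(rng, n_sites=80, n_samples=10, with_depth=True)
        once, rep1 = filter_variants(t, FilterConfig())
        twice, rep2 = filter_variants(
            once, FilterConfig(),
            thresholds=np.array([rep1.depth_thresholds[s] for s in t.samples]),
        )
        assert np.array_equal(once.gt, twice.gt)
        assert once.n_sites == twice.n_sites

    def test_loosening_monotonicity(self, rng):
        t = random_table(rng, n_sites=80, n_samples=10, with_depth=True)
        strict, _ = filter_variants(t, FilterConfig())
        loose_cfgs = [
            FilterConfig(min_qual=0),
            FilterConfig(ab_low=0.1, ab_high=0.9),
            FilterConfig(min_dp=0, dp_sd_mult=100),
            FilterConfig(max_site_missing=0.5),
        ]
        for cfg in loose_cfgs:
            loose, _ = filter_variants(t, cfg)
            assert loose.n_sites >= strict.n_sites

    def test_counts_sum(self, rng):
        t = random_table(rng, n_sites=100, n_samples=10, with_depth=True)
        _, rep = filter_variants(t, FilterConfig())
        assert rep.n_input_sites == rep.n_retained_sites + rep.n_removed_sites
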