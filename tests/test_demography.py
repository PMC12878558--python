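import math

import numpy as np
import pytest

import oracles
from conftest import make_table
from popg.coalescent import SimulationConfig, simulate_coalescent_dataset
from popg.demography import (
    DemographicModel,
    JointSFS,
    aic,
    build_folded_joint_sfs,
    composite_log10_likelihood,
    delta_aic,
    effective_migration,
    expected_sfs,
    fit_model,
)


def gt_for_counts(ac_a, ac_b):
    """One-site table: 2 diploids per pop carrying the requested alt counts."""
    def dip(c):
        return {0: [0, 0], 1: [1, 0], 2: [1, 1], 3: [2, 1], 4: [2, 2]}[c]

    row = dip(ac_a) + dip(ac_b)
    return make_table(np.array([row], dtype=np.int8), variant=[True])


POP_A = ["s0", "s1"]
POP_B = ["s2", "s3"]


class TestJointSFS:
    def test_low_count_cell(self):
        t = gt_for_counts(1, 0)
        sfs = build_folded_joint_sfs(t, POP_A, POP_B, projection=(4, 4))
        assert sfs.counts[1, 0] == pytest.approx(1.0)

    def test_fold_high_counts(self):
        # derived counts (3, 4): total 7 of 8 > half -> folds to (1, 0)
        t = gt_for_counts(3, 4)
        sfs = build_folded_joint_sfs(t, POP_A, POP_B, projection=(4, 4))
        assert sfs.counts[1, 0] == pytest.approx(1.0)
        assert sfs.counts[3, 4] == 0.0

    def test_invariant_sites_fill_monomorphic_cell(self):
        gt = np.zeros((5, 4), dtype=np.int8)
        t = make_table(gt, variant=[False] * 5)
        sfs = build_folded_joint_sfs(t, POP_A, POP_B, projection=(4, 4))
        assert sfs.counts[0, 0] == pytest.approx(5.0)
        assert sfs.n_sites == 5.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gt = rng.choice([0, 1, 2, -1], size=(25, 8),
                        p=[0.35, 0.25, 0.3, 0.1]).astype(np.int8)
        t = make_table(gt, variant=[True] * 25)
        pa = [f"s{i}" for i in range(4)]
        pb = [f"s{i}" for i in range(4, 8)]
        sfs = build_folded_joint_sfs(t, pa, pb, projection=(5, 5))
        want, n_used = oracles.brute_joint_sfs(
            t.gt, np.arange(4), np.arange(4, 8), 5, 5
        )
        assert sfs.n_sites == n_used
        assert np.allclose(sfs.counts, want, atol=1e-9)

    def test_projection_too_large(self):
        t = gt_for_counts(1, 0)
        with pytest.raises(ValueError, match="excludes"):
            build_folded_joint_sfs(t, POP_A, POP_B, projection=(6, 6))

    def test_auto_projection_keeps_sites(self, two_pop_table):
        a = [s for s in two_pop_table.samples if s.startswith("pop1")]
        b = [s for s in two_pop_table.samples if s.startswith("pop2")]
        sfs = build_folded_joint_sfs(two_pop_table, a, b, keep_fraction=0.9)
        assert sfs.n_sites >= 0.9 * two_pop_table.n_sites


class TestExpectedSFS:
    def test_neutral_marginal_shape(self):
        # single population: folded total-count spectrum ~ 1/i + 1/(2n-i)
        model = DemographicModel(scenario="single", Ne_anc=2000, mu=1e-7)
        probs = expected_sfs(model, 6, 6, n_sims=40_000, seed=2)
        n = 12
        marg = np.zeros(n // 2 + 1)
        for i in range(7):
            for j in range(7):
                t = i + j
                if 0 < t <= n // 2:
                    marg[t] += probs[i, j]
        marg = marg[1:] / marg[1:].sum()
        want = oracles.neutral_folded_sfs_weights(n)
        assert np.allclose(marg, want, atol=0.01)

    def test_tdiv_zero_equals_single(self):
        single = DemographicModel(scenario="single", Ne_anc=3000, mu=1e-7)
        split = DemographicModel(
            scenario="split_isolation", Ne_anc=3000, Ne_1=3000, Ne_2=3000,
            T_div=1e-9, mu=1e-7,
        )
        p1 = expected_sfs(single, 5, 5, n_sims=30_000, seed=3)
        p2 = expected_sfs(split, 5, 5, n_sims=30_000, seed=3)
        assert np.allclose(p1, p2, atol=0.002)

    def test_high_migration_approaches_panmixia(self):
        def offdiag_deficit(m):
            model = DemographicModel(
                scenario="split_migration", Ne_anc=3000, Ne_1=3000,
                Ne_2=3000, T_div=50_000, m_12=m, m_21=m, mu=1e-7,
            )
            p = expected_sfs(model, 5, 5, n_sims=15_000, seed=4)
            shared = p[1:5, 1:5].sum()   # polymorphic in both demes
            private = p[1:, 0].sum() + p[0, 1:].sum()
            return shared / (shared + private)

        vals = [offdiag_deficit(m) for m in (0.0001, 0.01, 0.3)]
        assert vals[0] < vals[1] < vals[2]

    def test_probabilities_sum_to_one(self):
        model = DemographicModel(scenario="single", Ne_anc=1000, mu=1e-8)
        p = expected_sfs(model, 4, 4, n_sims=5000, seed=5)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_warns_on_tiny_n_sims(self):
        model = DemographicModel(scenario="single", Ne_anc=1000, mu=1e-8)
        with pytest.warns(UserWarning, match="noisy"):
            expected_sfs(model, 4, 4, n_sims=500, seed=6)


class TestCompositeLikelihood:
    def _sfs(self, counts):
        counts = np.asarray(counts, dtype=float)
        return JointSFS(
            n1=counts.shape[0] - 1, n2=counts.shape[1] - 1,
            counts=counts, n_sites=counts.sum(),
        )

    def test_worked_example(self):
        # O = {10, 90}, p = {0.1, 0.9}: L = -14.1182
        obs = self._sfs([[10.0], [90.0]])
        probs = np.array([[0.1], [0.9]])
        ll = composite_log10_likelihood(obs, probs)
        assert ll == pytest.approx(10 * math.log10(0.1) + 90 * math.log10(0.9),
                                   abs=1e-12)
        assert ll == pytest.approx(-14.1182, abs=1e-4)

    def test_gibbs_inequality(self, rng):
        counts = rng.integers(1, 50, size=(3, 3)).astype(float)
        obs = self._sfs(counts)
        p_match = counts / counts.sum()
        best = composite_log10_likelihood(obs, p_match)
        for _ in range(20):
            noise = rng.uniform(0.5, 2.0, size=counts.shape)
            p = p_match * noise
            p /= p.sum()
            assert composite_log10_likelihood(obs, p) <= best + 1e-12

    def test_zero_cell_floored(self):
        obs = self._sfs([[5.0], [5.0]])
        probs = np.array([[1.0], [0.0]])
        with pytest.warns(UserWarning, match="floor"):
            ll = composite_log10_likelihood(obs, probs)
        assert np.isfinite(ll)

    def test_negative_counts_rejected(self):
        sfs = self._sfs([[1.0], [1.0]])
        sfs.counts[0, 0] = -1
        with pytest.raises(ValueError):
            composite_log10_likelihood(sfs, np.array([[0.5], [0.5]]))


class TestAIC:
    def test_printed_formula(self):
        # k=6, MaxEstLhood=-23431: 12 + 2*23431/log10(e) = 107915.7
        got = aic(6, -23_431)
        assert got == pytest.approx(107_915.7, abs=0.05)

    def test_table_deltas(self):
        assert delta_aic([108_365, 107_928, 107_914]) == [451, 14, 0]

    def test_single_value(self):
        assert delta_aic([42.0]) == [0.0]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            delta_aic([])

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            aic(0, -1.0)

    def test_effective_migration(self):
        m = DemographicModel(
            scenario="split_migration", Ne_anc=17_209, Ne_1=64_156,
            Ne_2=32_181, T_div=434, m_12=0.0096, m_21=0.0094, mu=1e-7,
        )
        assert effective_migration(m) == pytest.approx(17_209 * 0.0096)
        assert effective_migration(m) >= 1.0


class TestModel:
    def test_single_forces_tdiv_zero(self):
        m = DemographicModel(scenario="single", Ne_anc=500, T_div=100,
                             m_12=0.01, mu=1e-8)
        assert m.T_div == 0.0
        assert m.m_12 == 0.0
        assert m.Ne_1 == m.Ne_anc
        assert m.k == 1

    def test_k_counts(self):
        assert DemographicModel(scenario="split_isolation", mu=1e-8).k == 4
        assert DemographicModel(scenario="split_migration", mu=1e-8).k == 6

    def test_invalid_scenario(self):
        with pytest.raises(ValueError):
            DemographicModel(scenario="bottleneck", mu=1e-8)


@pytest.fixture(scope="module")
def observed():
    cfg = SimulationConfig(
            n_samples_per_pop=5, Ne_anc=3000, Ne_1=3000, Ne_2=3000,
        T_div=0.0, mu=2e-7, seq_length=5000, n_loci=80, seed=51,
    )
    t = simulate_coalescent_dataset(cfg)
    a = [s for s in t.samples if s.startswith("pop1")]
    b = [s for s in t.samples if s.startswith("pop2")]
    return build_folded_joint_sfs(t, a, b, projection=(8, 8))


class TestFit:
    def test_deterministic(self, observed):
        a = fit_model(observed, "single", mu=2e-7, n_cycles=2, n_sims=3000,
                      seed=7)
        b = fit_model(observed, "single", mu=2e-7, n_cycles=2, n_sims=3000,
                      seed=7)
        assert a.model.Ne_anc == b.model.Ne_anc
        assert a.max_est_lhood == b.max_est_lhood

    def test_single_recovers_ne_scale(self, observed):
        fit = fit_model(observed, "single", mu=2e-7, n_cycles=8, n_sims=8000,
                        seed=8)
        assert 1000 < fit.model.Ne_anc < 9000  # truth 3000, factor ~3
        assert fit.k == 1
        assert fit.aic == pytest.approx(aic(1, fit.max_est_lhood))

    def test_likelihood_peaks_near_truth(self, observed):
        def ll(ne):
            model = DemographicModel(scenario="single", Ne_anc=ne, mu=2e-7)
            p = expected_sfs(model, 8, 8, n_sims=20_000, seed=9)
            return composite_log10_likelihood(observed, p)

        at_truth = ll(3000)
        assert at_truth > ll(3000 / 4)
        assert at_truth > ll(3000 * 4)
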