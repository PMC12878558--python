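import numpy as np
import pandas as pd
import pytest

import oracles
from popg.structure import (
    DistanceMatrix,
    allele_sharing_distance,
    haversine_km,
    haversine_matrix,
    ibs_distance,
    mrm,
    nj_tree,
    pca,
)
from popg.variants import GenotypeMatrix, MISSING, to_genotype_matrix


def matrix_from(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(dosage.shape[0])],
        dosage=dosage,
        contig=np.array(["c1"] * dosage.shape[1], dtype=object),
        pos=np.arange(1, dosage.shape[1] + 1),
    )


class TestPCA:
    def test_two_groups_pc1(self):
        dosage = np.vstack([np.zeros((4, 30)), np.full((4, 30), 2)])
        res = pca(matrix_from(dosage))
        assert res.explained[0] == pytest.approx(1.0)
        pc1 = res.scores[:, 0]
        assert (np.sign(pc1[:4]) != np.sign(pc1[4:])).all()

    def test_matches_eigendecomposition_oracle(self, rng):
        dosage = rng.binomial(2, 0.4, size=(12, 60)).astype(np.int8)
        res = pca(matrix_from(dosage), n_axes=12)
        x = dosage.astype(float) - dosage.mean(axis=0)
        cov = x @ x.T / (x.shape[0] - 1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.eigenvalues, evals[: len(res.eigenvalues)],
                           atol=1e-9)
        # scores reproduce the centred data's pairwise geometry
        got = res.scores @ res.scores.T
        assert np.allclose(got, x @ x.T, atol=1e-6)

    def test_explained_proportions_valid(self, rng):
        dosage = rng.binomial(2, 0.3, size=(10, 40)).astype(np.int8)
        res = pca(matrix_from(dosage))
        assert np.all(res.explained >= 0)
        assert np.all(np.diff(res.explained) <= 1e-12)
        assert res.explained.sum() <= 1 + 1e-9

    def test_missingness_filter_and_imputation(self, rng):
        dosage = rng.binomial(2, 0.4, size=(20, 50)).astype(np.int8)
        dosage[:, 0] = MISSING  # fully missing site must be dropped
        dosage[0, 1] = MISSING  # 5% missing: dropped at max_missing=0.01
        res = pca(matrix_from(dosage), max_missing=0.01)
        assert res.n_sites_used == 48

    def test_degenerate_all_identical(self):
        dosage = np.tile(np.array([0, 1, 2, 0, 1]), (6, 1))
        res = pca(matrix_from(dosage))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-18)
        assert np.allclose(res.scores, 0.0, atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pca(matrix_from(np.zeros((1, 5))))

    def test_sign_deterministic(self, rng):
        dosage = rng.binomial(2, 0.4, size=(10, 30)).astype(np.int8)
        a = pca(matrix_from(dosage))
        b = pca(matrix_from(dosage))
        assert np.array_equal(a.scores, b.scores)


class TestIBS:
    def test_identical_zero(self):
        d = np.tile([0, 1, 2], (2, 1))
        res = ibs_distance(matrix_from(d))
        assert res.values[0, 1] == 0.0

    def test_opposite_homozygotes(self):
        d = np.array([[0, 0, 0], [2, 2, 2]])
        assert ibs_distance(matrix_from(d)).values[0, 1] == 1.0

    def test_het_vs_hom(self):
        d = np.array([[1, 1, 1], [0, 0, 0]])
        assert ibs_distance(matrix_from(d)).values[0, 1] == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.choice([0, 1, 2, MISSING], size=(6, 40),
                       p=[0.4, 0.2, 0.3, 0.1]).astype(np.int8)
        got = ibs_distance(matrix_from(d)).values
        want = oracles.brute_ibs(d)
        assert np.allclose(got, want, atol=1e-12, equal_nan=True)


class TestHaversine:
    def test_same_point(self):
        assert haversine_km(50, 10, 50, 10) == 0.0

    def test_quarter_circle(self):
        # (0,0) to (0,90): R * pi/2 = 10007.54 km
        assert haversine_km(0, 0, 0, 90) == pytest.approx(10_007.54, abs=0.01)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = rng.uniform(-90, 90), rng.uniform(-180, 180)
            b = rng.uniform(-90, 90), rng.uniform(-180, 180)
            assert haversine_km(*a, *b) == pytest.approx(
                haversine_km(*b, *a), abs=1e-9
            )

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)
        with pytest.raises(ValueError):
            haversine_km(0, 181, 0, 0)

    def test_matrix(self):
        coords = pd.DataFrame(
            {"sample": ["a", "b"], "lat": [0.0, 0.0], "lon": [0.0, 90.0]}
        )
        dm = haversine_matrix(coords)
        dm.validate()
        assert dm.values[0, 1] == pytest.approx(10_007.54, abs=0.01)


class TestMRM:
    def _dm(self, values, samples):
        return DistanceMatrix(samples, values)

    def test_perfect_linear_response(self, rng):
        n = 12
        pts = rng.uniform(0, 100, size=n)
        pred = np.abs(pts[:, None] - pts[None, :])
        resp = 3.0 * pred + 1.0
        np.fill_diagonal(resp, 0)
        samples = [f"s{i}" for i in range(n)]
        res = mrm(self._dm(resp, samples), self._dm(pred, samples),
                  n_perm=199, seed=4)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.slope == pytest.approx(3.0, abs=1e-9)
        assert res.p_value == pytest.approx(1 / 200)

    def test_independent_response(self, rng):
        n = 15
        samples = [f"s{i}" for i in range(n)]
        high_p = 0
        for rep in range(20):
            a = rng.uniform(0, 1, size=(n, n))
            b = rng.uniform(0, 1, size=(n, n))
            a = (a + a.T) / 2
            b = (b + b.T) / 2
            np.fill_diagonal(a, 0)
            np.fill_diagonal(b, 0)
            res = mrm(self._dm(a, samples), self._dm(b, samples),
                      n_perm=99, seed=rep)
            if res.p_value > 0.05:
                high_p += 1
        assert high_p >= 16  # ~90% of replicates non-significant

    def test_relabelling_invariance(self, rng):
        n = 10
        samples = [f"s{i}" for i in range(n)]
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.uniform(0, 1, size=(n, n))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        r1 = mrm(self._dm(a, samples), self._dm(b, samples), n_perm=49, seed=1)
        perm = rng.permutation(n)
        a2 = a[np.ix_(perm, perm)]
        b2 = b[np.ix_(perm, perm)]
        s2 = [samples[i] for i in perm]
        r2 = mrm(self._dm(a2, s2), self._dm(b2, s2), n_perm=49, seed=1)
        assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-12)

    def test_mismatched_samples(self):
        a = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        b = DistanceMatrix(["a", "c"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            mrm(a, b)


class TestNJ:
    def test_exact_on_additive_four_taxa(self):
        # unrooted tree: ((A:2,B:3):1,(C:4,D:5)); additive distances
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        taxa = ["A", "B", "C", "D"]
        nwk = nj_tree(DistanceMatrix(taxa, d))
        got = oracles.newick_patristic(nwk, taxa)
        assert np.allclose(got, d, atol=1e-9)

    def test_random_additive_matrices(self, rng):
        pytest.importorskip("skbio")
        for rep in range(5):
            n = 7
            # build a random additive matrix from a random tree via skbio
            import io

            from skbio import TreeNode

            labels = [f"t{i}" for i in range(n)]
            # random binary tree newick with random branch lengths
            nodes = [f"{l}:{rng.uniform(0.5, 2):.4f}" for l in labels]
            while len(nodes) > 2:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False),
                              reverse=True)
                a = nodes.pop(i)
                b = nodes.pop(j)
                nodes.append(f"({a},{b}):{rng.uniform(0.5, 2):.4f}")
            nwk_true = f"({nodes[0]},{nodes[1]});"
            tree = TreeNode.read(io.StringIO(nwk_true))
            dm = tree.tip_tip_distances()
            ids = list(dm.ids)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    if i != j:
                        d[i, j] = dm[ids.index(labels[i]), ids.index(labels[j])]
            nwk = nj_tree(DistanceMatrix(labels, d))
            got = oracles.newick_patristic(nwk, labels)
            assert np.allclose(got, d, atol=1e-6)

    def test_three_taxa(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        nwk = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        got = oracles.newick_patristic(nwk, ["a", "b", "c"])
        assert np.allclose(got, d, atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_deep_split_monophyly(self, two_pop_table):
        pytest.importorskip("skbio")
        import io

        from skbio import TreeNode

        asd = allele_sharing_distance(two_pop_table)
        tree = TreeNode.read(io.StringIO(nj_tree(asd)))
        pop1 = {s for s in two_pop_table.samples if s.startswith("pop1")}

        def norm(name):  # newick readers turn unquoted underscores to spaces
            return name.replace(" ", "_")

        tips = {norm(t.name) for t in tree.tips()}
        found = False
        for node in tree.non_tips(include_self=False):
            clade = {norm(t.name) for t in node.tips()}
            if clade == pop1 or (tips - clade) == pop1:
                found = True
        assert found


class TestAlleleSharingDistance:
    def test_includes_invariant_sites(self, rng):
        from conftest import make_table

        gt = np.array([[0, 2], [0, 0], [0, 0], [0, 0]], dtype=np.int8)
        t = make_table(gt, variant=[True, False, False, False])
        d = allele_sharing_distance(t)
        # one full difference over 4 sites
        assert d.values[0, 1] == pytest.approx(0.25)
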