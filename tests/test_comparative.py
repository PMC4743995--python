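import numpy as np
import pandas as pd
import pytest

from osmo.comparative import (
    DistanceMatrix,
    cityblock_distances,
    distance_correlation_test,
    hierarchical_cluster,
    jukes_cantor_distances,
    jukes_cantor_pair,
    pca_scores,
)
from osmo.io import ValidationError
from osmo.simulate import (
    random_coalescent_tree,
    simulate_alignment,
    simulate_tree_structured_responses,
)


class TestPca:
    def test_rank_one_matrix_explained_by_first_component(self):
        x = np.outer([1.0, 2.0, 3.0], [1.0, -1.0, 0.5, 2.0])
        _, _, frac = pca_scores(pd.DataFrame(x))
        assert frac[0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(6, 10)))
        scores, loadings, _ = pca_scores(x)
        centered = x.to_numpy() - x.to_numpy().mean(axis=0)
        np.testing.assert_allclose(
            scores.to_numpy() @ loadings.to_numpy().T, centered, atol=1e-10
        )

    def test_explained_fractions_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 5))
        _, _, frac = pca_scores(pd.DataFrame(x))
        cov = np.cov(x - x.mean(axis=0), rowvar=False, ddof=1)
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(frac, ev / ev.sum(), atol=1e-10)

    def test_missing_values_treated_as_unchanged(self):
        x = pd.DataFrame([[1.0, np.nan], [-1.0, 0.0], [0.0, 0.0]])
        scores, _, _ = pca_scores(x)
        assert np.isfinite(scores.to_numpy()).all()

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            pca_scores(pd.DataFrame(np.zeros((3, 4))))


class TestCityblock:
    def test_hand_example(self):
        d = cityblock_distances(pd.DataFrame([[1.0, 2.0], [4.0, 6.0]]))
        assert d.values[0, 1] == pytest.approx(7.0)
        assert d.values[0, 0] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 20))
        d = cityblock_distances(pd.DataFrame(x))
        for i in range(10):
            for j in range(10):
                assert d.values[i, j] == pytest.approx(
                    np.abs(x[i] - x[j]).sum(), rel=1e-12
                )

    def test_pairwise_complete_over_missing(self):
        x = pd.DataFrame([[1.0, np.nan, 3.0], [2.0, 10.0, 5.0]])
        d = cityblock_distances(x)
        assert d.values[0, 1] == pytest.approx(1.0 + 2.0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(6)
        d = cityblock_distances(pd.DataFrame(rng.normal(size=(6, 12)))).values
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestHierarchicalCluster:
    def test_coincident_pair_merges_first(self):
        x = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]], index=["a", "b", "c"]
        )
        tree = hierarchical_cluster(cityblock_distances(x))
        a, b = int(tree.linkage[0, 0]), int(tree.linkage[0, 1])
        assert {tree.labels[a], tree.labels[b]} == {"a", "b"}
        assert tree.linkage[0, 2] == 0.0

    def test_ultrametric_input_reproduced_exactly(self):
        labels = ["a", "b", "c", "d"]
        m = np.array(
            [
                [0.0, 2.0, 8.0, 8.0],
                [2.0, 0.0, 8.0, 8.0],
                [8.0, 8.0, 0.0, 4.0],
                [8.0, 8.0, 4.0, 0.0],
            ]
        )
        d = DistanceMatrix(labels, m)
        tree = hierarchical_cluster(d, linkage="average")
        np.testing.assert_allclose(tree.cophenetic().values, m, atol=1e-12)

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(7, 9))
        labels = [f"s{i}" for i in range(7)]
        d1 = cityblock_distances(pd.DataFrame(x, index=labels))
        perm = rng.permutation(7)
        d2 = cityblock_distances(pd.DataFrame(x[perm], index=[labels[i] for i in perm]))
        c1 = pd.DataFrame(
            hierarchical_cluster(d1).cophenetic().values, index=labels, columns=labels
        )
        t2 = hierarchical_cluster(d2)
        c2 = pd.DataFrame(
            t2.cophenetic().values, index=t2.labels, columns=t2.labels
        ).loc[labels, labels]
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-10)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(8)
        d = cityblock_distances(pd.DataFrame(rng.normal(size=(9, 5))))
        tree = hierarchical_cluster(d)
        assert (np.diff(tree.merge_heights()) >= -1e-12).all()

    def test_newick_roundtrip_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(6)]
        d = cityblock_distances(pd.DataFrame(rng.normal(size=(6, 8)), index=labels))
        tree = hierarchical_cluster(d)
        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in dt.leaf_node_iter()} == set(labels)
        # leaf-to-leaf path length equals the cophenetic distance
        pdm = dt.phylogenetic_distance_matrix()
        coph = tree.cophenetic().to_frame()
        for t1 in dt.taxon_namespace:
            for t2 in dt.taxon_namespace:
                if t1 is t2:
                    continue
                assert pdm.patristic_distance(t1, t2) == pytest.approx(
                    coph.loc[t1.label, t2.label], rel=1e-6
                )


class TestJukesCantor:
    def test_identical_sequences(self):
        assert jukes_cantor_pair("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p_03(self):
        # 3 mismatches over 10 comparable columns = p 0.3
        a = "AAAAAAAAAA"
        b = "CCCAAAAAAA"
        assert jukes_cantor_pair(a, b) == pytest.approx(-0.75 * np.log(0.6), rel=1e-12)
        assert jukes_cantor_pair(a, b) == pytest.approx(0.3831, abs=5e-5)

    def test_saturation_flagged(self):
        aln = {"a": "AAAA", "b": "CCCA"}  # p = 0.75
        d = jukes_cantor_distances(aln)
        assert np.isnan(d.values[0, 1])
        assert ("a", "b") in d.undefined

    def test_gap_columns_excluded(self):
        a = "AA--AAAAAA"
        b = "CC--AAAAAA"  # p = 2/8
        expected = -0.75 * np.log(1 - 4 * 0.25 / 3)
        assert jukes_cantor_pair(a, b) == pytest.approx(expected, rel=1e-12)

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValidationError):
            jukes_cantor_pair("--AA", "AA--")

    def test_estimator_consistency_on_simulated_alignment(self):
        tree = random_coalescent_tree([f"x{i}" for i in range(4)],
                                      np.random.default_rng(10), total_height=0.2)
        aln = simulate_alignment(tree, 40_000, seed=11)
        d = jukes_cantor_distances(aln)
        true_d = tree.leaf_distances()
        for (a, b), td in true_d.items():
            i, j = d.labels.index(a), d.labels.index(b)
            assert d.values[i, j] == pytest.approx(td, rel=0.08, abs=0.004)


class TestDistanceCorrelation:
    def _dist(self, rng, n=8, labels=None):
        x = rng.normal(size=(n, 12))
        return cityblock_distances(
            pd.DataFrame(x, index=labels or [f"s{i}" for i in range(n)])
        )

    def test_proportional_matrices_give_r_one(self):
        rng = np.random.default_rng(12)
        d1 = self._dist(rng)
        d2 = DistanceMatrix(d1.labels, 2.0 * d1.values)
        res = distance_correlation_test(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_perm < 0.05

    def test_upper_triangle_flatten_oracle(self):
        rng = np.random.default_rng(13)
        d1, d2 = self._dist(rng), self._dist(rng)
        res = distance_correlation_test(d1, d2, n_perm=9, seed=0)
        iu = np.triu_indices(len(d1.labels), 1)
        expected = np.corrcoef(d1.values[iu], d2.values[iu])[0, 1]
        assert res.r == pytest.approx(expected, rel=1e-12)

    def test_matches_scikit_bio_mantel(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel

        rng = np.random.default_rng(14)
        d1, d2 = self._dist(rng), self._dist(rng)
        res = distance_correlation_test(d1, d2, n_perm=999, seed=1)
        r_skbio, p_skbio, _ = mantel(
            SkbioDM(d1.values, ids=d1.labels),
            SkbioDM(d2.values, ids=d2.labels),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert res.r == pytest.approx(float(r_skbio), rel=1e-9)
        assert abs(res.p_perm - float(p_skbio)) < 0.12

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(15)
        d1 = self._dist(rng)
        d2 = self._dist(rng, labels=[f"z{i}" for i in range(8)])
        with pytest.raises(ValidationError):
            distance_correlation_test(d1, d2)

    def test_label_reordering_handled(self):
        rng = np.random.default_rng(16)
        d1 = self._dist(rng)
        perm = rng.permutation(len(d1.labels))
        d2 = DistanceMatrix(
            [d1.labels[i] for i in perm], 2.0 * d1.values[np.ix_(perm, perm)]
        )
        res = distance_correlation_test(d1, d2, n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0)


class TestTreeStructuredRecovery:
    def test_cladogram_close_to_true_tree(self):
        """Responses diverging along a known tree yield a cladogram closer
        to that tree than to random trees (Robinson-Foulds)."""
        import dendropy

        rng = np.random.default_rng(20)
        labels = [f"org{i}" for i in range(16)]
        tree = random_coalescent_tree(labels, rng)
        fc = simulate_tree_structured_responses(tree, 300, seed=21)
        clado = hierarchical_cluster(cityblock_distances(fc))

        tns = dendropy.TaxonNamespace()
        t_true = dendropy.Tree.get(
            data=tree.to_newick(), schema="newick", taxon_namespace=tns
        )
        t_est = dendropy.Tree.get(
            data=clado.to_newick(), schema="newick", taxon_namespace=tns
        )
        rf_est = dendropy.calculate.treecompare.symmetric_difference(t_true, t_est)
        rf_random = []
        for k in range(60):
            rnd = random_coalescent_tree(labels, rng)
            t_rnd = dendropy.Tree.get(
                data=rnd.to_newick(), schema="newick", taxon_namespace=tns
            )
            rf_random.append(
                dendropy.calculate.treecompare.symmetric_difference(t_true, t_rnd)
            )
        assert rf_est < np.percentile(rf_random, 5)

    def test_mantel_positive_on_tree_structured_responses(self):
        rng = np.random.default_rng(22)
        labels = [f"org{i}" for i in range(16)]
        tree = random_coalescent_tree(labels, rng)
        fc = simulate_tree_structured_responses(tree, 300, seed=23)
        d_met = cityblock_distances(fc)
        aln = simulate_alignment(tree, 3000, seed=24)
        d_phy = jukes_cantor_distances(aln)
        order = [d_phy.labels.index(lb) for lb in d_met.labels]
        d_phy = DistanceMatrix(
            list(d_met.labels), d_phy.values[np.ix_(order, order)]
        )
        res = distance_correlation_test(d_met, d_phy, n_perm=999, seed=25)
        assert res.r > 0
        assert res.p_perm < 0.05

    def test_organism_independent_responses_give_near_zero_r(self):
        rng = np.random.default_rng(26)
        labels = [f"org{i}" for i in range(16)]
        tree = random_coalescent_tree(labels, rng)
        rs = []
        for seed in range(8):
            fc = pd.DataFrame(
                np.random.default_rng(100 + seed).normal(size=(16, 300)), index=labels
            )
            d_met = cityblock_distances(fc)
            aln = simulate_alignment(tree, 2000, seed=seed)
            d_phy = jukes_cantor_distances(aln)
            order = [d_phy.labels.index(lb) for lb in d_met.labels]
            d_phy = DistanceMatrix(
                list(d_met.labels), d_phy.values[np.ix_(order, order)]
            )
            rs.append(distance_correlation_test(d_met, d_phy, n_perm=19, seed=seed).r)
        assert abs(np.mean(rs)) < 0.15
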