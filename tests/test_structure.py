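import numpy as np
import pandas as pd
import pytest

from germpop.diversity import mrd_pairwise
from germpop.panel import GenotypePanel, GroupLabels
from germpop.structure import (
    LikelihoodTable,
    MembershipMatrix,
    assignment_correspondence,
    evanno_delta_k,
    gmm_cluster,
    laplacian_components,
    pca_components,
    pcoa_from_distance,
    threshold_assign,
    tw_significant_components,
)
from .conftest import random_panel


class TestPCA:
    def test_rank_one_data_single_component(self):
        X = np.outer([0.0, 0.5, 1.0], np.ones(4))
        panel = GenotypePanel(["a", "b", "c"], [f"m{j}" for j in range(4)], X)
        res = pca_components(panel)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_variance_explained_sums_to_one(self):
        panel = random_panel(n_lines=15, n_markers=30, missing=0.0, seed=3)
        res = pca_components(panel)
        assert res.variance_explained.sum() == pytest.approx(1.0)

    def test_too_many_components_rejected(self):
        panel = random_panel(n_lines=5, n_markers=8, missing=0.0, seed=3)
        with pytest.raises(ValueError):
            pca_components(panel, n_components=6)


class TestPCoA:
    def test_all_zero_distances(self):
        from germpop.diversity import DistanceMatrix

        D = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa_from_distance(D)
        np.testing.assert_allclose(res.coordinates, 0.0, atol=1e-12)

    def test_two_points_recover_separation(self):
        from germpop.diversity import DistanceMatrix

        d = 0.37
        D = DistanceMatrix(["a", "b"], np.array([[0, d], [d, 0]]))
        res = pcoa_from_distance(D)
        sep = abs(res.coordinates[0, 0] - res.coordinates[1, 0])
        assert sep == pytest.approx(d)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_euclidean_distances_give_no_negative_eigenvalues(self):
        panel = random_panel(n_lines=20, n_markers=50, missing=0.0, seed=4)
        res = pcoa_from_distance(mrd_pairwise(panel))
        assert res.negative_eigenvalues.size == 0

    def test_duality_with_pca_on_complete_panels(self):
        # PCoA of MRD = PCA scores / sqrt(m), axis signs free
        panel = random_panel(n_lines=25, n_markers=60, missing=0.0, seed=5)
        m = panel.n_markers
        pca = pca_components(panel)
        pcoa = pcoa_from_distance(mrd_pairwise(panel))
        k = min(5, pcoa.n_components)
        for axis in range(k):
            a = pca.coordinates[:, axis] / np.sqrt(m)
            b = pcoa.coordinates[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8
        np.testing.assert_allclose(
            pca.variance_explained[:k], pcoa.variance_explained[:k], atol=1e-10
        )


class TestTracyWidom:
    def test_alpha_zero_counts_nothing(self):
        panel = random_panel(n_lines=30, n_markers=50, missing=0.0, seed=6)
        pca = pca_components(panel, scale="patterson")
        assert tw_significant_components(pca, 30, 50, alpha=0) == 0

    def test_diverged_panel_detected(self):
        rng = np.random.default_rng(7)
        blocks = []
        for p in (0.1, 0.9):
            blocks.append((rng.random((40, 80)) < p).astype(float))
        X = np.vstack(blocks)
        panel = GenotypePanel(
            [f"l{i}" for i in range(80)], [f"m{j}" for j in range(80)], X
        )
        pca = pca_components(panel, scale="patterson")
        assert tw_significant_components(pca, 80, 80, alpha=0.05) >= 1

    def test_requires_patterson_scaling(self):
        panel = random_panel(n_lines=20, n_markers=30, missing=0.0, seed=8)
        pca = pca_components(panel)
        with pytest.raises(ValueError, match="patterson"):
            tw_significant_components(pca, 20, 30, alpha=0.05)


class TestLaplacian:
    def test_disconnected_blocks_separated_exactly(self):
        # two internally identical blocks -> complete within-block graphs,
        # no cross edges; the leading lapvector is the block contrast
        rng = np.random.default_rng(9)
        base1 = (rng.random(40) < 0.5).astype(float)
        base2 = (rng.random(40) < 0.5).astype(float)
        noise = (rng.random((10, 40)) < 0.05).astype(float)
        X = np.vstack([np.abs(base1 - noise[:5]), np.abs(base2 - noise[5:])])
        panel = GenotypePanel(
            [f"l{i}" for i in range(10)], [f"m{j}" for j in range(40)], X
        )
        res = laplacian_components(panel, eps=0.5, n_components=3)
        v = res.coordinates[:, 0]
        assert res.eigenvalues[0] == pytest.approx(0.0, abs=1e-9)
        assert len(set(np.sign(v[:5]))) == 1 and len(set(np.sign(v[5:]))) == 1
        assert np.sign(v[0]) != np.sign(v[5])

    def test_empty_graph_rejected(self):
        panel = random_panel(n_lines=10, n_markers=30, missing=0.0, seed=10)
        with pytest.raises(ValueError, match="eps"):
            laplacian_components(panel, eps=1.0)


class TestGMM:
    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(11)
        X = np.vstack([
            rng.normal(-5, 0.1, size=(100, 2)),
            rng.normal(5, 0.1, size=(100, 2)),
        ])
        truth = GroupLabels([str(i) for i in range(200)], ["a"] * 100 + ["b"] * 100)
        best_k, members, _ = gmm_cluster(X, K_range=range(1, 6), seed=0)
        assert best_k == 2
        assigned = threshold_assign(members)
        assert assignment_correspondence(assigned, truth) == pytest.approx(1.0)

    def test_single_gaussian_prefers_k1(self):
        wins = 0
        for s in range(10):
            X = np.random.default_rng(s).normal(size=(200, 2))
            best_k, _, _ = gmm_cluster(X, K_range=range(1, 4), seed=s, restarts=3)
            wins += best_k == 1
        assert wins >= 9

    def test_membership_rows_sum_to_one(self):
        X = np.random.default_rng(12).normal(size=(50, 3))
        _, members, _ = gmm_cluster(X, K_range=[3], seed=0, restarts=3)
        np.testing.assert_allclose(members.probabilities.sum(axis=1), 1.0, atol=1e-8)

    def test_invariant_to_line_permutation(self):
        rng = np.random.default_rng(13)
        X = np.vstack([
            rng.normal(-3, 0.2, size=(40, 2)),
            rng.normal(3, 0.2, size=(40, 2)),
        ])
        ids = [str(i) for i in range(80)]
        perm = rng.permutation(80)
        _, m1, _ = gmm_cluster(X, K_range=[2], seed=0, line_ids=ids)
        _, m2, _ = gmm_cluster(X[perm], K_range=[2], seed=0,
                               line_ids=[ids[i] for i in perm])
        f1 = m1.to_frame().sort_index()
        f2 = m2.to_frame().sort_index()
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-6)


class TestEvanno:
    def test_hand_computed_example(self):
        table = LikelihoodTable(pd.DataFrame({
            "K": [1, 1, 2, 2, 3, 3],
            "replicate": [0, 1] * 3,
            "logL": [-1000, -1000, -800, -802, -795, -797],
        }))
        dk = evanno_delta_k(table)
        assert dk.loc[2] == pytest.approx(194 / np.sqrt(2), rel=1e-6)
        assert np.isnan(dk.loc[1]) and np.isnan(dk.loc[3])

    def test_linear_profile_gives_zero(self):
        rows = []
        for k in (1, 2, 3, 4):
            for r, eps in ((0, 0.5), (1, -0.5)):
                rows.append({"K": k, "replicate": r, "logL": -100.0 * k + eps})
        dk = evanno_delta_k(LikelihoodTable(pd.DataFrame(rows)))
        np.testing.assert_allclose(dk.loc[[2, 3]], 0.0, atol=1e-9)

    def test_two_k_values_rejected(self):
        table = LikelihoodTable(pd.DataFrame({
            "K": [1, 1, 2, 2], "replicate": [0, 1, 0, 1],
            "logL": [-10, -11, -9, -8],
        }))
        with pytest.raises(ValueError):
            evanno_delta_k(table)


class TestAssignment:
    def members(self, rows):
        return MembershipMatrix([str(i) for i in range(len(rows))], np.array(rows))

    def test_threshold_rules(self):
        m = self.members([[0.9, 0.1], [0.7, 0.3], [0.55, 0.45]])
        strict = threshold_assign(m, rule=0.8)
        assert strict.labels == ["G1", "unassigned", "unassigned"]
        maxrule = threshold_assign(m, rule="max")
        assert maxrule.labels == ["G1", "G1", "G1"]

    def test_tie_goes_unassigned(self):
        m = self.members([[0.5, 0.5]])
        assert threshold_assign(m).labels == ["unassigned"]

    def test_invalid_threshold_rejected(self):
        m = self.members([[1.0, 0.0]])
        with pytest.raises(ValueError):
            threshold_assign(m, rule=0.4)

    def test_relabeling_invariance(self):
        ids = ["a", "b", "c", "d"]
        x = GroupLabels(ids, ["1", "1", "2", "2"])
        y = GroupLabels(ids, ["2", "2", "1", "1"])
        assert assignment_correspondence(x, y) == pytest.approx(1.0)
        assert assignment_correspondence(x, x) == pytest.approx(1.0)

    def test_best_bijection_of_crossed_labels(self):
        ids = ["a", "b", "c", "d"]
        x = GroupLabels(ids, ["1", "1", "2", "2"])
        y = GroupLabels(ids, ["1", "2", "1", "2"])
        assert assignment_correspondence(x, y) == pytest.approx(0.5)

    def test_symmetry(self):
        ids = [str(i) for i in range(6)]
        x = GroupLabels(ids, ["1", "1", "1", "2", "2", "3"])
        y = GroupLabels(ids, ["a", "a", "b", "b", "b", "a"])
        assert assignment_correspondence(x, y) == pytest.approx(
            assignment_correspondence(y, x)
        )
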