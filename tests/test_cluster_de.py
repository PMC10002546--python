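import numpy as np
import pytest
from scipy import stats

from crossortho.cluster_de import (
    ClusterAssignment,
    DEParams,
    bh_adjust,
    build_knn_graph,
    cluster_graph,
    rank_markers,
    reduce_pca,
    renumber_labels,
    wilcoxon_rank_sum_p,
)
from crossortho.errors import PipelineError
from crossortho.qc_normalize import normalize_log, pearson_residuals, select_hvg
from crossortho.synthetic import SimulationConfig, generate_dataset
from conftest import make_counts
from _oracles import bh_stepup_reference, ranksum_exact_reference


class TestPCA:
    def test_collinear_cells_explained_by_first_component(self, rng):
        t = rng.normal(size=30)
        dense = np.outer(np.array([1.0, 2.0, -1.0]), t)  # genes × cells on a line
        nm = _as_layer(dense)
        emb = reduce_pca(nm, None, 2)
        var = emb.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_component_variances_non_increasing(self, rng):
        nm = _as_layer(rng.normal(size=(12, 40)))
        emb = reduce_pca(nm, None, 6)
        var = emb.var(axis=0)
        assert (np.diff(var) <= 1e-12).all()

    def test_total_variance_conserved_at_full_rank(self, rng):
        dense = rng.normal(size=(5, 20))
        nm = _as_layer(dense)
        emb = reduce_pca(nm, None, 5)
        centered = dense.T - dense.T.mean(axis=0)
        # independent route: eigenvalues of the covariance matrix
        eigvals = np.linalg.eigvalsh(np.cov(centered.T, bias=False))
        np.testing.assert_allclose(
            sorted(emb.var(axis=0, ddof=1)), sorted(eigvals), rtol=1e-9
        )

    def test_deterministic_sign_convention(self, rng):
        nm = _as_layer(rng.normal(size=(8, 25)))
        a = reduce_pca(nm, None, 4)
        b = reduce_pca(nm, None, 4)
        np.testing.assert_array_equal(a, b)

    def test_single_cell_is_degenerate(self):
        with pytest.raises(PipelineError):
            reduce_pca(_as_layer(np.ones((3, 1))), None, 2)


def _as_layer(dense):
    from crossortho.qc_normalize import NormalizedMatrix

    n_genes, n_cells = dense.shape
    return NormalizedMatrix(
        values=np.asarray(dense, dtype=float),
        layer="pearson_residual",
        species="t",
        gene_ids=[f"G{i}" for i in range(n_genes)],
        gene_symbols=[f"S{i}" for i in range(n_genes)],
        cell_barcodes=[f"B{i}" for i in range(n_cells)],
    )


class TestKnnGraph:
    def test_three_equidistant_cells_form_uniform_triangle(self):
        emb = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        g = build_knn_graph(emb, k=2)
        assert g.ecount() == 3
        assert len(set(np.round(g.es["weight"], 12))) == 1

    def test_separated_blobs_have_no_cross_edges(self, rng):
        a = rng.normal(size=(20, 3)) * 0.1
        b = rng.normal(size=(20, 3)) * 0.1 + 100.0
        g = build_knn_graph(np.vstack([a, b]), k=5)
        for e in g.es:
            assert (e.source < 20) == (e.target < 20)

    def test_graph_symmetric_and_self_loop_free(self, rng):
        g = build_knn_graph(rng.normal(size=(30, 4)), k=4)
        assert not g.is_directed()
        assert all(e.source != e.target for e in g.es)


class TestClusterGraph:
    def test_disconnected_cliques_recovered(self):
        import igraph as ig

        g1 = ig.Graph.Full(6)
        g2 = ig.Graph.Full(5)
        g = g1.disjoint_union(g2)
        g.es["weight"] = [1.0] * g.ecount()
        ca = cluster_graph(g, resolution=0.5, seed=0)
        assert ca.n_clusters == 2
        assert len(set(ca.cluster_of_cell[:6])) == 1
        assert len(set(ca.cluster_of_cell[6:])) == 1
        # renumbering: bigger clique first
        assert ca.cluster_of_cell[0] == 0

    def test_same_seed_identical_assignment(self, rng):
        g = build_knn_graph(rng.normal(size=(60, 5)), k=8)
        a = cluster_graph(g, 1.0, seed=42)
        b = cluster_graph(g, 1.0, seed=42)
        np.testing.assert_array_equal(a.cluster_of_cell, b.cluster_of_cell)

    def test_cluster_count_monotone_in_resolution_on_fixture(self):
        cfg = SimulationConfig(
            seed=4,
            n_species=1,
            species_names=("human",),
            K=4,
            G_shared=300,
            G_specific=0,
            species_specific_markers_per_type=0,
            cells_per_species=400,
            markers_per_type=10,
            marker_fold=3.0,
            high_mito_cell_fraction=0.0,
            ortholog_noise=0,
        )
        mats, _, truth = generate_dataset(cfg)
        m = mats[0]
        res = pearson_residuals(m)
        emb = reduce_pca(res, select_hvg(res, 300), 20)
        g = build_knn_graph(emb, 15)
        counts = [
            cluster_graph(g, r, seed=1).n_clusters for r in (0.1, 0.5, 1.0)
        ]
        assert counts == sorted(counts)
        # at the working resolution the planted structure is recovered
        ca = cluster_graph(g, 0.5, seed=1)
        from crossortho.pipeline import majority_vote_accuracy

        acc, _ = majority_vote_accuracy(ca, truth.true_type_of_cell["human"])
        assert acc >= 0.95


class TestRenumbering:
    def test_labels_ordered_by_size_then_first_index(self):
        raw = np.array([7, 7, 3, 3, 3, 9])
        np.testing.assert_array_equal(renumber_labels(raw), [1, 1, 0, 0, 0, 2])

    def test_size_tie_broken_by_first_cell(self):
        raw = np.array([5, 2, 5, 2])
        np.testing.assert_array_equal(renumber_labels(raw), [0, 1, 0, 1])


class TestWilcoxon:
    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n1 = int(rng.integers(2, 9))
            n2 = int(rng.integers(2, 9))
            # ties likely: small integer support
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
            assert wilcoxon_rank_sum_p(x, y) == pytest.approx(
                ranksum_exact_reference(x, y), abs=1e-12
            )

    def test_exact_path_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 9)))
            y = rng.normal(size=int(rng.integers(3, 9)))
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert wilcoxon_rank_sum_p(x, y) == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_path_tracks_scipy_large_samples(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(loc=0.5, size=70)
        ours = wilcoxon_rank_sum_p(x, y)
        ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert ours == pytest.approx(ref, rel=1e-10)


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.01, 0.04], [0.02, 0.04]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_q_at_least_p_and_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRankMarkers:
    def _two_cluster_layer(self, dense, split):
        nm = normalize_log(make_counts(dense))
        labels = np.array([0] * split + [1] * (dense.shape[1] - split))
        return nm, ClusterAssignment(labels)

    def test_exclusive_gene_tops_its_cluster(self, rng):
        dense = rng.integers(1, 4, size=(10, 40))
        dense[3, :20] = 12  # strongly up in cluster 0
        dense[3, 20:] = 0
        nm, ca = self._two_cluster_layer(dense, 20)
        de = rank_markers(nm, ca, DEParams())
        top = de[de["cluster"] == 0].iloc[0]
        assert top["gene_id"] == "G3"
        assert top["pct_in"] == 1.0 and top["pct_out"] == 0.0
        assert top["q_value"] < 0.01

    def test_identical_distributions_give_large_p(self):
        dense = np.tile(np.array([[0, 1, 2, 3, 0, 1, 2, 3]]), (2, 1))
        dense[1] = 1  # second gene constant so ≥2 genes exist
        nm, ca = self._two_cluster_layer(dense, 4)
        p = wilcoxon_rank_sum_p(
            nm.dense()[0, :4], nm.dense()[0, 4:]
        )
        assert p > 0.5

    def test_prefilter_drops_rare_flat_genes(self, rng):
        dense = np.zeros((3, 40), dtype=int)
        dense[0] = rng.integers(1, 5, 40)  # background gene
        dense[1, [0, 20]] = 1  # 5% detection both groups, tiny fold
        dense[2, :20] = 6  # real marker so output non-empty
        nm, ca = self._two_cluster_layer(dense, 20)
        de = rank_markers(nm, ca, DEParams(min_pct=0.10, min_logfc=0.25))
        assert "G1" not in set(de["gene_id"])

    def test_small_cluster_floor_enforced(self):
        dense = np.ones((4, 5), dtype=int)
        nm = normalize_log(make_counts(dense))
        ca = ClusterAssignment(np.array([0, 0, 0, 1, 1]))
        with pytest.raises(PipelineError, match="1"):
            rank_markers(nm, ca)

    def test_rows_sorted_by_cluster_then_q_then_fold(self, rng):
        dense = rng.integers(0, 6, size=(15, 60))
        dense[2, :30] += 8
        dense[5, 30:] += 8
        nm, ca = self._two_cluster_layer(dense, 30)
        de = rank_markers(nm, ca, DEParams(min_logfc=0.0))
        for c in (0, 1):
            sub = de[de["cluster"] == c]
            assert (np.diff(sub["q_value"]) >= -1e-15).all()
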