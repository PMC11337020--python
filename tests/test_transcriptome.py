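import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mfclone.errors import ConfigurationError
from mfclone.io import CountMatrix
from mfclone.transcriptome import (
    Embedding,
    choose_n_pcs,
    cluster_snn_louvain,
    embed_umap,
    log_normalize,
    regress_covariates,
    run_pca,
    score_gene_module,
    select_hvg,
)
from tests.conftest import random_count_matrix


def as_norm(rng, n_genes=40, n_cells=25):
    return log_normalize(random_count_matrix(rng, n_genes, n_cells))


class TestLogNormalize:
    def test_zero_count_maps_to_zero(self, rng):
        m = random_count_matrix(rng)
        norm = log_normalize(m)
        zero_mask = m.counts.toarray() == 0
        assert np.all(norm.x.toarray()[zero_mask] == 0)

    def test_scale_cancels_at_total_equal_to_scale_factor(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 10
        counts[1, 0] = 9990
        m = CountMatrix(["a", "b"], ["A", "B"], ["c-1"], sp.csr_matrix(counts), "s")
        norm = log_normalize(m, scale_factor=1e4)
        assert norm.x.toarray()[0, 0] == pytest.approx(np.log(11), abs=1e-12)

    def test_matches_dense_oracle(self, rng):
        m = random_count_matrix(rng, 60, 40)
        norm = log_normalize(m).dense()
        dense = m.counts.toarray()
        totals = dense.sum(axis=0)
        expected = np.log1p(dense / np.where(totals > 0, totals, 1) * 1e4)
        assert np.allclose(norm, expected, atol=1e-12)

    def test_zero_total_cell_gives_zero_column(self):
        counts = np.zeros((3, 2))
        counts[:, 0] = [1, 2, 3]
        m = CountMatrix(["a", "b", "c"], ["A", "B", "C"], ["c1-1", "c2-1"],
                        sp.csr_matrix(counts), "s")
        assert np.all(log_normalize(m).dense()[:, 1] == 0)


class TestScoreGeneModule:
    def test_zero_expression_set_scores_nonpositive(self, rng):
        m = random_count_matrix(rng, 50, 30)
        dense = m.counts.toarray()
        dense[:3] = 0  # the module genes are silent
        m = CountMatrix(m.gene_ids, m.gene_symbols, m.cell_barcodes,
                        sp.csr_matrix(dense), "s")
        norm = log_normalize(m)
        score = score_gene_module(norm, ["G0", "G1", "G2"], seed=0)
        assert (score <= 1e-12).all()

    def test_set_equal_to_pool_scores_near_zero(self, rng):
        norm = as_norm(rng, n_genes=10, n_cells=20)
        # single bin: every gene is its own control pool
        score = score_gene_module(norm, [f"G{i}" for i in range(10)], n_bins=1, seed=0)
        assert np.allclose(score, 0, atol=1e-10)

    def test_empty_intersection_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            score_gene_module(as_norm(rng), ["NOPE"], seed=0)

    def test_deterministic_given_seed(self, rng):
        norm = as_norm(rng)
        a = score_gene_module(norm, ["G0", "G1"], seed=3)
        b = score_gene_module(norm, ["G0", "G1"], seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_planted_cycling_cells_score_higher(self, small_cohort):
        data = small_cohort.samples["P1"]
        truth = small_cohort.truth.cells.set_index("barcode")
        norm = log_normalize(data.matrix)
        s_genes = [s for s in data.matrix.gene_symbols
                   if small_cohort.truth.genes.set_index("symbol").loc[s, "category"] == "cycle_s"]
        score = score_gene_module(norm, s_genes, seed=0)
        t = truth[truth.patient == "P1"]
        s_cells = score.loc[t.index[t.cycling == "S"]]
        rest = score.loc[t.index[t.cycling == "none"]]
        wins = np.mean([s > r for s in s_cells for r in rest.sample(40, random_state=0)])
        assert wins >= 0.95


class TestRegression:
    def test_zero_covariate_is_identity(self, rng):
        norm = as_norm(rng)
        covs = pd.DataFrame({"z": np.zeros(norm.n_cells)}, index=norm.cell_barcodes)
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_covariates(norm, covs)
        assert np.allclose(out.dense(), norm.dense(), atol=1e-10)

    def test_gene_linear_in_covariate_flattened(self, rng):
        norm = as_norm(rng, n_genes=5, n_cells=30)
        cov = rng.normal(size=30)
        dense = norm.dense()
        dense[0] = 2.0 + 3.0 * cov
        norm.x = dense
        out = regress_covariates(norm, pd.DataFrame({"c": cov}, index=norm.cell_barcodes))
        assert np.var(out.dense()[0]) < 1e-20
        # intercept added back: the flattened gene keeps its mean level
        assert out.dense()[0].mean() == pytest.approx(2.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        norm = as_norm(rng, n_genes=15, n_cells=40)
        covs = pd.DataFrame(
            {"a": rng.normal(size=40), "b": rng.normal(size=40)},
            index=norm.cell_barcodes,
        )
        out = regress_covariates(norm, covs).dense()
        X = np.column_stack([np.ones(40), covs["a"], covs["b"]])
        Y = norm.dense().T
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        expected = (Y - X @ beta + beta[0]).T
        assert np.allclose(out, expected, atol=1e-8)


class TestHVG:
    def test_constant_genes_never_selected(self, rng):
        norm = as_norm(rng, n_genes=30, n_cells=25)
        dense = norm.dense()
        dense[5] = 2.0  # constant expression across cells
        norm.x = dense
        with pytest.warns(UserWarning, match="variable genes"):
            hvg = select_hvg(norm, n=30)
        assert "G5" not in hvg

    def test_request_exceeding_genes_warns_and_returns_all_variable(self, rng):
        norm = as_norm(rng, n_genes=10)
        with pytest.warns(UserWarning, match="variable genes"):
            hvg = select_hvg(norm, n=50)
        assert len(hvg) <= 10

    def test_planted_high_dispersion_genes_rank_top(self, rng):
        # background with a realistic spread of mean expression, so bins mix
        # high-dispersion plants with low-dispersion genes of similar mean
        n_genes, n_cells = 400, 150
        mu = rng.lognormal(np.log(5), 1.0, n_genes)
        base = rng.poisson(mu[:, None], (n_genes, n_cells)).astype(float)
        hot = rng.choice(n_genes, 30, replace=False)
        on = rng.random((30, n_cells)) < 0.5
        base[hot] = np.where(on, rng.poisson(30.0, (30, n_cells)), 0)
        m = CountMatrix(
            [f"ID{i}" for i in range(n_genes)], [f"G{i}" for i in range(n_genes)],
            [f"c{i}-1" for i in range(n_cells)], sp.csr_matrix(base), "s",
        )
        hvg = select_hvg(log_normalize(m), n=150)
        assert set(f"G{i}" for i in hot) <= set(hvg)


class TestPCA:
    def test_rank_r_fixture_explains_all_variance(self, rng):
        r = 3
        loadings = rng.normal(size=(40, r))
        scores = rng.normal(size=(60, r))
        x = (loadings @ scores.T) * 0.5 + 5
        m_norm_like = log_normalize(random_count_matrix(rng, 40, 60))
        m_norm_like.x = x
        emb = run_pca(m_norm_like, [f"G{i}" for i in range(40)], n_pcs_max=10, clip=100)
        var = emb.variance_per_dim
        assert var[:r].sum() / var.sum() > 0.999

    def test_variance_non_increasing_and_loadings_shape(self, rng):
        norm = as_norm(rng, 30, 40)
        emb = run_pca(norm, [f"G{i}" for i in range(30)], n_pcs_max=10)
        assert np.all(np.diff(emb.variance_per_dim) <= 1e-10)
        assert emb.loadings.shape == (30, emb.n_dims)

    def test_elbow_at_constructed_knee(self):
        v = np.concatenate([np.linspace(100, 20, 17), np.full(20, 1.0)])
        assert choose_n_pcs(v, lo=1, hi=40) == 17

    def test_elbow_clamps_to_range(self):
        flat = np.linspace(100, 99, 40)  # featureless spectrum
        assert choose_n_pcs(flat) == 15
        knee40 = np.concatenate([np.linspace(500, 100, 40), np.full(10, 1.0)])
        assert choose_n_pcs(knee40) == 25


class TestClustering:
    def _blobs(self, rng, n=150, sep=25.0):
        a = rng.normal(0, 1, (n, 5))
        b = rng.normal(0, 1, (n, 5)) + sep
        coords = np.vstack([a, b])
        return Embedding(coords=coords, kind="PCA",
                         cell_barcodes=[f"c{i}" for i in range(2 * n)])

    def test_two_blobs_two_clusters(self, rng):
        emb = self._blobs(rng)
        labels = cluster_snn_louvain(emb, seed=0)
        assert labels.n_clusters == 2
        first = labels.labels.iloc[:150]
        second = labels.labels.iloc[150:]
        agreement = max(
            (first == 0).mean() + (second == 1).mean(),
            (first == 1).mean() + (second == 0).mean(),
        ) / 2
        assert agreement >= 0.99

    def test_identical_coordinates_single_cluster(self):
        emb = Embedding(coords=np.zeros((50, 3)), kind="PCA",
                        cell_barcodes=[f"c{i}" for i in range(50)])
        assert cluster_snn_louvain(emb, seed=0).n_clusters == 1

    def test_too_few_cells_single_cluster_with_warning(self):
        emb = Embedding(coords=np.random.default_rng(0).normal(size=(10, 3)),
                        kind="PCA", cell_barcodes=[f"c{i}" for i in range(10)])
        with pytest.warns(UserWarning):
            labels = cluster_snn_louvain(emb, n_neighbors=20, seed=0)
        assert labels.n_clusters == 1

    def test_deterministic_given_seed(self, rng):
        emb = self._blobs(rng, sep=4.0)
        a = cluster_snn_louvain(emb, seed=5).labels
        b = cluster_snn_louvain(emb, seed=5).labels
        assert (a == b).all()


class TestUMAP:
    def test_finite_and_deterministic(self, rng):
        coords = rng.normal(size=(40, 6))
        emb = Embedding(coords=coords, kind="PCA",
                        cell_barcodes=[f"c{i}" for i in range(40)])
        u1 = embed_umap(emb, seed=1)
        u2 = embed_umap(emb, seed=1)
        assert u1.coords.shape == (40, 2) and np.isfinite(u1.coords).all()
        assert np.array_equal(u1.coords, u2.coords)

    def test_blob_separation(self, rng):
        a = rng.normal(0, 1, (60, 5))
        b = rng.normal(0, 1, (60, 5)) + 20
        emb = Embedding(coords=np.vstack([a, b]), kind="PCA",
                        cell_barcodes=[f"c{i}" for i in range(120)])
        u = embed_umap(emb, seed=0).coords
        intra = np.linalg.norm(u[:60] - u[:60].mean(0), axis=1).mean()
        inter = np.linalg.norm(u[:60].mean(0) - u[60:].mean(0))
        assert inter > intra
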