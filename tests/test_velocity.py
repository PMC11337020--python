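import numpy as np
import pytest

from mfclone.errors import ConfigurationError, ContractError
from mfclone.transcriptome import Embedding
from mfclone.velocity import (
    VelocityModel,
    compute_velocity,
    embedding_displacement,
    fit_gamma,
    project_future,
    transition_distance,
    transition_distance_minmax,
    vector_field,
)


def make_embedding(loadings, center=None, scale=None, clip=100.0):
    g, k = loadings.shape
    return Embedding(
        coords=np.zeros((1, k)), kind="PCA", cell_barcodes=["c0"],
        loadings=loadings, genes=[f"G{i}" for i in range(g)],
        center=center if center is not None else np.zeros(g),
        scale=scale if scale is not None else np.ones(g),
        clip=clip,
    )


class TestFitGamma:
    def test_exact_line_recovers_slope(self, rng):
        s = rng.integers(1, 50, (1, 100)).astype(float)
        model = fit_gamma(s, 2.0 * s, min_cells_expressing=10)
        assert model.gamma[0] == pytest.approx(2.0, abs=1e-12)

    def test_zero_unspliced_gives_zero_gamma(self, rng):
        s = rng.integers(1, 50, (1, 100)).astype(float)
        model = fit_gamma(s, np.zeros_like(s), min_cells_expressing=10)
        assert model.gamma[0] == 0.0 and model.used[0]

    def test_sparse_gene_flagged_unused(self, rng):
        s = np.zeros((1, 100))
        s[0, :5] = 3
        model = fit_gamma(s, s * 0.5, min_cells_expressing=20)
        assert not model.used[0]

    def test_missing_layer_rejected(self):
        with pytest.raises(ConfigurationError, match="spliced"):
            fit_gamma(None, None)

    def test_steady_state_parameter_recovery(self, rng):
        n = 500
        s = rng.negative_binomial(2, 2 / (2 + 5.0), (1, n)).astype(float)
        u = rng.poisson(0.7 * s).astype(float)
        model = fit_gamma(s, u)
        assert model.gamma[0] == pytest.approx(0.7, abs=0.1)


class TestComputeVelocity:
    def test_cell_on_steady_state_line_has_zero_velocity(self):
        s = np.array([[1.0, 2.0, 4.0]])
        model = VelocityModel(gamma=np.array([0.5]), used=np.array([True]), fit_quantile=0.05)
        v = compute_velocity(s, 0.5 * s, model)
        assert np.allclose(v, 0)

    def test_sign_law(self):
        s = np.full((2, 4), 2.0)
        u = np.vstack([np.full(4, 3.0), np.full(4, 0.2)])  # induced / repressed
        model = VelocityModel(gamma=np.array([0.5, 0.5]), used=np.array([True, True]),
                              fit_quantile=0.05)
        v = compute_velocity(s, u, model)
        assert (v[0] > 0).all() and (v[1] < 0).all()

    def test_unused_genes_zeroed(self):
        s = np.ones((2, 3))
        u = np.ones((2, 3)) * 5
        model = VelocityModel(gamma=np.array([1.0, np.nan]),
                              used=np.array([True, False]), fit_quantile=0.05)
        v = compute_velocity(s, u, model)
        assert np.allclose(v[1], 0)

    def test_knn_smoothing_preserves_population_mean(self, rng):
        s = rng.random((3, 50)) * 5
        u = rng.random((3, 50)) * 5
        coords = rng.normal(size=(50, 2))
        model = VelocityModel(gamma=np.zeros(3), used=np.ones(3, bool), fit_quantile=0.05)
        v = compute_velocity(s, u, model, pc_coords=coords, k=10)
        assert v.mean() == pytest.approx(u.mean(), abs=0.2)


class TestProjectFuture:
    def test_zero_velocity_zero_delta(self, rng):
        loadings = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        emb = make_embedding(loadings)
        current = rng.random((6, 10))
        delta = project_future(emb, current, np.zeros_like(current))
        assert np.allclose(delta, 0, atol=1e-14)

    def test_velocity_along_first_loading_moves_only_pc1(self, rng):
        loadings = np.linalg.qr(rng.normal(size=(8, 3)))[0]
        emb = make_embedding(loadings)
        current = np.full((8, 5), 10.0)  # far from the floor at zero
        v = np.tile(loadings[:, [0]], (1, 5)) * 0.5
        delta = project_future(emb, current, v)
        assert np.all(np.abs(delta[:, 1:]) < 1e-10)
        assert np.all(delta[:, 0] > 0.4)

    def test_matches_dense_oracle(self, rng):
        loadings = np.linalg.qr(rng.normal(size=(10, 4)))[0]
        center, scale = rng.random(10), rng.random(10) + 0.5
        emb = make_embedding(loadings, center, scale)
        current = rng.random((10, 7)) * 5
        v = rng.normal(0, 0.3, (10, 7))
        delta = project_future(emb, current, v, dt=1.0)
        future = np.maximum(current + v, 0)
        z_now = (current - center[:, None]) / scale[:, None]
        z_fut = (future - center[:, None]) / scale[:, None]
        expected = z_fut.T @ loadings - z_now.T @ loadings
        assert np.allclose(delta, expected, atol=1e-10)

    def test_missing_loadings_rejected(self):
        emb = Embedding(coords=np.zeros((1, 2)), kind="UMAP", cell_barcodes=["c0"])
        with pytest.raises(ContractError):
            project_future(emb, np.zeros((3, 1)), np.zeros((3, 1)))


class TestTransitionDistance:
    def test_three_four_five_triangle(self):
        summary = transition_distance(np.array([[3.0, 4.0]]), ["c0"])
        assert summary.per_cell.td.iloc[0] == 5.0

    def test_constant_td_gives_zero_iqr(self):
        delta = np.tile([1.0, 1.0], (20, 1))
        s = transition_distance(delta, [f"c{i}" for i in range(20)])
        assert s.per_sample.iqr_td.iloc[0] == 0.0
        assert (s.per_cell.td_normalized == s.per_cell.td_normalized.iloc[0]).all()

    def test_all_static_defined_with_warning(self):
        with pytest.warns(UserWarning, match="0"):
            s = transition_distance(np.zeros((5, 2)), [f"c{i}" for i in range(5)])
        assert (s.per_cell.td_normalized == 0).all()

    def test_median_iqr_match_sort_based_oracle(self, rng):
        delta = rng.normal(size=(1000, 2))
        s = transition_distance(delta, [f"c{i}" for i in range(1000)])
        td = np.hypot(delta[:, 0], delta[:, 1])
        tn = np.sort((td - td.min()) / td.max())

        def q(sorted_vals, p):  # linear-interpolation quantile
            h = (len(sorted_vals) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        assert s.per_sample.median_td.iloc[0] == pytest.approx(q(tn, 0.5), abs=1e-12)
        assert s.per_sample.iqr_td.iloc[0] == pytest.approx(
            q(tn, 0.75) - q(tn, 0.25), abs=1e-12
        )

    def test_invariant_under_joint_rotation(self, rng):
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        delta = rng.normal(size=(200, 2))
        td0 = transition_distance(delta, [f"c{i}" for i in range(200)]).per_cell.td
        td1 = transition_distance(delta @ rot.T, [f"c{i}" for i in range(200)]).per_cell.td
        assert np.allclose(td0, td1, atol=1e-10)

    def test_normalized_in_unit_interval_when_min_zero(self, rng):
        delta = rng.normal(size=(100, 2))
        delta[0] = 0.0
        s = transition_distance(delta, [f"c{i}" for i in range(100)])
        tn = s.per_cell.td_normalized
        assert tn.min() >= 0 and tn.max() <= 1

    def test_printed_normalization_deviation_bounded_by_min_over_max(self, rng):
        td = rng.random(50) + 1.0
        delta = np.column_stack([td, np.zeros(50)])
        s = transition_distance(delta, [f"c{i}" for i in range(50)])
        strict = transition_distance_minmax(td)
        dev = np.abs(s.per_cell.td_normalized.to_numpy() - strict)
        assert dev.max() <= td.min() / td.max() + 1e-12

    def test_per_sample_grouping(self, rng):
        delta = rng.normal(size=(60, 2))
        import pandas as pd

        samples = pd.Series(["a"] * 30 + ["b"] * 30,
                            index=[f"c{i}" for i in range(60)])
        s = transition_distance(delta, [f"c{i}" for i in range(60)], samples)
        assert sorted(s.per_sample["sample"]) == ["a", "b"]
        assert (s.per_sample.n_cells == 30).all()


class TestVectorField:
    def test_zero_velocity_zero_arrows(self, rng):
        coords = rng.normal(size=(50, 2))
        arrows = vector_field(coords, np.zeros((50, 2)), grid=5)
        assert np.allclose(arrows[["dx", "dy"]], 0)

    def test_uniform_translation_gives_coherent_arrows(self, rng):
        coords = rng.normal(size=(100, 2))
        disp = np.tile([1.0, 0.5], (100, 1))
        arrows = vector_field(coords, disp, grid=6)
        vecs = arrows[["dx", "dy"]].to_numpy()
        norms = np.linalg.norm(vecs, axis=1)
        unit = vecs[norms > 1e-6] / norms[norms > 1e-6, None]
        cos = unit @ unit.T
        assert cos[np.triu_indices_from(cos, 1)].mean() > 0.9

    def test_far_grid_cells_emit_no_arrow(self, rng):
        coords = np.vstack([rng.normal(0, 0.1, (30, 2)),
                            rng.normal(0, 0.1, (30, 2)) + 100])
        arrows = vector_field(coords, np.ones((60, 2)), grid=20)
        assert len(arrows) < 20 * 20  # the empty middle emits nothing


def test_embedding_displacement_follows_velocity_direction(rng):
    # cells on a 2-D lattice whose expression mirrors their position
    grid = np.array([[i, j] for i in range(8) for j in range(8)], dtype=float)
    expression = np.vstack([grid[:, 0], grid[:, 1], np.ones(64)])
    velocity = np.zeros_like(expression)
    velocity[0] = 1.0  # moving along the first expression axis = +x
    disp = embedding_displacement(grid, expression, velocity, k=8)
    inner = disp[(grid[:, 0] > 0) & (grid[:, 0] < 7)]
    assert inner[:, 0].mean() > 0.5 * np.abs(inner[:, 1]).mean()
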