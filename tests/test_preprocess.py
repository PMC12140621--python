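"""Graph construction: HVG selection, PCA, neighbor heuristic, KNN layers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spotsbm import (
    ExpressionMatrix,
    PreprocessConfig,
    SpatialCoords,
    build_multilayer,
    default_neighbors,
    knn_graph,
    pca_embed,
    select_hvg,
)

RAW = PreprocessConfig(normalize=False, log1p=False, scale=False)


class TestSelectHVG:
    def test_returns_all_genes_when_n_top_exceeds_count(self, toy_expression):
        out = select_hvg(toy_expression, n_top=50)
        assert out.n_genes == toy_expression.n_genes
        assert set(out.gene_ids) == set(toy_expression.gene_ids)

    def test_picks_highest_variance_genes_in_order(self):
        # per-gene variances (0.1, 4.0, 2.0) on raw values
        counts = np.array(
            [[1.0, 0.0, 0.0], [1.2, 4.0, 1.0], [1.4, 0.0, 3.0], [1.6, 4.0, 2.0]]
        )
        expr = ExpressionMatrix(counts, [f"s{i}" for i in range(4)], ["g1", "g2", "g3"])
        assert np.allclose(counts.var(axis=0), [0.05, 4.0, 1.25], atol=0.3)
        out = select_hvg(expr, n_top=2, config=RAW)
        assert out.gene_ids == ["g2", "g3"]

    def test_default_keeps_2000_genes(self):
        rng = np.random.default_rng(0)
        expr = ExpressionMatrix(
            rng.poisson(2.0, size=(30, 2100)).astype(float),
            [f"s{i}" for i in range(30)],
            [f"g{j}" for j in range(2100)],
        )
        assert select_hvg(expr).n_genes == 2000

    def test_rejects_empty_matrix(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(np.empty((0, 0)), [], [])


class TestPCAEmbed:
    def test_rank_one_data_explained_by_first_component(self):
        t = np.linspace(0, 1, 8)
        counts = np.column_stack([2 * t, 3 * t])  # exactly on a line
        expr = ExpressionMatrix(counts, [f"s{i}" for i in range(8)], ["g1", "g2"])
        emb = pca_embed(expr, n_components=1, config=RAW)
        assert emb.matrix.shape == (8, 1)
        # all variance along component 1: distances match 1-D spread
        spread = np.ptp(emb.matrix[:, 0])
        assert spread == pytest.approx(np.sqrt(13), rel=1e-9)

    def test_shape_contract(self, toy_expression):
        emb = pca_embed(toy_expression, n_components=3)
        assert emb.matrix.shape == (toy_expression.n_spots, 3)

    def test_matches_covariance_eigensolve(self):
        rng = np.random.default_rng(5)
        counts = np.abs(rng.normal(2.0, 1.0, size=(4, 3)))
        expr = ExpressionMatrix(counts, [f"s{i}" for i in range(4)], ["a", "b", "c"])
        emb = pca_embed(expr, n_components=2, config=RAW)
        # independent oracle: eigendecomposition of the sample covariance
        x = counts - counts.mean(axis=0)
        vals, vecs = np.linalg.eigh(x.T @ x)
        proj = x @ vecs[:, ::-1][:, :2]
        d_emb = np.linalg.norm(emb.matrix[:, None] - emb.matrix[None], axis=-1)
        d_ora = np.linalg.norm(proj[:, None] - proj[None], axis=-1)
        np.testing.assert_allclose(d_emb, d_ora, atol=1e-10)

    def test_rejects_excess_components(self, toy_expression):
        with pytest.raises(ValueError):
            pca_embed(toy_expression, n_components=100)


class TestDefaultNeighbors:
    @pytest.mark.parametrize(
        "n,expected",
        [(9, 3), (2696, 51), (2500, 49), (100, 9), (2, 1), (10**6, 999)],
    )
    def test_examples(self, n, expected):
        assert default_neighbors(n) == expected

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            default_neighbors(1)

    @given(st.integers(min_value=2, max_value=10**6))
    @settings(max_examples=200, derandomize=True)
    def test_odd_and_closest(self, n):
        r = default_neighbors(n)
        assert r % 2 == 1 and r >= 1
        root = np.sqrt(n)
        # no odd integer is strictly closer; ties go downward
        for cand in (r - 2, r + 2):
            if cand >= 1:
                closer = abs(cand - root) < abs(r - root)
                tie_above = cand > r and abs(cand - root) == abs(r - root)
                assert not closer
                assert not (tie_above and cand < r)

    def test_monotone_in_n(self):
        vals = [default_neighbors(n) for n in range(2, 5000)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestKnnGraph:
    def test_line_points_union_symmetrization(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        a = knn_graph(pts, R=1).toarray()
        expected = np.zeros((4, 4), dtype=np.int8)
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            expected[i, j] = expected[j, i] = 1
        np.testing.assert_array_equal(a, expected)
        assert list(a.sum(axis=0)) == [1, 2, 2, 1]

    def test_equilateral_ties_broken_by_index(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        a = knn_graph(pts, R=1).toarray()
        # every node picks its lowest-index non-self neighbor: 0-1, 0-2
        assert a[0, 1] == 1 and a[0, 2] == 1 and a[1, 2] == 0
        np.testing.assert_array_equal(a, a.T)

    def test_rejects_r_geq_n(self):
        with pytest.raises(ValueError):
            knn_graph(np.zeros((3, 2)), R=3)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_symmetric_binary_zero_diag_and_min_degree(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        r = int(rng.integers(1, n - 1))
        a = knn_graph(rng.normal(size=(n, 3)), R=r)
        dense = a.toarray()
        np.testing.assert_array_equal(dense, dense.T)
        assert dense.diagonal().sum() == 0
        assert set(np.unique(dense)) <= {0, 1}
        assert (dense.sum(axis=1) >= r).all()

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(15, 2))
        phi = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        moved = pts @ rot.T + rng.normal(size=2)
        a = knn_graph(pts, R=3).toarray()
        b = knn_graph(moved, R=3).toarray()
        np.testing.assert_array_equal(a, b)


class TestBuildMultilayer:
    def test_default_r_from_spot_count(self):
        rng = np.random.default_rng(1)
        n = 100
        expr = ExpressionMatrix(
            rng.poisson(3.0, size=(n, 20)).astype(float),
            [f"s{i}" for i in range(n)],
            [f"g{j}" for j in range(20)],
        )
        coords = SpatialCoords(rng.normal(size=(n, 2)), [f"s{i}" for i in range(n)])
        g = build_multilayer(expr, coords)  # R defaults to 9 for N=100
        assert g.n_layers == 2 and g.n_spots == n
        assert all((layer.toarray().sum(axis=1) >= 9).all() for layer in g.layers)

    def test_determinism(self, toy_expression, toy_coords):
        g1 = build_multilayer(toy_expression, toy_coords, R=3)
        g2 = build_multilayer(toy_expression, toy_coords, R=3)
        for a, b in zip(g1.layers, g2.layers):
            assert (a != b).nnz == 0

    def test_mismatched_ids_named_in_error(self, toy_expression):
        coords = SpatialCoords(np.zeros((12, 2)), [f"x{i}" for i in range(12)])
        with pytest.raises(ValueError, match="not aligned"):
            build_multilayer(toy_expression, coords)
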