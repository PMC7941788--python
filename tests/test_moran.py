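"""Spatial weights and Moran statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from wildfire_excess import (
    SpatialWeights,
    build_weights,
    falsification_report,
    global_moran,
    local_moran,
)


def brute_global_moran(x, W):
    """Double-loop Moran's I, written independently of the vectorized path."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
    den = sum((xi - xbar) ** 2 for xi in x)
    return (n / W.sum()) * num / den


def brute_local_moran(x, W):
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    m2 = sum((xk - xbar) ** 2 for xk in x) / n
    out = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += W[i, j] * (x[j] - xbar)
        out[i] = (x[i] - xbar) / m2 * s
    return out


def random_weights(n, rng):
    W = (rng.random((n, n)) < 0.3).astype(float)
    np.fill_diagonal(W, 0)
    for i in np.flatnonzero(W.sum(axis=1) == 0):
        W[i, (i + 1) % n] = 1.0  # every unit needs at least one neighbor
    W = W / W.sum(axis=1, keepdims=True)
    return SpatialWeights(W, [f"u{i}" for i in range(n)], "random", True)


def line_geometry(xs):
    return pd.DataFrame(
        {"unit_id": [f"u{i}" for i in range(len(xs))],
         "x_km": xs, "y_km": [0.0] * len(xs), "population": [1] * len(xs)}
    )


class TestWeights:
    def test_nearest_neighbor_on_a_line(self):
        w = build_weights(line_geometry([0.0, 1.0, 2.0, 3.0]), k=1, row_standardize=False)
        assert w.matrix[0, 1] == 1 and w.matrix[0].sum() == 1
        assert w.matrix[3, 2] == 1 and w.matrix[3].sum() == 1

    def test_square_corners_prefer_edge_neighbors(self):
        geo = pd.DataFrame(
            {"unit_id": list("abcd"), "x_km": [0.0, 1.0, 0.0, 1.0],
             "y_km": [0.0, 0.0, 1.0, 1.0], "population": [1] * 4}
        )
        w = build_weights(geo, k=2, row_standardize=False)
        # each corner's two nearest are the edge-adjacent corners, not the diagonal
        assert w.matrix[0, 1] == 1 and w.matrix[0, 2] == 1 and w.matrix[0, 3] == 0

    def test_row_standardization_and_knn_degree(self, geometry108):
        w = build_weights(geometry108, k=8)
        assert np.allclose(w.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert (w.neighbor_counts() == 8).all()
        assert (np.diag(w.matrix) == 0).all()

    def test_duplicate_coordinates_tie_broken_with_warning(self):
        geo = line_geometry([0.0, 0.0, 5.0, 6.0])
        with pytest.warns(UserWarning):
            w = build_weights(geo, k=1, row_standardize=False)
        assert w.matrix[0, 1] == 1  # lexicographic unit order breaks the tie

    def test_k_out_of_range(self, geometry108):
        with pytest.raises(ValueError):
            build_weights(geometry108, k=108)


class TestGlobalMoran:
    def test_oracle_equivalence_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(5, 21))
            w = random_weights(n, rng)
            x = rng.normal(size=n)
            r = global_moran(x, w, n_permutations=19, seed=0)
            assert r.I == pytest.approx(brute_global_moran(x, w.matrix), abs=1e-10)
            assert r.expected_I == pytest.approx(-1 / (n - 1))

    def test_alternating_values_on_path_graph_reach_minus_one(self):
        n = 6
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1
        W = A / A.sum(axis=1, keepdims=True)
        w = SpatialWeights(W, [f"u{i}" for i in range(n)], "path", True)
        x = np.array([1.0, -1.0] * (n // 2))
        r = global_moran(x, w, n_permutations=99, seed=0)
        assert r.I == pytest.approx(-1.0)
        assert r.verdict in ("dispersed", "random")

    def test_permutation_p_floor_and_determinism(self, weights8):
        rng = np.random.default_rng(1)
        x = rng.normal(size=weights8.n)
        r1 = global_moran(x, weights8, n_permutations=99, seed=5)
        r2 = global_moran(x, weights8, n_permutations=99, seed=5)
        assert (r1.I, r1.p_perm) == (r2.I, r2.p_perm)
        assert r1.p_perm >= 1 / 100

    def test_constant_input_rejected(self, weights8):
        with pytest.raises(ValueError):
            global_moran(np.ones(weights8.n), weights8)


class TestLocalMoran:
    def test_oracle_equivalence_and_sum_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(6, 21))
            w = random_weights(n, rng)
            x = rng.normal(size=n)
            loc = local_moran(x, w, n_permutations=19, seed=0)
            assert np.allclose(loc.I, brute_local_moran(x, w.matrix), atol=1e-10)
            glob = global_moran(x, w, n_permutations=19, seed=0)
            assert loc.I.sum() == pytest.approx(n * glob.I, abs=1e-10)

    def test_spatial_outlier_is_high_low(self):
        rng = np.random.default_rng(3)
        w = random_weights(8, rng)
        x = np.zeros(8)
        x[0] = 10.0  # one high value in a flat low field
        loc = local_moran(x, w, n_permutations=19, seed=0)
        assert loc.quadrant[0] == "HL"

    def test_benjamini_hochberg_only_removes_flags(self, weights8):
        rng = np.random.default_rng(4)
        x = rng.normal(size=weights8.n)
        raw = local_moran(x, weights8, n_permutations=199, seed=1)
        adj = local_moran(x, weights8, n_permutations=199, seed=1, bh_adjust=True)
        assert set(np.flatnonzero(adj.significant)) <= set(np.flatnonzero(raw.significant))


class TestFalsificationReport:
    def test_identical_values_identical_verdicts(self, weights8):
        rng = np.random.default_rng(5)
        x = rng.normal(size=weights8.n)
        fr = falsification_report({"a": x, "b": x.copy()}, weights8, seed=9)
        assert fr.loc[0, "verdict"] == fr.loc[1, "verdict"]
        assert fr.loc[0, "p_perm"] == fr.loc[1, "p_perm"]

    def test_empty_input_rejected(self, weights8):
        with pytest.raises(ValueError):
            falsification_report({}, weights8)
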