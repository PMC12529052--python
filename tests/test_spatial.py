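"""Spatial statistics: k-NN weights, deviation maps, Moran's I, aggregation."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import stomagrid as sg
from stomagrid.grid import DensityGrid
from stomagrid.spatial import UndefinedStatisticError


def make_grid(sd, valid=None):
    sd = np.asarray(sd, float)
    valid = np.isfinite(sd) if valid is None else np.asarray(valid, bool)
    return DensityGrid(sd, valid)


def brute_force_knn(grid, k):
    """Independent neighbour oracle: python sort over all valid cell pairs."""
    cells = [tuple(c) for c in np.argwhere(grid.valid)]
    centres = {c: (c[0] + 0.5, c[1] + 0.5) for c in cells}
    out = {}
    for i, ci in enumerate(cells):
        cand = []
        for j, cj in enumerate(cells):
            if i == j:
                continue
            d2 = (centres[ci][0] - centres[cj][0]) ** 2 + (centres[ci][1] - centres[cj][1]) ** 2
            cand.append((d2, j))
        cand.sort()
        out[i] = [j for _, j in cand[:k]]
    return cells, out


def loop_morans(values2d, valid, neighbours, cells):
    """Literal nested-loop transcription of the printed formulas."""
    vals = np.array([values2d[r, c] for r, c in cells])
    n = len(vals)
    mean = vals.mean()
    z = vals - mean
    W = sum(len(neighbours[i]) for i in range(n))
    num = 0.0
    for i in range(n):
        for j in neighbours[i]:
            num += z[i] * z[j]
    global_i = n / W * num / (z**2).sum()
    local = [z[i] * sum(z[j] for j in neighbours[i]) for i in range(n)]
    return global_i, np.array(local)


class TestKnnWeights:
    def test_interior_cell_rook_neighbours(self):
        g = make_grid(np.arange(25.0).reshape(5, 5))
        w = sg.knn_weights(g, 4)
        cells = [tuple(c) for c in w.cells]
        i = cells.index((2, 2))
        got = {cells[j] for j in w.neighbours[i]}
        assert got == {(1, 2), (3, 2), (2, 1), (2, 3)}

    def test_corner_cell_tie_break_row_major(self):
        g = make_grid(np.arange(16.0).reshape(4, 4))
        w = sg.knn_weights(g, 4)
        cells = [tuple(c) for c in w.cells]
        got = {cells[j] for j in w.neighbours[cells.index((0, 0))]}
        # 2 rook at distance 1, 1 diagonal at sqrt(2); the tie at distance 2
        # between (0,2) and (2,0) resolves to the lower row-major index (0,2)
        assert got == {(0, 1), (1, 0), (1, 1), (0, 2)}

    def test_masked_hole_skips_invalid_cells(self):
        sd = np.arange(36.0).reshape(6, 6)
        valid = np.ones((6, 6), bool)
        valid[2:4, 2:4] = False
        g = make_grid(sd, valid)
        w = sg.knn_weights(g, 4)
        cells, oracle = brute_force_knn(g, 4)
        for i in range(w.n):
            mine = sorted(w.neighbours[i].tolist())
            # compare distances, not indices (ties may reorder equals)
            d = lambda j: (cells[i][0] - cells[j][0]) ** 2 + (cells[i][1] - cells[j][1]) ** 2
            assert sorted(map(d, mine)) == sorted(map(d, oracle[i]))

    def test_w_equals_nk_and_no_self(self):
        g = make_grid(np.random.default_rng(0).random((5, 7)) * 100)
        w = sg.knn_weights(g, 4)
        assert w.W == w.n * 4
        for i in range(w.n):
            assert i not in w.neighbours[i]
            assert len(set(w.neighbours[i])) == 4

    def test_too_few_cells_rejected(self):
        g = make_grid([[1.0, 2.0], [3.0, np.nan]])
        with pytest.raises(UndefinedStatisticError):
            sg.knn_weights(g, 4)


class TestDeviation:
    def test_uniform_grid_zero(self):
        d = sg.relative_global_deviation(make_grid(np.full((4, 4), 80.0)))
        assert d.mean_d_rel == 0.0
        assert np.all(d.d_rel[np.isfinite(d.d_rel)] == 0)

    def test_hand_computed_1x2(self):
        d = sg.relative_global_deviation(make_grid([[1.0, 3.0]]))
        assert np.allclose(d.d_rel, [[0.5, 0.5]])
        assert d.mean_d_rel == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        sd = rng.uniform(30, 150, (5, 5))
        d1 = sg.relative_global_deviation(make_grid(sd))
        d2 = sg.relative_global_deviation(make_grid(sd * 7.3))
        assert np.allclose(d1.d_rel, d2.d_rel)
        assert d1.mean_d_rel == pytest.approx(d2.mean_d_rel)

    def test_signed_map_retained(self):
        d = sg.relative_global_deviation(make_grid([[1.0, 3.0]]))
        assert np.allclose(d.d_signed, [[-1.0, 1.0]])

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            sg.relative_global_deviation(make_grid(np.zeros((3, 3))))


class TestMoran:
    def test_constant_grid_undefined(self):
        g = make_grid(np.full((4, 4), 50.0))
        w = sg.knn_weights(g, 4)
        with pytest.raises(UndefinedStatisticError):
            sg.global_morans_i(g, w)

    def test_3x3_matches_nested_loop_oracle(self):
        g = make_grid(np.arange(1.0, 10.0).reshape(3, 3))
        w = sg.knn_weights(g, 4)
        cells = [tuple(c) for c in w.cells]
        ref_g, ref_local = loop_morans(g.sd, g.valid, {i: w.neighbours[i].tolist() for i in range(w.n)}, cells)
        assert sg.global_morans_i(g, w) == pytest.approx(ref_g, abs=1e-12)
        res = sg.local_morans_i(g, w)
        mine = res.local_i[g.valid]
        assert np.allclose(mine, ref_local, atol=1e-12)

    def test_checkerboard_negative(self):
        sd = np.indices((8, 8)).sum(axis=0) % 2 * 1.0
        g = make_grid(sd)
        w = sg.knn_weights(g, 4)
        assert sg.global_morans_i(g, w) < -0.5

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        sd = rng.uniform(10, 200, (6, 6))
        g1, g2 = make_grid(sd), make_grid(3.7 * sd - 40.0)
        w = sg.knn_weights(g1, 4)
        assert sg.global_morans_i(g1, w) == pytest.approx(
            sg.global_morans_i(g2, sg.knn_weights(g2, 4)), abs=1e-10
        )

    def test_cell_at_mean_has_zero_local_i(self):
        sd = np.array([[10.0, 20.0, 30.0], [40.0, 25.0, 10.0], [20.0, 40.0, 30.0]])
        assert sd.mean() == 25.0
        g = make_grid(sd)
        res = sg.local_morans_i(g, sg.knn_weights(g, 4))
        assert res.local_i[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_outlier_cell_negative_local_i(self):
        sd = np.full((5, 5), 20.0)
        sd += np.random.default_rng(3).normal(0, 0.5, (5, 5))  # break zero variance
        sd[2, 2] = 120.0
        g = make_grid(sd)
        res = sg.local_morans_i(g, sg.knn_weights(g, 4))
        assert res.local_i[2, 2] < 0

    def test_sum_identity_random_6x6(self):
        rng = np.random.default_rng(4)
        g = make_grid(rng.uniform(0, 150, (6, 6)))
        w = sg.knn_weights(g, 4)
        res = sg.local_morans_i(g, w)
        z = g.values() - g.values().mean()
        ident = w.n / w.W * res.local_i[g.valid].sum() / (z**2).sum()
        assert ident == pytest.approx(res.global_i, abs=1e-12)

    def test_standardized_variant_scales_by_m2(self):
        rng = np.random.default_rng(5)
        g = make_grid(rng.uniform(0, 100, (5, 5)))
        w = sg.knn_weights(g, 4)
        plain = sg.local_morans_i(g, w)
        std = sg.local_morans_i(g, w, standardized=True)
        z = g.values() - g.values().mean()
        m2 = (z**2).sum() / w.n
        assert np.allclose(std.local_i[g.valid], plain.local_i[g.valid] / m2)

    def test_permutation_null_expectation(self):
        """Mean of Moran's I over random value permutations approaches the
        classical exchangeability expectation -1/(n-1)."""
        rng = np.random.default_rng(6)
        sd = rng.uniform(20, 140, (6, 6))
        g = make_grid(sd)
        w = sg.knn_weights(g, 4)
        vals = sd.ravel().copy()
        sims = []
        for _ in range(2000):
            rng.shuffle(vals)
            sims.append(sg.global_morans_i(make_grid(vals.reshape(6, 6)), w))
        sims = np.array(sims)
        expect = -1.0 / (w.n - 1)
        se = sims.std(ddof=1) / np.sqrt(len(sims))
        assert abs(sims.mean() - expect) <= 3 * se


class TestMoranProperties:
    @given(
        sd=arrays(
            np.float64,
            st.tuples(st.integers(3, 8), st.integers(3, 8)),
            elements=st.floats(0, 200, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_global_local_identity_and_affine_invariance(self, sd):
        assume(np.ptp(sd) > 1e-6)
        g = make_grid(sd)
        w = sg.knn_weights(g, 4)
        res = sg.local_morans_i(g, w)
        z = g.values() - g.values().mean()
        ident = w.n / w.W * res.local_i[g.valid].sum() / (z**2).sum()
        assert ident == pytest.approx(res.global_i, abs=1e-10)
        g2 = make_grid(2.5 * sd + 11.0)
        assert sg.global_morans_i(g2, sg.knn_weights(g2, 4)) == pytest.approx(
            res.global_i, rel=1e-9, abs=1e-9
        )


class TestAggregateReplicates:
    def test_identical_replicates_identity(self):
        m = np.arange(12.0).reshape(3, 4)
        out = sg.aggregate_replicates([m, m, m])
        assert np.allclose(out, m)

    def test_median_robust_to_outlier_map(self):
        m = np.full((3, 3), 50.0)
        outlier = np.full((3, 3), 500.0)
        out = sg.aggregate_replicates([m, m, outlier])
        assert np.allclose(out, 50.0)

    def test_different_widths_cropped_to_intersection(self):
        a = np.ones((3, 5))
        b = np.ones((4, 3))
        out = sg.aggregate_replicates([a, b])
        assert out.shape == (3, 3)

    def test_alignment_at_top_left_valid_anchor(self):
        a = np.full((3, 3), 10.0)
        b = np.full((4, 4), np.nan)
        b[1:, 1:] = 10.0  # same map, shifted by one cell
        out = sg.aggregate_replicates([a, b])
        assert out.shape == (3, 3)
        assert np.allclose(out, 10.0)

    def test_validity_majority_rule(self):
        a = np.array([[1.0, np.nan]])
        b = np.array([[1.0, np.nan]])
        c = np.array([[1.0, 5.0]])
        out = sg.aggregate_replicates([a, b, c])
        assert np.isnan(out[0, 1])  # valid in only 1/3 replicates

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sg.aggregate_replicates([])


class TestCV:
    def test_uniform_zero(self):
        assert sg.coefficient_of_variation(make_grid(np.full((3, 3), 42.0))) == 0.0

    def test_two_cell_hand_value(self):
        cv = sg.coefficient_of_variation(make_grid([[50.0, 150.0]]))
        assert cv == pytest.approx(100 * np.sqrt(5000) / 100, rel=1e-12)  # 70.71%

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        sd = rng.uniform(10, 100, (4, 4))
        assert sg.coefficient_of_variation(make_grid(sd)) == pytest.approx(
            sg.coefficient_of_variation(make_grid(sd * 3.0))
        )

    def test_degenerate_inputs(self):
        with pytest.raises(UndefinedStatisticError):
            sg.coefficient_of_variation(make_grid([[5.0]]))
        with pytest.raises(UndefinedStatisticError):
            sg.coefficient_of_variation(make_grid(np.zeros((2, 2))))
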