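import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cornseg import BoundaryCurve, BScanImage, GradientField, SegConfig
from cornseg.core import InvalidInputError
from cornseg.refine import (
    axial_gradient,
    decay_horizon,
    geometric_weights,
    refine_boundary_2d,
    smooth_sg,
)
from oracles import oracle_refine


class TestAxialGradient:
    def test_direct_formula(self):
        col = np.array([0.2, 0.6, 0.6])
        img = BScanImage(np.tile(col[:, None], (1, 3)), 5.0, 60.0)
        g = axial_gradient(img)
        assert np.allclose(g.values[:, 0], [0.2, 0.0, 0.0])

    def test_constant_image_zero_gradient(self):
        img = BScanImage(np.full((6, 6), 0.4), 5.0, 60.0)
        assert np.allclose(axial_gradient(img).values, 0.0)

    def test_matches_elementwise_evaluation(self, rng):
        px = rng.random((20, 20))
        g = axial_gradient(BScanImage(px, 5.0, 60.0)).values
        for y in range(19):
            for x in range(20):
                assert g[y, x] == (px[y + 1, x] - px[y, x]) / 2.0
        assert np.array_equal(g[19], g[18])


class TestGeometricWeights:
    def test_half_decay(self):
        assert np.allclose(geometric_weights(0.5, 3), [0.5, 0.25, 0.125])

    def test_high_p(self):
        assert np.allclose(geometric_weights(0.9, 2), [0.9, 0.09])

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.floats(0.01, 0.99), st.integers(1, 200))
    def test_partial_sums_match_closed_form(self, p, n):
        w = geometric_weights(p, n)
        assert np.all(np.diff(w) < 0)
        assert w.sum() == pytest.approx(1 - (1 - p) ** n, abs=1e-12)

    def test_rejects_degenerate_p(self):
        with pytest.raises(InvalidInputError):
            geometric_weights(1.0, 3)


class TestRefineBoundary2D:
    def _field(self, rng, y=30, x=12):
        return GradientField(rng.random((y, x)) - 0.5)

    def test_zero_radius_returns_coarse_unchanged(self, rng):
        g = self._field(rng)
        coarse = BoundaryCurve(rng.uniform(5, 20, 12), np.ones(12, bool))
        cfg = SegConfig(search_radius_px=0)
        out = refine_boundary_2d(g, coarse, cfg)
        assert np.array_equal(out.positions, coarse.positions)

    def test_single_column_equals_seed_argmax(self, rng):
        vals = rng.random((30, 3))
        g = GradientField(vals)
        coarse = BoundaryCurve([np.nan, 15.0, np.nan], [False, True, False])
        cfg = SegConfig(search_radius_px=5)
        out = refine_boundary_2d(g, coarse, cfg)
        window = np.abs(vals[10:21, 1])
        assert out.positions[1] == 10 + np.argmax(window)

    def test_never_leaves_search_window(self, rng):
        g = self._field(rng, y=60, x=40)
        coarse = BoundaryCurve(np.full(40, 30.0), np.ones(40, bool))
        cfg = SegConfig(search_radius_px=4)
        out = refine_boundary_2d(g, coarse, cfg)
        assert np.abs(out.positions - 30.0).max() <= 4

    def test_deterministic(self, rng):
        g = self._field(rng, y=50, x=30)
        coarse = BoundaryCurve(np.full(30, 25.0), np.ones(30, bool))
        cfg = SegConfig()
        a = refine_boundary_2d(g, coarse, cfg)
        b = refine_boundary_2d(g, coarse, cfg)
        assert np.array_equal(a.positions, b.positions)

    def test_recovers_sharp_edge_on_sinusoidal_boundary(self):
        # a single strong edge exactly on a non-polynomial boundary, coarse
        # given as the (wrong but close) flat curve
        x = np.arange(64)
        truth = (30 + 3 * np.sin(2 * np.pi * x / 40)).round().astype(int)
        vals = np.zeros((60, 64))
        vals[truth, x] = 1.0
        out = refine_boundary_2d(
            GradientField(vals),
            BoundaryCurve(np.full(64, 30.0), np.ones(64, bool)),
            SegConfig(search_radius_px=5),
        )
        assert np.array_equal(out.positions, truth)

    def test_all_invalid_rejected(self, rng):
        g = self._field(rng)
        coarse = BoundaryCurve(np.full(12, np.nan), np.zeros(12, bool))
        with pytest.raises(InvalidInputError):
            refine_boundary_2d(g, coarse, SegConfig())

    @pytest.mark.parametrize("seed", range(12))
    def test_greedy_scores_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x_dim = int(rng.integers(2, 9))
        y_dim = int(rng.integers(8, 15))
        r = int(rng.integers(1, 3))
        p = float(rng.uniform(0.2, 0.9))
        vals = rng.random((y_dim, x_dim))
        base_rows = rng.integers(2, y_dim - 2, x_dim)
        valid = rng.random(x_dim) > 0.2
        if not valid.any():
            valid[0] = True
        coarse = BoundaryCurve(
            np.where(valid, base_rows.astype(float), np.nan), valid
        )
        cfg = SegConfig(search_radius_px=r, decay_p=p)
        out = refine_boundary_2d(GradientField(vals), coarse, cfg)
        base = np.clip(np.rint(np.where(valid, coarse.positions, 0)).astype(int), 0, y_dim - 1)
        refined, _ = oracle_refine(np.abs(vals), base, valid, p, r)
        for x, row in refined.items():
            assert out.positions[x] == row, f"column {x} (seed {seed})"

    def test_high_p_collapses_to_greedy_chain(self):
        # with p ~ 1 the propagation trusts only the nearest neighbour; on a
        # field with one dominant edge per column the result is the
        # per-column argmax chained from the seed
        x = np.arange(40)
        truth = (20 + 2 * np.sin(2 * np.pi * x / 25)).round().astype(int)
        vals = np.zeros((40, 40))
        vals[truth, x] = 1.0
        out = refine_boundary_2d(
            GradientField(vals),
            BoundaryCurve(np.full(40, 20.0), np.ones(40, bool)),
            SegConfig(search_radius_px=4, decay_p=0.999),
        )
        assert np.array_equal(out.positions, truth)


class TestSmoothSG:
    def test_affine_curve_preserved(self, cfg):
        x = np.arange(60, dtype=float)
        curve = BoundaryCurve(3 + 0.2 * x, np.ones(60, bool))
        out = smooth_sg(curve, cfg)
        assert np.allclose(out.positions, curve.positions, atol=1e-9)

    def test_constant_curve_preserved(self, cfg):
        curve = BoundaryCurve(np.full(40, 11.0), np.ones(40, bool))
        assert np.allclose(smooth_sg(curve, cfg).positions, 11.0, atol=1e-12)

    def test_noise_suppression_factor(self, cfg):
        # order-1/21-frame smoothing averages ~21 samples; residual spread
        # should drop well below sigma/3 on a line + white noise
        rng = np.random.default_rng(0)
        x = np.arange(400, dtype=float)
        devs = []
        for _ in range(100):
            noisy = 5 + 0.1 * x + rng.normal(0, 1.0, 400)
            out = smooth_sg(BoundaryCurve(noisy, np.ones(400, bool)), cfg)
            devs.append(np.std(out.positions - (5 + 0.1 * x)))
        assert np.mean(devs) < 1.0 / 3.0

    def test_short_runs_shrink_window(self, cfg):
        pos = np.array([np.nan, 4.0, 5.0, 6.0, np.nan, 9.0])
        valid = ~np.isnan(pos)
        out = smooth_sg(BoundaryCurve(pos, valid), cfg)
        assert np.allclose(out.positions[1:4], [4, 5, 6], atol=1e-9)
        assert out.positions[5] == 9.0


class TestDecayHorizon:
    def test_matches_direct_inequality(self):
        for p in (0.1, 0.5, 0.9):
            h = decay_horizon(p)
            assert (1 - p) ** h < 1e-6
            assert (1 - p) ** (h - 1) >= 1e-6
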