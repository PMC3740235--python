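"""Level-set machinery: smoothed step functions, flows, initialization."""

import numpy as np
import pytest

from dyntexseg import (
    LevelSetState,
    SolverConfig,
    default_scene_polygons,
    init_from_polygons,
    segment,
    smooth_dirac,
    smooth_heaviside,
    synthetic_config,
)
from dyntexseg.errors import DegeneratePolygon, NumericalBlowup
from dyntexseg.levelset_solver import (
    EnergyTerms,
    diffusion_coefficient,
    gradient_flow_step,
    reinitialize,
    signed_distance,
)


class TestSmoothStepFunctions:
    def test_heaviside_at_zero(self):
        assert smooth_heaviside(np.array(0.0)) == pytest.approx(0.5)

    def test_heaviside_odd_symmetry(self, rng):
        phi = rng.standard_normal(100) * 5
        assert np.allclose(smooth_heaviside(phi) + smooth_heaviside(-phi), 1.0)

    def test_heaviside_limits_and_monotonicity(self):
        phi = np.linspace(-50, 50, 201)
        h = smooth_heaviside(phi, 1.5)
        assert (np.diff(h) > 0).all()
        assert h[0] < 0.01 and h[-1] > 0.99

    def test_dirac_integrates_to_one_across_the_interface(self):
        phi = np.linspace(-200, 200, 40001)
        d = smooth_dirac(phi, 1.5)
        assert np.trapezoid(d, phi) == pytest.approx(1.0, abs=1e-2)

    def test_dirac_is_derivative_of_heaviside(self):
        phi = np.linspace(-5, 5, 1001)
        h = smooth_heaviside(phi, 1.5)
        numeric = np.gradient(h, phi)
        assert np.allclose(numeric, smooth_dirac(phi, 1.5), atol=1e-4)


class TestDiffusionCoefficient:
    def test_flat_image_gives_unity(self):
        g = diffusion_coefficient(np.full((10, 10), 0.3), None)
        assert np.allclose(g, 1.0)

    def test_half_value_at_eta(self):
        image = np.tile(np.arange(10.0), (10, 1))  # |grad| = 1 everywhere
        g = diffusion_coefficient(image, None, eta=1.0)
        assert np.allclose(g[2:-2, 2:-2], 0.5)

    def test_monotone_decreasing_in_gradient(self):
        yy = np.tile(np.arange(20.0) ** 2, (5, 1))
        g = diffusion_coefficient(yy, None, eta=10.0)
        row = g[2, 2:-2]
        assert (np.diff(row) < 0).all()


class TestGradientFlow:
    def _state(self, shape=(24, 24)):
        mask1 = np.zeros(shape, dtype=bool)
        mask1[8:16, 8:16] = True
        mask2 = np.zeros(shape, dtype=bool)
        mask2[4:20, 4:20] = True
        return LevelSetState(phi1=signed_distance(mask1), phi2=signed_distance(mask2))

    def test_zero_weights_leave_state_unchanged(self):
        state = self._state()
        terms = EnergyTerms(L={0: np.zeros((24, 24)), 1: np.zeros((24, 24)),
                               2: np.zeros((24, 24))})
        cfg = SolverConfig(alpha=0, beta=0, gamma=0, zeta=0, lambda_d=0.0)
        out = gradient_flow_step(state, terms, cfg)
        assert np.allclose(out.phi1, state.phi1)
        assert np.allclose(out.phi2, state.phi2)

    def test_pure_diffusion_reduces_total_variation(self, rng):
        state = self._state()
        noisy = state.phi2 + 0.5 * rng.standard_normal(state.phi2.shape)
        state = LevelSetState(phi1=None, phi2=noisy)
        terms = EnergyTerms(L={0: np.zeros((24, 24)), 1: np.zeros((24, 24))})
        cfg = SolverConfig(alpha=0, beta=0, gamma=0, zeta=0, kappa=0.0, lambda_d=0.2)

        def tv(phi):
            gy, gx = np.gradient(phi)
            return np.hypot(gy, gx).sum()

        before = tv(state.phi2)
        for _ in range(5):
            state = gradient_flow_step(state, terms, cfg)
        assert tv(state.phi2) < before

    def test_blowup_detected(self):
        state = self._state()
        bad = np.full((24, 24), np.inf)
        terms = EnergyTerms(L={0: bad, 1: bad, 2: bad})
        cfg = SolverConfig(lambda_d=0.0)
        state.phi1[0, 0] = np.nan
        with pytest.raises(NumericalBlowup):
            gradient_flow_step(state, terms, cfg)

    def test_label_classes_tile_the_image(self, rng):
        phi1 = rng.standard_normal((16, 16))
        phi2 = rng.standard_normal((16, 16))
        labels = LevelSetState(phi1=phi1, phi2=phi2).labels
        assert set(np.unique(labels)) <= {0, 1, 2, 3}
        assert labels.shape == (16, 16)
        # sign pattern consistency
        assert ((labels == 2) == ((phi1 < 0) & (phi2 < 0))).all()
        assert ((labels == 3) == ((phi1 < 0) & (phi2 >= 0))).all()


class TestInitialization:
    def test_square_polygon_interior_is_negative(self):
        poly = np.array([[4, 4], [4, 12], [12, 12], [12, 4]], dtype=float)
        phi1, phi2 = init_from_polygons(poly, None, (20, 20))
        assert phi1 is None
        inside = phi2 < 0
        assert inside[8, 8]
        assert not inside[1, 1]
        assert not inside[15, 15]

    def test_thrombus_clipped_to_vessel(self):
        vessel = np.array([[2, 2], [2, 10], [10, 10], [10, 2]], dtype=float)
        thrombus = np.array([[6, 6], [6, 16], [16, 16], [16, 6]], dtype=float)
        phi1, phi2 = init_from_polygons(vessel, thrombus, (20, 20))
        thr = phi1 < 0
        ves = phi2 < 0
        assert thr.any()
        assert (thr & ~ves).sum() == 0

    def test_degenerate_polygon_raises(self):
        with pytest.raises(DegeneratePolygon):
            init_from_polygons(np.array([[1.0, 1.0], [2.0, 2.0]]), None, (10, 10))

    def test_signed_distance_against_brute_force(self, rng):
        mask = np.zeros((15, 15), dtype=bool)
        mask[4:10, 5:12] = True
        phi = signed_distance(mask)
        coords = np.argwhere(mask)
        anti = np.argwhere(~mask)
        for r, c in [(0, 0), (6, 7), (4, 5), (14, 14), (9, 11)]:
            if mask[r, c]:
                expected = -np.sqrt(((anti - [r, c]) ** 2).sum(axis=1).min())
            else:
                expected = np.sqrt(((coords - [r, c]) ** 2).sum(axis=1).min())
            assert phi[r, c] == pytest.approx(expected, abs=1e-9)

    def test_reinitialize_preserves_sign_and_normalizes_gradient(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[8:22, 8:22] = True
        phi = 7.3 * signed_distance(mask)  # badly scaled
        out = reinitialize(phi)
        assert ((out < 0) == mask).all()
        gy, gx = np.gradient(out)
        mag = np.hypot(gy, gx)
        band = np.abs(out) < 4
        assert mag[band].min() > 0.5 and mag[band].max() < 1.6


class TestSegment:
    def test_max_outer_zero_returns_init_partition(self, three_region_scene):
        seq, labels = three_region_scene
        cfg = synthetic_config(seed=0, max_outer=0)
        res = segment(seq, (0, 61), init_labels=labels, config=cfg)
        assert np.array_equal(res.labels, labels)

    def test_fixed_seed_is_bit_reproducible(self, three_region_scene):
        seq, _ = three_region_scene
        thr_p, ves_p = default_scene_polygons()
        cfg = synthetic_config(seed=5, max_outer=4)
        a = segment(seq, (0, 61), init_polygons=(thr_p, ves_p), config=cfg)
        b = segment(seq, (0, 61), init_polygons=(thr_p, ves_p), config=cfg)
        assert np.array_equal(a.labels, b.labels)

    def test_short_run_improves_partition(self, three_region_scene):
        """A few outer iterations from the default polygons already move the
        partition toward the ground truth."""
        from dyntexseg import rand_index

        seq, labels = three_region_scene
        thr_p, ves_p = default_scene_polygons()
        phi1, phi2 = init_from_polygons(ves_p, thr_p, seq.shape[:2])
        init_rand = rand_index(LevelSetState(phi1=phi1, phi2=phi2).labels, labels)
        cfg = synthetic_config(seed=2, max_outer=6)
        res = segment(seq, (0, 61), init_polygons=(thr_p, ves_p), config=cfg)
        assert rand_index(res.labels, labels) > init_rand + 0.05

    def test_energy_descent_mostly_monotone(self, three_region_scene):
        """Within inner loops the smoothed descent functional is
        non-increasing for at least 90% of the recorded steps."""
        seq, labels = three_region_scene
        thr_p, ves_p = default_scene_polygons()
        cfg = synthetic_config(seed=3, max_outer=4, track_energy=True,
                               lambda_d=0.0, reinit_every=1000)
        res = segment(seq, (0, 61), init_polygons=(thr_p, ves_p), config=cfg)
        e = np.array(res.energy_history)
        per_outer = e.reshape(res.n_outer, -1)
        drops = np.diff(per_outer, axis=1) <= 1e-6
        assert drops.mean() >= 0.9
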