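"""Dynamic-texture estimation and the Martin distance."""

import numpy as np
import pytest

from dyntexseg import (
    DTModel,
    compute_dt_field,
    estimate_dt,
    martin_distance,
    observability_matrix,
    pairwise_sq_distances,
    random_stable_lds,
    simulate_lds,
)
from dyntexseg.errors import InsufficientFrames, OrderMismatch, WindowOutOfRange


def _rotation_blocks(n, rho=0.95, omega=0.8):
    """Stable block-rotation dynamics: keeps every state direction excited
    along a noise-free trajectory (real well-separated eigenvalues would let
    the trajectory collapse to one direction and leave A unidentifiable)."""
    A = np.zeros((n, n))
    for j in range(0, n - 1, 2):
        c, s = np.cos(omega + j), np.sin(omega + j)
        A[j: j + 2, j: j + 2] = rho * np.array([[c, -s], [s, c]])
    if n % 2:
        A[-1, -1] = rho
    return A


def _noise_free_lds(n, p, seed, T, z0_scale=0.3):
    spec = random_stable_lds(n, p, seed=seed, q_std=0.0, r_std=0.0)
    A = _rotation_blocks(n)
    rng = np.random.default_rng(seed + 1)
    z0 = z0_scale * rng.standard_normal(n)
    y_bar = spec.y_bar + spec.C @ np.zeros(n)
    z = z0.copy()
    y = np.empty((p, T))
    for t in range(T):
        y[:, t] = spec.y_bar + spec.C @ z
        z = A @ z
    truth = DTModel(A=A, C=spec.C, y_bar=spec.y_bar, n=n)
    return y, truth


class TestEstimation:
    def test_roundtrip_recovers_generating_subspace(self):
        """Noise-free order-2 data: estimated and true observability
        subspaces coincide to numerical precision."""
        y, truth = _noise_free_lds(n=2, p=9, seed=3, T=31)
        est = estimate_dt(y, 2)
        assert martin_distance(truth, est) < 1e-6

    def test_observation_matrix_is_orthonormal(self):
        y, _ = _noise_free_lds(n=3, p=25, seed=5, T=60)
        est = estimate_dt(y, 3)
        assert np.abs(est.C.T @ est.C - np.eye(3)).max() < 1e-8

    def test_constant_patch_is_flagged_degenerate(self):
        stack = np.full((9, 20), 0.7)
        est = estimate_dt(stack, 2)
        assert est.degenerate
        assert np.allclose(est.A, 0.0)
        assert np.abs(est.C.T @ est.C - np.eye(2)).max() < 1e-8

    def test_too_few_frames_raises(self):
        stack = np.random.default_rng(0).random((9, 3))
        with pytest.raises(InsufficientFrames):
            estimate_dt(stack, 3)  # tau = 2 < n

    def test_mean_is_temporal_mean(self):
        rng = np.random.default_rng(1)
        stack = rng.random((4, 10))
        est = estimate_dt(stack, 2)
        assert np.allclose(est.y_bar, stack.mean(axis=1))


class TestObservability:
    def test_single_block_for_order_one(self):
        m = DTModel(A=np.array([[0.5]]), C=np.array([[1.0], [0.0]]),
                    y_bar=np.zeros(2), n=1)
        assert np.allclose(observability_matrix(m), [[1.0], [0.0]])

    def test_identity_dynamics_stacks_copies_of_c(self):
        rng = np.random.default_rng(2)
        C, _ = np.linalg.qr(rng.standard_normal((5, 2)))
        m = DTModel(A=np.eye(2), C=C, y_bar=np.zeros(5), n=2)
        O = observability_matrix(m)
        assert np.allclose(O[:5], C)
        assert np.allclose(O[5:], C)

    def test_blocks_match_matrix_power_oracle(self):
        rng = np.random.default_rng(3)
        A = 0.8 * rng.standard_normal((3, 3)) / 3
        C, _ = np.linalg.qr(rng.standard_normal((7, 3)))
        m = DTModel(A=A, C=C, y_bar=np.zeros(7), n=3)
        O = observability_matrix(m)
        power = np.eye(3)
        for k in range(3):
            assert np.allclose(O[7 * k: 7 * (k + 1)], C @ power)
            power = power @ A


def _model_1d(direction):
    c = np.asarray(direction, dtype=float)[:, None]
    c = c / np.linalg.norm(c)
    return DTModel(A=np.array([[0.5]]), C=c, y_bar=np.zeros(len(direction)), n=1)


class TestMartinDistance:
    def test_identity_is_zero(self):
        y, _ = _noise_free_lds(n=2, p=9, seed=7, T=40)
        m = estimate_dt(y, 2)
        assert martin_distance(m, m) < 1e-9

    def test_orthogonal_subspaces_are_infinitely_far(self):
        assert martin_distance(_model_1d([1, 0]), _model_1d([0, 1])) == np.inf

    def test_one_dimensional_closed_form(self):
        """d^2 = -log cos^2(theta) for 1-d observability subspaces."""
        m60 = _model_1d([np.cos(np.pi / 3), np.sin(np.pi / 3)])
        d2 = martin_distance(_model_1d([1, 0]), m60)
        assert abs(d2 - (-np.log(0.25))) < 1e-9

    @pytest.mark.parametrize("seed", range(6))
    def test_symmetry_and_nonnegativity(self, seed):
        ya, ta = _noise_free_lds(n=2, p=9, seed=seed * 2 + 11, T=40)
        yb, tb = _noise_free_lds(n=2, p=9, seed=seed * 2 + 12, T=40)
        a, b = estimate_dt(ya, 2), estimate_dt(yb, 2)
        dab, dba = martin_distance(a, b), martin_distance(b, a)
        assert dab >= 0
        assert abs(dab - dba) < 1e-9

    def test_invariance_under_joint_basis_rotation(self):
        """Rotating C and conjugating A by the same orthogonal matrix leaves
        the observability subspace, hence the distance, unchanged."""
        rng = np.random.default_rng(11)
        y, truth = _noise_free_lds(n=2, p=9, seed=21, T=40)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rotated = DTModel(A=R.T @ truth.A @ R, C=truth.C @ R,
                          y_bar=truth.y_bar, n=2)
        assert martin_distance(truth, rotated) < 1e-9

    def test_order_mismatch_raises(self):
        with pytest.raises(OrderMismatch):
            martin_distance(_model_1d([1, 0]), _model_1d([1, 0, 0]))

    def test_bulk_pairwise_agrees_with_scalar_path(self, scene_field):
        """slogdet bulk distances equal the principal-angle scalar form."""
        Q = scene_field.orth_observability()
        idx = [0, 500, 1500, 2500]
        bulk = pairwise_sq_distances(Q[idx], Q[idx], cap=1e6)
        for i, a in enumerate(idx):
            for j, b in enumerate(idx):
                scalar = martin_distance(scene_field.flat_model(a),
                                         scene_field.flat_model(b), cap=1e6)
                assert abs(bulk[i, j] - scalar) < 1e-7 * (1 + scalar)


class TestField:
    def test_grid_shape_matches_stride_arithmetic(self, three_region_scene):
        seq, _ = three_region_scene
        f = compute_dt_field(seq, (0, 61), patch_side=5, n=2, stride=4)
        H = seq.shape[0]
        expected = int(np.ceil((H - 5 + 1) / 4))
        assert f.grid_shape[0] == expected

    def test_window_out_of_range(self, three_region_scene):
        seq, _ = three_region_scene
        with pytest.raises(WindowOutOfRange):
            compute_dt_field(seq, (0, seq.shape[2] + 5))

    def test_interior_models_cohere_within_region(self, scene_field, three_region_scene):
        """Within one texture region, pairwise distances are far below the
        distances to a different texture region."""
        from scipy import ndimage

        _, labels = three_region_scene
        Q = scene_field.orth_observability()
        idx_map = scene_field.pixel_model_index()
        rng = np.random.default_rng(0)
        picks = {}
        for lab in (1, 2):
            er = ndimage.binary_erosion(labels == lab, iterations=4)
            pos = np.argwhere(er)
            picks[lab] = idx_map[pos[:, 0], pos[:, 1]][
                rng.choice(len(pos), 15, replace=False)]
        within = pairwise_sq_distances(Q[picks[1]], Q[picks[1]])
        within = within[~np.eye(15, dtype=bool)]
        between = pairwise_sq_distances(Q[picks[1]], Q[picks[2]])
        assert within.mean() < between.mean()

    def test_border_pixels_inherit_nearest_model(self, scene_field):
        idx_map = scene_field.pixel_model_index()
        assert idx_map[0, 0] == 0  # clipped to the first grid node
        assert scene_field.model_at(0, 0) is None
        assert scene_field.model_at(2, 2) is not None

    def test_field_roundtrips_through_archive(self, scene_field, tmp_path):
        path = tmp_path / "field.npz"
        scene_field.save(path)
        loaded = type(scene_field).load(path)
        assert loaded.same_grid(scene_field)
        assert np.allclose(loaded.A, scene_field.A)
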