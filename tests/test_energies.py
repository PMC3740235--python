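"""Energy terms: motion, event, shape prior, topological."""

import numpy as np
import pytest

from dyntexseg import (
    EventMap,
    compute_dt_field,
    event_detection_energy,
    event_detection_map,
    fit_rectangle,
    make_event_pair,
    motion_segmentation_energy,
    shape_prior_energy,
    topological_energy,
    total_energy,
)
from dyntexseg.energies import Rectangle, shape_prior_map
from dyntexseg.errors import DegenerateMask, GridMismatch, MissingStats


class TestMotionEnergy:
    def _terms(self, shape, values):
        return {k: (np.full(shape, v), var) for k, (v, var) in values.items()}

    def test_matches_naive_loop(self, rng):
        partition = rng.integers(0, 3, size=(10, 10))
        terms = {}
        for k in range(3):
            terms[k] = (rng.random((10, 10)), 0.5 + rng.random())
        fast = motion_segmentation_energy(partition, terms)
        slow = 0.0
        for r in range(10):
            for c in range(10):
                sq, var = terms[int(partition[r, c])]
                slow += sq[r, c] / (2 * var) + 0.5 * np.log(var)
        assert fast == pytest.approx(slow, rel=1e-12)

    def test_relabel_symmetry_when_regions_identical(self, rng):
        """If all regions share one statistic, the energy is invariant
        under relabeling the partition."""
        sq = rng.random((8, 8))
        terms = {k: (sq, 1.3) for k in range(3)}
        p1 = rng.integers(0, 3, size=(8, 8))
        p2 = (p1 + 1) % 3
        assert motion_segmentation_energy(p1, terms) == pytest.approx(
            motion_segmentation_energy(p2, terms))

    def test_empty_region_contributes_nothing(self, rng):
        partition = np.zeros((5, 5), dtype=int)
        terms = {0: (rng.random((5, 5)), 1.0)}
        val = motion_segmentation_energy(partition, terms)
        terms[1] = (rng.random((5, 5)) * 100, 0.1)  # unused label
        assert motion_segmentation_energy(partition, terms) == val

    def test_missing_stats_raises(self):
        with pytest.raises(MissingStats):
            motion_segmentation_energy(np.ones((3, 3), dtype=int), {0: (np.zeros((3, 3)), 1.0)})

    def test_correct_partition_beats_single_flips(self, scene_field, three_region_scene):
        """On the default scene with truth statistics, the true partition has
        lower energy than any of a set of single-pixel label swaps."""
        from dyntexseg.dt_statistics import compute_region_statistics, region_log_likelihood

        _, labels = three_region_scene
        terms = {}
        for lab in range(3):
            st, sq = compute_region_statistics(
                scene_field, labels == lab, lab, np.random.default_rng(0), n_samples=40)
            terms[lab] = (sq, st.variance)
        base = motion_segmentation_energy(labels, terms)
        rng = np.random.default_rng(1)
        wins = 0
        trials = 0
        for _ in range(20):
            r, c = rng.integers(8, 56, size=2)
            flipped = labels.copy()
            flipped[r, c] = (flipped[r, c] + rng.integers(1, 3)) % 3
            if (flipped == labels).all():
                continue
            trials += 1
            wins += motion_segmentation_energy(flipped, terms) > base
        assert wins / trials >= 0.9


class TestEventDetection:
    def test_identical_windows_give_zero_map(self, three_region_scene):
        seq, _ = three_region_scene
        f = compute_dt_field(seq, (0, 41), patch_side=5, n=4, stride=2)
        em = event_detection_map(f, f)
        assert np.abs(em.delta).max() < 1e-9

    def test_changed_foreground_lights_up(self):
        seq0, seq1, fg = make_event_pair(seed=3)
        T = seq0.shape[2]
        f0 = compute_dt_field(seq0, (0, T), patch_side=5, n=4, stride=2)
        f1 = compute_dt_field(seq1, (0, T), patch_side=5, n=4, stride=2)
        em = event_detection_map(f0, f1)
        assert em.delta[fg].mean() > 2 * em.delta[~fg].mean()

    def test_grid_mismatch_raises(self, three_region_scene):
        seq, _ = three_region_scene
        f1 = compute_dt_field(seq, (0, 41), patch_side=5, n=4, stride=2)
        f2 = compute_dt_field(seq, (0, 41), patch_side=5, n=4, stride=4)
        with pytest.raises(GridMismatch):
            event_detection_map(f1, f2)

    def test_energy_closed_forms(self):
        delta = np.full((6, 6), 2.0)
        partition = np.zeros((6, 6), dtype=int)
        em = EventMap(delta=delta)
        # delta == mean, std 1 -> zero energy
        assert event_detection_energy(em, partition, {0: (2.0, 1.0)}) == pytest.approx(0.0)
        # doubling sigma with delta == mean adds |region| log 2
        assert event_detection_energy(em, partition, {0: (2.0, 2.0)}) == pytest.approx(
            36 * np.log(2.0))

    def test_energy_matches_loop(self, rng):
        delta = rng.random((7, 7))
        partition = rng.integers(0, 2, size=(7, 7))
        stats = {0: (0.3, 0.7), 1: (0.6, 1.2)}
        fast = event_detection_energy(EventMap(delta=delta), partition, stats)
        slow = 0.0
        for r in range(7):
            for c in range(7):
                mu, sd = stats[int(partition[r, c])]
                slow += (delta[r, c] - mu) ** 2 / (2 * sd ** 2) + np.log(sd)
        assert fast == pytest.approx(slow, rel=1e-12)


class TestRectangle:
    def test_axis_aligned_rectangle(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask[10:20, 5:45] = True  # 40 x 10 solid rectangle
        rect = fit_rectangle(mask)
        assert abs(rect.slope) < 1e-6
        assert rect.center[1] == pytest.approx(14.5, abs=0.01)  # centroid row (y)
        assert rect.center[0] == pytest.approx(24.5, abs=0.01)
        assert abs(rect.radius - 4.5) <= 0.5

    def test_rotated_rectangle_recovers_slope(self):
        yy, xx = np.mgrid[0:80, 0:80].astype(float)
        # band of half-width 5 about the 45-degree diagonal
        d = np.abs((yy - 40) - (xx - 40)) / np.sqrt(2)
        along = np.abs((yy - 40) + (xx - 40)) / np.sqrt(2)
        mask = (d <= 5) & (along <= 25)
        rect = fit_rectangle(mask)
        assert abs(rect.slope - 1.0) < 0.05

    def test_single_pixel_degenerate(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(DegenerateMask):
            fit_rectangle(mask)

    def test_collinear_degenerate(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 2:9] = True
        with pytest.raises(DegenerateMask):
            fit_rectangle(mask)

    def test_equivariant_to_quarter_rotation(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[20:28, 8:42] = True
        r0 = fit_rectangle(mask)
        r90 = fit_rectangle(np.rot90(mask))
        assert abs(abs(r0.angle - r90.angle) - np.pi / 2) < 0.05
        assert abs(r0.radius - r90.radius) < 0.5


class TestShapePrior:
    def _rect(self):
        return Rectangle(slope=0.0, center=(20.0, 15.0), radius=5.0, angle=0.0)

    def test_inside_band_costs_nothing(self):
        rect = self._rect()
        partition = np.zeros((30, 40), dtype=int)
        partition[12:18, :] = 1  # aorta strictly inside the band (rows 10..20)
        assert shape_prior_energy(partition, rect, sigma_sp=5.0) == 0.0

    def test_single_pixel_closed_form(self):
        rect = self._rect()
        sigma = 5.0
        pen = shape_prior_map(rect, (30, 40), sigma)
        # pixel at distance d has penalty exp(d^2 / 2 sigma^2) - 1
        d = pen[27, 20]
        dist = 27 - (15 + 5)  # rows beyond the band edge at 20
        assert d == pytest.approx(np.exp(dist ** 2 / (2 * sigma ** 2)) - 1, rel=1e-6)

    def test_empty_aorta_is_zero(self):
        partition = np.zeros((30, 40), dtype=int)
        assert shape_prior_energy(partition, self._rect(), 5.0) == 0.0


class TestTopological:
    def test_positive_phi1_everywhere_is_negligible(self):
        phi1 = np.full((20, 20), 10.0)
        phi2 = np.full((20, 20), -10.0)
        assert topological_energy(phi1, phi2) < 20 * 20 * 0.05

    def test_sharp_limit_counts_forbidden_pixels(self):
        phi1 = np.full((10, 10), 1e6)
        phi2 = np.full((10, 10), -1e6)
        phi1[:3, :3] = -1e6
        phi2[:3, :3] = 1e6  # 9 forbidden pixels
        assert topological_energy(phi1, phi2) == pytest.approx(9.0, abs=1e-3)

    def test_monotone_in_forbidden_set(self):
        rng = np.random.default_rng(0)
        phi1 = np.full((16, 16), 5.0)
        phi2 = np.full((16, 16), 5.0)
        vals = []
        for k in (2, 4, 6):
            p1 = phi1.copy()
            p1[:k, :k] = -5.0  # grow the forbidden set
            vals.append(topological_energy(p1, phi2))
        assert vals[0] < vals[1] < vals[2]


class TestTotalEnergy:
    def test_zero_weights(self):
        assert total_energy(3.0, 4.0, 5.0, 6.0, 0, 0, 0, 0) == 0.0

    def test_default_weights(self):
        # alpha=1, beta=0.5, gamma=0.1, zeta=1.25
        assert total_energy(1.0, 1.0, 1.0, 1.0) == pytest.approx(1 + 0.5 - 0.1 + 1.25)

    def test_linear_in_each_weight(self, rng):
        e = rng.random(4)
        base = total_energy(*e, 1.0, 0.5, 0.1, 1.25)
        bumped = total_energy(*e, 1.0 + 1e-3, 0.5, 0.1, 1.25)
        assert (bumped - base) == pytest.approx(1e-3 * e[0], rel=1e-6)
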