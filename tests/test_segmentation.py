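import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import sharpmax as sx
from sharpmax.errors import DegenerateMapError, NotApplicableError, SharpmaxError


class TestMoleculeMask:
    def test_finds_occupied_octant(self):
        # atoms fill one octant of the cell at protein packing density;
        # the detected region should be that octant
        rng = np.random.default_rng(1)
        n = 2800
        xyz = rng.uniform(2.0, 38.0, size=(n, 3))
        model = sx.AtomicModel(np.array(["C"] * n, dtype=object), xyz,
                               np.zeros(n), np.ones(n))
        m = sx.model_to_map(model, (80.0,) * 3, (80,) * 3, 3.0, 20.0)
        m = sx.VolumeGrid(m.values + rng.normal(scale=0.002, size=(80,) * 3),
                          m.cell)
        mask = sx.find_molecule_mask(m, 3.0)
        octant = np.zeros((80,) * 3, dtype=bool)
        octant[:40, :40, :40] = True
        jacc = (mask.mask & octant).sum() / (mask.mask | octant).sum()
        assert jacc >= 0.8
        # and essentially nothing is picked up far from the molecule
        assert mask.mask[~ndimage.binary_dilation(octant, iterations=6)].mean() < 0.02

    def test_pure_noise_keeps_the_guess(self):
        # a featureless variance field gives the update nothing to refine
        rng = np.random.default_rng(2)
        g = sx.VolumeGrid(rng.normal(size=(32, 32, 32)), np.full(3, 32.0))
        for guess in (0.1, 0.3, 0.5):
            mask = sx.find_molecule_mask(g, 3.0,
                                         initial_fraction_guesses=(guess,))
            assert mask.volume_fraction == pytest.approx(guess, abs=0.05)

    def test_offset_invariance(self, blob_fixture):
        region = blob_fixture["region"]
        m1 = sx.find_molecule_mask(region, 3.0)
        shifted = sx.VolumeGrid(region.values + 7.5, region.cell)
        m2 = sx.find_molecule_mask(shifted, 3.0)
        assert np.array_equal(m1.mask, m2.mask)

    def test_constant_map_rejected(self):
        g = sx.VolumeGrid(np.zeros((8, 8, 8)), np.full(3, 8.0))
        with pytest.raises(DegenerateMapError):
            sx.find_molecule_mask(g, 3.0)


class TestThresholdForVolume:
    @staticmethod
    def ramp_map():
        vals = np.arange(1.0, 1001.0).reshape(10, 10, 10)
        g = sx.VolumeGrid(vals, np.full(3, 10.0))
        mask = sx.MoleculeMask(np.ones((10, 10, 10), bool), 0.999, 4.5)
        return g, mask

    def test_selects_top_fraction_exactly(self):
        g, mask = self.ramp_map()
        t = sx.threshold_for_volume(g, mask, 0.2)
        assert t == 801.0
        assert (g.values >= t).sum() == 200

    def test_fraction_one_reaches_minimum(self):
        g, mask = self.ramp_map()
        t = sx.threshold_for_volume(g, mask, 0.9996)
        assert t <= g.values.min()

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(f1=st.floats(0.05, 0.9), f2=st.floats(0.05, 0.9))
    def test_monotone_in_fraction(self, f1, f2):
        g, mask = self.ramp_map()
        lo, hi = sorted((f1, f2))
        assert (sx.threshold_for_volume(g, mask, hi)
                <= sx.threshold_for_volume(g, mask, lo))

    def test_constant_density_rejected(self):
        g = sx.VolumeGrid(np.ones((10, 10, 10)), np.full(3, 10.0))
        mask = sx.MoleculeMask(np.ones((10, 10, 10), bool), 0.5, 4.5)
        with pytest.raises(DegenerateMapError):
            sx.threshold_for_volume(g, mask, 0.2)


def brute_force_contour_stats(inside):
    """Independent flood-fill + neighbour-scan oracle (6-connectivity)."""
    shape = inside.shape
    seen = np.zeros(shape, dtype=bool)
    n_regions = 0
    for start in zip(*np.nonzero(inside)):
        if seen[start]:
            continue
        n_regions += 1
        stack = [start]
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                               (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < shape[i] for i in range(3)) \
                        and inside[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
    surface = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if inside[x, y, z]:
                    continue
                for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    p = (x + dx, y + dy, z + dz)
                    if all(0 <= p[i] < shape[i] for i in range(3)) \
                            and inside[p]:
                        surface += 1
                        break
    return n_regions, surface


class TestContourStats:
    def test_single_interior_voxel(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 1.0
        stats = sx.contour_stats(sx.VolumeGrid(v, np.full(3, 5.0)), 0.5)
        assert stats.n_regions == 1
        assert stats.surface_area == 6

    def test_edge_touching_voxels_are_separate_regions(self):
        v = np.zeros((5, 5, 5))
        v[1, 1, 1] = v[2, 2, 1] = 1.0  # share an edge, not a face
        stats = sx.contour_stats(sx.VolumeGrid(v, np.full(3, 5.0)), 0.5)
        assert stats.n_regions == 2
        # under 26-connectivity they merge
        stats26 = sx.contour_stats(sx.VolumeGrid(v, np.full(3, 5.0)), 0.5,
                                   connectivity=26)
        assert stats26.n_regions == 1

    def test_empty_contour_gives_zeros(self):
        v = np.zeros((5, 5, 5))
        stats = sx.contour_stats(sx.VolumeGrid(v, np.full(3, 5.0)), 0.5)
        assert stats.n_regions == 0 and stats.surface_area == 0

    def test_matches_flood_fill_oracle_on_random_grids(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            inside = rng.random((6, 6, 6)) < rng.uniform(0.1, 0.7)
            g = sx.VolumeGrid(inside.astype(float), np.full(3, 6.0))
            stats = sx.contour_stats(g, 0.5)
            n_ref, sa_ref = brute_force_contour_stats(inside)
            assert stats.n_regions == n_ref
            assert stats.surface_area == sa_ref


class TestAdjustedSurfaceArea:
    def test_zero_scale_returns_surface_area(self):
        stats = sx.ContourStats(0.5, 40, 120)
        assert sx.adjusted_surface_area(stats, 0.0) == 120.0

    def test_arithmetic(self):
        stats = sx.ContourStats(0.5, 40, 120)
        assert sx.adjusted_surface_area(stats, 3.0) == 0.0

    def test_linear_in_scale(self):
        stats = sx.ContourStats(0.5, 7, 100)
        vals = [sx.adjusted_surface_area(stats, c) for c in (0.0, 1.0, 2.0)]
        assert vals[0] - vals[1] == pytest.approx(vals[1] - vals[2])


class TestCScaleCalibration:
    def test_closed_form_two_endpoint_solution(self):
        sa = [200.0, 150.0, 80.0]
        nr = [50, 30, 10]
        c = sx.calibrate_c_scale(sa, nr)
        assert c == 3.0
        assert sa[0] - c * nr[0] == pytest.approx(sa[-1] - c * nr[-1])
        assert sa[0] - c * nr[0] == pytest.approx(50.0)

    def test_identical_extremes_rejected(self):
        with pytest.raises(NotApplicableError):
            sx.calibrate_c_scale([100.0, 90.0, 100.0], [5, 4, 5])

    def test_endpoint_equality_on_scanned_trace(self, blob_trace):
        sa_adj = blob_trace.sa_adjusted
        assert sa_adj[0] == pytest.approx(sa_adj[-1], abs=1e-6)


class TestApplicability:
    def test_symmetric_tent_is_applicable(self):
        b = [0.0, 25.0, 50.0, 75.0, 100.0]
        sa = [0.0, 10.0, 20.0, 10.0, 0.0]
        ok, signal, noise = sx.applicability_check(b, sa)
        assert ok
        assert signal == pytest.approx(20.0)
        # kink at the apex is the only interpolation residual
        assert noise == pytest.approx(np.sqrt(100.0 / 3.0))

    def test_dip_below_endpoints_at_probe_rejected(self):
        b = [-100.0, -50.0, 0.0, 50.0, 100.0, 300.0]
        sa = [50.0, 80.0, 60.0, 30.0, 70.0, 50.0]
        ok, _, _ = sx.applicability_check(b, sa, b_probe=50.0)
        assert not ok

    def test_hand_computed_five_point_trace(self):
        b = [0.0, 25.0, 50.0, 75.0, 100.0]
        sa = [10.0, 30.0, 25.0, 28.0, 10.0]
        ok, signal, noise = sx.applicability_check(b, sa)
        # endpoint = 10, max = 30 -> signal 20; interpolation residuals
        # 12.5, -4, 10.5 -> rms sqrt(94.1667) = 9.70395
        assert signal == pytest.approx(20.0)
        assert noise == pytest.approx(9.70395, abs=1e-4)
        assert not ok  # 20 / 9.7 is below the 3:1 default

    def test_short_trace_rejected(self):
        with pytest.raises(SharpmaxError):
            sx.applicability_check([0.0, 50.0, 100.0], [0.0, 1.0, 0.0])
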