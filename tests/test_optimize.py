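import numpy as np
import pytest

import sharpmax as sx
from sharpmax.errors import DegenerateMapError, SharpmaxError
from sharpmax.optimize import _argmax_prefer_last


class TestCCStar:
    def test_perfect_halfmap_agreement(self):
        assert sx.cc_star_from_halfmap_fsc(1.0) == 1.0

    def test_zero_correlation(self):
        assert sx.cc_star_from_halfmap_fsc(0.0) == 0.0

    def test_half_correlation_closed_form(self):
        # sqrt(2 * 0.5 / 1.5) evaluated by hand
        assert sx.cc_star_from_halfmap_fsc(0.5) == pytest.approx(0.816497,
                                                                 abs=1e-6)

    def test_negative_fsc_clipped_to_zero(self):
        assert sx.cc_star_from_halfmap_fsc(-0.4) == 0.0

    def test_monotone_and_bounded(self):
        cc = np.linspace(-0.9, 1.0, 50)
        out = sx.cc_star_from_halfmap_fsc(cc)
        assert np.all(np.diff(out) >= 0)
        assert np.all((out >= 0) & (out <= 1))


class TestScanSharpening:
    def test_trace_shape_on_noisy_map(self, blob_fixture, blob_trace):
        t = blob_trace
        # detail: surface area decreases as the map is blurred
        sa = t.surface_area
        violations = np.sum(np.diff(sa) > 0)
        assert violations <= 0.05 * len(sa)
        # fragmentation: region count spikes at strongly negative B
        assert t.n_regions[0] > 5 * t.n_regions[len(t.n_regions) // 2]
        # the adjusted surface area peaks strictly inside the scan
        idx = int(np.argmax(t.sa_adjusted))
        assert 0 < idx < len(t.sa_adjusted) - 1
        assert t.applicable

    def test_fitted_b_tracks_candidates(self, blob_trace):
        # after sharpening to target B the refit lands near the target
        sel = slice(2, -2)
        assert np.allclose(blob_trace.b_fitted[sel],
                           blob_trace.b_candidate[sel], atol=25.0)

    def test_scale_invariance_of_chosen_b(self, blob_fixture):
        region = blob_fixture["region"]
        doubled = sx.VolumeGrid(2.0 * region.values, region.cell)
        _, t1 = sx.auto_sharpen_sa(region, 3.0)
        _, t2 = sx.auto_sharpen_sa(doubled, 3.0)
        assert t1.chosen_b == t2.chosen_b

    def test_declined_returns_input_unchanged(self):
        # a single smooth Gaussian blob carries no interior optimum
        model = sx.AtomicModel(np.array(["C"], dtype=object),
                               np.array([[16.0, 16.0, 16.0]]),
                               np.zeros(1), np.ones(1))
        g = sx.model_to_map(model, (32.0,) * 3, (32,) * 3, 3.0, 60.0)
        out, trace = sx.auto_sharpen_sa(g, 3.0)
        assert not trace.applicable
        assert out is g

    def test_tie_break_prefers_higher_b(self):
        assert _argmax_prefer_last(np.array([1.0, 3.0, 3.0, 2.0])) == 2


class TestKurtosisSharpening:
    def test_trace_column_matches_direct_evaluation(self, blob_fixture):
        region = blob_fixture["region"]
        out, trace = sx.auto_sharpen_kurtosis(region, 3.0)
        assert trace.chosen_b == trace.b_candidate[
            _argmax_prefer_last(trace.kurtosis)]
        # re-sharpen independently at the chosen target and compare
        assert sx.kurtosis(out) == pytest.approx(
            trace.kurtosis[list(trace.b_candidate).index(trace.chosen_b)],
            rel=1e-6)

    def test_agrees_with_surface_area_optimum(self, blob_fixture, blob_trace):
        region = blob_fixture["region"]
        _, tk = sx.auto_sharpen_kurtosis(region, 3.0)
        assert abs(tk.chosen_b - blob_trace.chosen_b) <= 60.0

    def test_constant_map_rejected(self):
        g = sx.VolumeGrid(np.ones((12, 12, 12)), np.full(3, 12.0))
        with pytest.raises(DegenerateMapError):
            sx.auto_sharpen_kurtosis(g, 3.0)


class TestHalfmapSharpen:
    def test_noise_free_restores_model_amplitudes(self, blob_fixture):
        m = blob_fixture["map"]
        model = blob_fixture["model"]
        full = sx.map_to_coeffs(m, d_min=3.0)
        out = sx.halfmap_sharpen(full, m, m, model, 3.0)
        shells = sx.resolution_shells(out, 12)
        mod = sx.model_map_coeffs(model, m.cell, m.grid_shape, 3.0, 0.0)
        ref = sx.resolution_shells(mod, 12)
        assert np.allclose(shells.mean_amplitude, ref.mean_amplitude,
                           rtol=0.02)

    def test_noisy_halves_downweight_high_resolution(self, blob_fixture):
        m = blob_fixture["map"]
        model = blob_fixture["model"]
        h1, h2 = sx.make_half_maps(m, 0.05, seed=9)
        full = sx.map_to_coeffs(m, d_min=3.0)
        out = sx.halfmap_sharpen(full, h1, h2, model, 3.0)
        shells = out._shells
        assert shells.cc_star[-1] < 0.999  # high-res shell damped below R
        assert np.all(shells.cc_star * shells.ratio >= 0)
        assert shells.fsc[0] > shells.fsc[-1]

    def test_phases_untouched(self, blob_fixture):
        m = blob_fixture["map"]
        full = sx.map_to_coeffs(m, d_min=3.0)
        out = sx.halfmap_sharpen(full, m, m, blob_fixture["model"], 3.0)
        sel = (np.abs(full.data) > 1e-10) & (np.abs(out.data) > 1e-10)
        dphase = np.angle(out.data[sel]) - np.angle(full.data[sel])
        assert np.abs(dphase).max() <= 1e-12

    def test_mismatched_grids_rejected(self, blob_fixture):
        m = blob_fixture["map"]
        small = sx.VolumeGrid(m.values[:20, :20, :20], m.cell * 20 / 44)
        with pytest.raises(SharpmaxError):
            sx.halfmap_sharpen(sx.map_to_coeffs(m, d_min=3.0), small, m,
                               blob_fixture["model"], 3.0)


class TestModelSharpen:
    def test_default_error_follows_quarter_resolution_rule(self):
        err = sx.ModelErrorParams.from_resolution(3.5)
        assert err.rmse == pytest.approx(0.875)
        # B_eff = 8 pi^2 rmse^2 / 3 evaluated by hand
        assert err.b_eff == pytest.approx(20.150, abs=1e-3)

    def test_zero_rmse_means_no_correction(self, blob_fixture):
        m = blob_fixture["map"]
        model = blob_fixture["model"]
        full = sx.map_to_coeffs(m, d_min=3.0)
        out = sx.model_sharpen(full, model, 3.0, err=sx.ModelErrorParams(0.0))
        sh = out._shells
        assert np.allclose(sh.cc_star, np.clip(sh.fsc, 0.0, 1.0))

    def test_restores_zero_b_falloff(self, blob_fixture):
        # the map was blurred by a known B; model-based rescaling should
        # return it to the zero-B reference falloff
        m = blob_fixture["map"]
        model = blob_fixture["model"]
        full = sx.map_to_coeffs(m, d_min=3.0)
        out = sx.model_sharpen(full, model, 3.0)
        mod = sx.model_map_coeffs(model, m.cell, m.grid_shape, 3.0, 0.0)
        shells = sx.resolution_shells(out, 12)
        b_out = sx.fit_isotropic_b(out, shells)
        b_ref = sx.fit_isotropic_b(mod, sx.resolution_shells(mod, 12))
        assert b_out == pytest.approx(b_ref, abs=10.0)


class TestMapModelCC:
    def test_self_correlation_is_one(self, blob_fixture):
        truth = blob_fixture["truth"]
        model = blob_fixture["model"]
        assert sx.map_model_cc_zero_b(truth, model, 3.0) == pytest.approx(
            1.0, abs=1e-6)

    def test_negated_map_gives_minus_one(self, blob_fixture):
        truth = blob_fixture["truth"]
        neg = sx.VolumeGrid(-truth.values, truth.cell)
        cc = sx.map_model_cc_zero_b(neg, blob_fixture["model"], 3.0)
        assert cc == pytest.approx(-1.0, abs=1e-6)

    def test_cc_increases_as_blur_is_removed(self, blob_fixture):
        model = blob_fixture["model"]
        ccs = []
        for b in (200.0, 100.0, 50.0, 0.0):
            m = sx.model_to_map(model, (44.0,) * 3, (44,) * 3, 3.0, b)
            ccs.append(sx.map_model_cc_zero_b(m, model, 3.0))
        assert all(np.diff(ccs) > 0)
        assert 0 < ccs[0] < 1


class TestModelBasedSharpening:
    def test_recovers_zero_b_truth(self):
        fx = sx.make_map(sx.SyntheticSpec(seed=6, true_b=100.0,
                                          noise_sigma=0.0, layout="blob"))
        region, model = sx.extract_region_near_model(fx["map"], fx["model"],
                                                     5.0)
        out, trace = sx.auto_sharpen_model(region, model, 3.0)
        assert abs(trace.chosen_b) <= 20.0  # within one scan step of zero
        # unimodal correlation profile on the noise-free fixture
        d = np.diff(trace.cc)
        d = d[d != 0]
        assert np.sum(np.diff(np.sign(d)) != 0) <= 1
        # consistency with a direct per-candidate evaluation
        cc_direct = sx.map_model_cc_zero_b(out, model, 3.0)
        assert cc_direct == pytest.approx(trace.cc.max(), abs=1e-6)
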