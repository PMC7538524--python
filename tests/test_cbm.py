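"""Line-profile sampling, the blurred three-level fit, and map smoothing."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

import cortimap as cm
from cortimap.cbm import (CBMFit, CBMParams, LineProfile, estimate_global_density,
                          fit_profile, map_thickness, model_profile,
                          sample_profile, smooth_map)
from cortimap.imaging_io import CTVolume

from conftest import make_tube_surface

Y0, Y1, Y2 = 40.0, 1500.0, 150.0


def synth_profile(t, sigma, noise_sd=0.0, x0=0.0, step=0.25, half=9.0, seed=0):
    x = np.arange(-int(half / step), int(half / step) + 1) * step
    v = model_profile(x, Y0, Y1, Y2, x0, x0 + t, max(sigma, 1e-6))
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0, noise_sd, x.shape)
    return LineProfile(positions=x, values=v)


class TestSampleProfile:
    def test_constant_volume_constant_profile(self):
        vol = CTVolume(scalars=np.full((30, 30, 30), 100.0), spacing=(1, 1, 1))
        prof = sample_profile(vol, [15, 15, 15], [0, 0, 1], half_length=5)
        assert np.allclose(prof.values, 100.0)
        assert prof.positions[0] == -5.0 and prof.positions[-1] == 5.0

    def test_planar_cortex_matches_closed_form_erf_model(self):
        # slab geometry: 3-D Gaussian blur of a plane-layered volume is exactly
        # the 1-D convolved model, so the sampled profile must match it closely
        sigma, t = 0.6, 5.0
        step = 0.1
        n = 400
        xs = (np.arange(n) - n / 2) * step  # fine grid along axis 0
        line = np.where(xs < 0, Y0, np.where(xs < t, Y1, Y2))
        line = gaussian_filter1d(line, sigma / step)
        # the discrete step's effective edges sit half a fine-grid cell early
        x0_eff = -step / 2
        vol = CTVolume(scalars=np.broadcast_to(line[:, None, None],
                                               (n, 40, 40)).copy(),
                       spacing=(step, 1.0, 1.0),
                       origin=(-n / 2 * step, 0.0, 0.0))
        prof = sample_profile(vol, [0.0, 20.0, 20.0], [-1.0, 0.0, 0.0],
                              half_length=8.0, step=0.25)
        expected = model_profile(prof.positions, Y0, Y1, Y2, x0_eff,
                                 x0_eff + t, sigma)
        assert np.max(np.abs(prof.values - expected)) < 2.0

    def test_vertex_outside_volume_rejected(self):
        vol = CTVolume(scalars=np.zeros((10, 10, 10)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            sample_profile(vol, [50, 5, 5], [0, 0, 1])

    def test_long_line_clipped_and_flagged(self):
        vol = CTVolume(scalars=np.zeros((10, 10, 10)), spacing=(1, 1, 1))
        with pytest.warns(UserWarning, match="clipped"):
            prof = sample_profile(vol, [5, 5, 5], [0, 0, 1], half_length=20)
        assert prof.clipped
        assert prof.positions[0] >= -5.0 and prof.positions[-1] <= 5.0


class TestFitProfile:
    def test_recovers_generating_parameters_noiseless(self):
        fit = fit_profile(synth_profile(t=5.0, sigma=0.6))
        assert fit.ok
        assert fit.thickness == pytest.approx(5.0, abs=0.02)
        assert fit.y0 == pytest.approx(Y0, abs=1.0)
        assert fit.y1 == pytest.approx(Y1, abs=5.0)
        assert fit.y2 == pytest.approx(Y2, abs=1.0)
        assert fit.sigma == pytest.approx(0.6, abs=0.02)
        assert fit.x0 == pytest.approx(0.0, abs=0.02)

    def test_sharp_step_profile_degenerate_blur(self):
        # edges placed exactly on sample points; near-zero blur
        fit = fit_profile(synth_profile(t=5.0, sigma=0.1, x0=-1.0))
        assert fit.ok
        assert fit.thickness == pytest.approx(5.0, abs=1e-3)

    def test_thin_cortex_needs_density_constraint(self):
        prof = synth_profile(t=1.0, sigma=0.8)
        free = fit_profile(prof)
        constrained = fit_profile(prof, density_constraint=Y1)
        err_con = abs(constrained.thickness - 1.0)
        assert free.thickness > 1.0  # free fit biased upward (blur >> t)
        assert err_con <= 0.3
        assert err_con < abs(free.thickness - 1.0) + 1e-9

    def test_recovery_grid_mae_within_claimed_accuracy(self):
        # headline property: t 1..10 mm x sigma {0.4, 0.8} x noise {0, 20} HU
        errors = []
        for t in range(1, 11):
            for sigma in (0.4, 0.8):
                for noise in (0.0, 20.0):
                    for rep in range(3):
                        # half-length 12 mm so the endosteal edge of the
                        # thickest walls is still straddled by the profile
                        prof = synth_profile(t=float(t), sigma=sigma,
                                             noise_sd=noise, half=12.0,
                                             seed=1000 + 101 * t + rep)
                        fit = fit_profile(prof, density_constraint=Y1)
                        assert fit.ok
                        errors.append(abs(fit.thickness - t))
        assert np.mean(errors) <= 0.3

    def test_profile_missing_an_edge_fails_cleanly(self):
        x = np.arange(0.5, 9.0, 0.25)  # does not straddle the outer edge
        prof = LineProfile(positions=x, values=np.full_like(x, Y1))
        assert fit_profile(prof).status == "failed"


class TestGlobalDensity:
    @staticmethod
    def _fit(y1, t, sigma=0.5, status="free-fit"):
        return CBMFit(Y0, y1, Y2, 0.0, t, sigma, 1.0, status)

    def test_median_over_thick_fits_within_2pct(self):
        fits = [self._fit(1500 + d, t=6.0) for d in np.linspace(-30, 30, 80)]
        fits += [self._fit(900.0, t=1.0)]  # thin: excluded by the 3-sigma cutoff
        assert estimate_global_density(fits) == pytest.approx(1500.0, rel=0.02)

    def test_contaminated_fits_barely_move_estimate(self):
        rng = np.random.default_rng(2)
        fits = [self._fit(1500 + rng.normal(0, 20), t=6.0) for _ in range(90)]
        clean = estimate_global_density(fits)
        fits += [self._fit(3000.0, t=6.0) for _ in range(10)]  # 10% outliers
        contaminated = estimate_global_density(fits)
        assert abs(contaminated - clean) / clean < 0.02

    def test_all_failed_raises(self):
        fits = [self._fit(1500.0, t=6.0, status="failed")] * 100
        with pytest.raises(RuntimeError, match="min_fits"):
            estimate_global_density(fits)


class TestMapThickness:
    def test_noisy_phantom_map_accuracy(self, noisy_phantom, noisy_surface,
                                        noisy_thickness_map):
        _, _, truth = noisy_phantom
        tmap = noisy_thickness_map
        assert len(tmap) == noisy_surface.n_vertices
        assert tmap.valid_fraction >= 0.95
        assert tmap.global_density == pytest.approx(1500.0, rel=0.02)
        tt = truth.thickness_at(noisy_surface.vertices)
        sel = tmap.valid
        mae = np.mean(np.abs(tmap.thickness[sel] - tt[sel]))
        assert mae <= 0.3

    def test_noiseless_unblurred_phantom_near_ideal(self, annulus_phantom,
                                                    annulus_surface):
        _, volume, truth = annulus_phantom
        tmap = map_thickness(volume, annulus_surface, CBMParams())
        tt = truth.thickness_at(annulus_surface.vertices)
        sel = tmap.valid
        assert sel.mean() >= 0.95
        mae = np.mean(np.abs(tmap.thickness[sel] - tt[sel]))
        assert mae < 0.1


class TestSmoothing:
    def _map(self, surf, values, valid=None):
        if valid is None:
            valid = ~surf.is_cap
        return cm.ThicknessMap(thickness=values, valid=valid)

    def test_constant_map_unchanged(self):
        surf = make_tube_surface()
        values = np.full(surf.n_vertices, 4.2)
        out = smooth_map(surf, self._map(surf, values, np.ones(surf.n_vertices, bool)))
        np.testing.assert_allclose(out.thickness, 4.2, atol=1e-12)

    def test_zero_radius_is_identity(self):
        surf = make_tube_surface()
        rng = np.random.default_rng(0)
        values = rng.uniform(2, 8, surf.n_vertices)
        out = smooth_map(surf, self._map(surf, values), radius=0.0)
        np.testing.assert_array_equal(out.thickness, values)

    def test_spike_reduced_at_default_radius(self):
        surf = make_tube_surface()
        values = np.full(surf.n_vertices, 5.0)
        spike_at = surf.n_vertices // 2
        values[spike_at] += 10.0
        out = smooth_map(surf, self._map(surf, values,
                                         np.ones(surf.n_vertices, bool)),
                         radius=3.0)
        assert out.thickness[spike_at] - 5.0 <= 5.0  # >= 50% reduction

    def test_mean_conserved_on_fully_valid_map(self):
        surf = make_tube_surface()
        rng = np.random.default_rng(1)
        values = rng.uniform(2, 8, surf.n_vertices)
        out = smooth_map(surf, self._map(surf, values,
                                         np.ones(surf.n_vertices, bool)),
                         radius=3.0)
        assert out.thickness.mean() == pytest.approx(values.mean(), rel=1e-9)

    def test_invalid_vertices_imputed_from_neighbours(self):
        surf = make_tube_surface()
        values = np.full(surf.n_vertices, 6.0)
        valid = np.ones(surf.n_vertices, bool)
        dead = np.arange(10, 40)
        values[dead] = np.nan
        valid[dead] = False
        out = smooth_map(surf, self._map(surf, values, valid), radius=2.0)
        assert np.all(np.isfinite(out.thickness))
        np.testing.assert_allclose(out.thickness, 6.0, atol=1e-9)
        assert not out.valid[dead].any()  # flags preserved
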