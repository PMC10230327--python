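import numpy as np
import pytest

import clearwing as cw
from clearwing.errors import ValidationError
from clearwing.wing_models import DEFAULT_REGISTRY, fit_membrane_thicknesses


class TestRegistry:
    def test_printed_defaults(self):
        reg = DEFAULT_REGISTRY
        assert (reg.h_de.value, reg.h_m.value, reg.h_ve.value) == (436.0, 194.0, 412.0)
        assert (reg.h_n.value, reg.d_n.value, reg.pitch.value) == (142.0, 135.0, 300.0)
        assert (reg.h_mr.value, reg.w_mr.value, reg.gap_mr.value) == (45.0, 62.0, 58.0)
        assert reg.h_LL.value == 225.0
        assert reg.n_chitin == 1.56 and reg.n_pigment_real == 1.74

    def test_uncertainty_metadata_retained(self):
        assert DEFAULT_REGISTRY.h_de.sd == 20.0
        assert DEFAULT_REGISTRY.h_m.sd == 7.0

    def test_overrides_leave_original_untouched(self):
        reg2 = DEFAULT_REGISTRY.with_overrides(h_de=450.0)
        assert reg2.h_de.value == 450.0
        assert reg2.h_de.sd == 20.0  # sd carried over
        assert DEFAULT_REGISTRY.h_de.value == 436.0

    def test_registry_is_immutable(self):
        with pytest.raises(Exception):
            DEFAULT_REGISTRY.n_chitin = 1.6  # type: ignore[misc]


class TestBuildMembrane:
    def test_three_layer_flat_stack_geometry(self, membrane_flat):
        layers = membrane_flat.stack.layers
        assert [l.thickness_nm for l in layers] == [436.0, 194.0, 412.0]
        assert float(layers[0].material.n(550)) == 1.56
        assert complex(layers[1].material.index(550)) == pytest.approx(1.74 + 0.01j)

    def test_one_layer_total_thickness(self):
        m = cw.build_membrane("one-layer", "none")
        assert m.stack.total_thickness_nm() == pytest.approx(1042.0)
        assert len(m.stack.layers) == 1
        assert float(m.stack.layers[0].material.n(550)) == 1.56

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValidationError):
            cw.build_membrane("two-layer")  # type: ignore[arg-type]

    def test_corrugated_raster_draws_half_ellipses(self, membrane_nipples):
        r = membrane_nipples.raster(5.0, mode="corrugated")
        nz, nx = r.n_map.shape
        assert nx == 60  # one 300 nm period at dx = 5
        nip_rows = int(round(142.0 / 5.0))
        # base row fill close to 135/300, tip row much sparser
        base_fill = (r.n_map[nip_rows - 1] > 1.0).mean()
        tip_fill = (r.n_map[0] > 1.0).mean()
        assert base_fill == pytest.approx(0.45, abs=0.05)
        assert tip_fill < 0.2
        # both faces: the bottom nipple block mirrors the top one
        top = r.n_map[:nip_rows]
        bottom = r.n_map[-nip_rows:]
        assert np.array_equal(top, bottom[::-1])

    def test_graded_raster_matches_stack_thickness(self, membrane_nipples):
        r = membrane_nipples.raster(5.0, mode="graded")
        expected = membrane_nipples.stack.total_thickness_nm()
        assert r.n_map.shape[0] * 5.0 == pytest.approx(expected, abs=2.5)

    def test_symmetric_membrane_reproduces_extrema(self, lam_visible):
        """Equal exocuticle thicknesses (same total) barely move the extrema."""
        sym = DEFAULT_REGISTRY.with_overrides(h_de=424.0, h_ve=424.0)
        R_sym, _, _ = cw.tmm_spectrum(cw.build_membrane("three-layer", "none", sym).stack, lam_visible)
        R_def, _, _ = cw.tmm_spectrum(cw.build_membrane("three-layer", "none").stack, lam_visible)
        pos_sym = [e.wavelength_nm for e in cw.find_extrema(R_sym, (420, 680))]
        pos_def = [e.wavelength_nm for e in cw.find_extrema(R_def, (420, 680))]
        assert len(pos_sym) == len(pos_def)
        assert max(abs(a - b) for a, b in zip(pos_sym, pos_def)) <= 10.0


class TestInterridge:
    def test_stack_geometry(self):
        m = cw.build_interridge()
        assert [l.thickness_nm for l in m.stack.layers] == [45.0, 225.0]
        assert float(m.stack.layers[1].material.n(550)) == 1.56

    def test_single_prominent_peak_near_520(self, lam_visible):
        R, _, _ = cw.tmm_spectrum(cw.build_interridge().stack, lam_visible)
        maxima = [e for e in cw.find_extrema(R, (400, 700)) if e.type == "max"]
        assert len(maxima) == 1
        assert abs(maxima[0].wavelength_nm - 520.0) <= 20.0

    def test_wider_gap_blue_shifts_peak(self, lam_visible):
        peaks = dict(cw.microrib_spacing_sweep([58.0, 90.0]))
        assert peaks[90.0] < peaks[58.0]

    def test_bare_lamina_regression(self, lam_visible):
        """Removing the microrib layer leaves the bare 225 nm lamina."""
        bare = cw.Stack(layers=(cw.Layer(cw.CHITIN, 225.0),))
        R, _, _ = cw.tmm_spectrum(bare, lam_visible)
        peak = cw.peak_wavelength(R, (400, 700))
        # quarter-wave condition of the slab: 2nd/(m+1/2) with m=1 -> 468 nm
        assert peak == pytest.approx(468.0, abs=3.0)


class TestRidge:
    def test_energy_conservation(self, lam_visible):
        R, T, A = cw.tmm_spectrum(cw.build_ridge(90.0, 120.0).stack, lam_visible)
        assert np.allclose(R.value + T.value + A.value, 1.0, atol=1e-9)
        assert np.allclose(A.value, 0.0, atol=1e-9)  # all-lossless ridge

    def test_vanishing_air_gap_merges_chitin_layers(self, lam_visible):
        merged = cw.Stack(layers=(cw.Layer(cw.CHITIN, 85.0 + 225.0),))
        near = cw.build_ridge(1e-3, 85.0)
        R1, _, _ = cw.tmm_spectrum(merged, lam_visible)
        R2, _, _ = cw.tmm_spectrum(near.stack, lam_visible)
        assert np.abs(R1.value - R2.value).max() < 1e-4

    def test_regression_fixture_peak_near_410(self, lam_visible):
        # pair located by parameter scan; frozen as a regression anchor
        R, _, _ = cw.tmm_spectrum(cw.build_ridge(30.0, 85.0).stack, lam_visible)
        assert cw.peak_wavelength(R, (400, 700)) == pytest.approx(411.0, abs=1.0)

    def test_missing_parameters_raise(self):
        with pytest.raises(ValidationError):
            cw.build_ridge(None, 85.0)
        with pytest.raises(ValidationError):
            cw.build_ridge(30.0, None)


class TestMicroribSpacingSweep:
    def test_blue_shift_monotonicity(self):
        sweep = cw.microrib_spacing_sweep([40.0, 58.0, 80.0, 120.0])
        peaks = [p for _, p in sweep]
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))

    def test_printed_gap_peak(self):
        (_, peak), = cw.microrib_spacing_sweep([58.0])
        assert 500.0 <= peak <= 540.0

    def test_identical_gaps_identical_peaks(self):
        sweep = cw.microrib_spacing_sweep([58.0, 58.0])
        assert sweep[0][1] == sweep[1][1]

    def test_invalid_gaps(self):
        with pytest.raises(ValidationError):
            cw.microrib_spacing_sweep([-5.0])
        with pytest.raises(ValidationError):
            cw.microrib_spacing_sweep([80.0, 40.0])


class TestThicknessFit:
    lam = cw.wavelength_grid(400, 700, 5.0)

    def _target(self, reg):
        R, _, _ = cw.tmm_spectrum(cw.build_membrane("three-layer", "none", reg).stack, self.lam)
        return R

    def test_noiseless_recovery_within_2nm(self):
        true = DEFAULT_REGISTRY.with_overrides(h_de=445.0, h_m=190.0, h_ve=405.0)
        fitted, residual = fit_membrane_thicknesses(self._target(true))
        assert abs(fitted.h_de.value - 445.0) < 2.0
        assert abs(fitted.h_m.value - 190.0) < 2.0
        assert abs(fitted.h_ve.value - 405.0) < 2.0
        assert residual < 1e-6

    def test_noisy_recovery_within_10nm(self):
        true = DEFAULT_REGISTRY.with_overrides(h_de=445.0, h_m=190.0, h_ve=405.0)
        noisy = cw.synth_measured_spectrum(
            self._target(true), cw.GeneratorConfig(seed=7, gain_sd=0.01, additive_sd=0.0)
        )
        fitted, _ = fit_membrane_thicknesses(noisy)
        assert abs(fitted.h_de.value - 445.0) < 10.0
        assert abs(fitted.h_m.value - 190.0) < 10.0
        assert abs(fitted.h_ve.value - 405.0) < 10.0

    def test_pinned_bounds_return_defaults(self):
        target = self._target(DEFAULT_REGISTRY)
        bounds = {n: (getattr(DEFAULT_REGISTRY, n).value,) * 2 for n in ("h_de", "h_m", "h_ve")}
        fitted, residual = fit_membrane_thicknesses(target, bounds=bounds)
        assert fitted.h_de.value == 436.0
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_empty_bounds_rejected(self):
        with pytest.raises(ValidationError):
            fit_membrane_thicknesses(self._target(DEFAULT_REGISTRY), bounds={"h_de": (0, 0)})

    def test_fit_never_worse_than_defaults(self):
        noisy = cw.synth_measured_spectrum(
            self._target(DEFAULT_REGISTRY), cw.GeneratorConfig(seed=3)
        )
        _, residual = fit_membrane_thicknesses(noisy)
        R_def = self._target(DEFAULT_REGISTRY)
        base = float(np.sqrt(np.mean((R_def.value - noisy.value) ** 2)))
        assert residual <= base + 1e-12
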