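"""Z-spectrum fitting, B0 estimation, asymmetry and enhancement maps."""

import numpy as np
import pytest

from cestpipe import (
    MapKind,
    SaturationParams,
    ZSpectrumStack,
    compute_delta_st,
    compute_enh_map,
    compute_st,
    compute_st_map,
    default_schedule,
    estimate_b0_shift,
    fit_zspectrum,
    water_pool,
)
from cestpipe.phantom import region_spectrum, region_truth_st
from cestpipe.zspec import ContrastMap

from conftest import small_spec

OFFS = default_schedule().saturation_offsets


def lorentzian(x, depth=0.8, width=2.0, center=0.0):
    return 1.0 - depth / (1.0 + ((x - center) / (width / 2)) ** 2)


class TestFit:
    def test_interpolating_fit_matches_analytic_curve(self):
        f = fit_zspectrum(lorentzian(OFFS), OFFS, smoothing=0.0)
        x = np.arange(-6.0, 6.0 + 1e-9, 0.01)
        rel = np.abs(f(x) - lorentzian(x)) / lorentzian(x)
        assert rel.max() < 0.005

    def test_zero_smoothing_passes_through_samples(self):
        y = lorentzian(OFFS) + 0.01 * np.sin(3 * OFFS)
        f = fit_zspectrum(y, OFFS, smoothing=0.0)
        assert np.abs(f(OFFS) - y).max() < 1e-9

    def test_symmetric_samples_give_symmetric_curve(self):
        f = fit_zspectrum(lorentzian(OFFS), OFFS, smoothing=0.0)
        x = np.arange(0.0, 6.0, 0.01)
        assert np.abs(f(x) - f(-x)).max() < 1e-9

    def test_constant_samples_give_constant_curve(self):
        f = fit_zspectrum(np.full(OFFS.size, 0.8), OFFS, smoothing=0.0)
        x, y = f.grid()
        assert np.abs(y - 0.8).max() < 1e-9

    def test_too_few_finite_samples_marks_voxel_invalid(self):
        y = np.full(OFFS.size, np.nan)
        y[:9] = 0.9
        assert fit_zspectrum(y, OFFS) is None


class TestB0:
    def test_unshifted_symmetric_spectrum(self):
        f = fit_zspectrum(lorentzian(OFFS, width=1.0), OFFS, smoothing=0.0)
        shift, ok = estimate_b0_shift(f)
        assert ok and shift == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("method", ["symmetry", "argmin"])
    def test_simulated_shift_recovered(self, method):
        spec = small_spec()
        z = region_spectrum(spec, "pre", "brain", OFFS, b0=0.30)
        f = fit_zspectrum(z, OFFS, smoothing=0.0)
        shift, ok = estimate_b0_shift(f, method=method)
        assert ok and 0.28 <= shift <= 0.32

    def test_shift_beyond_window_flagged_unreliable(self):
        f = fit_zspectrum(lorentzian(OFFS, width=1.0, center=1.2), OFFS, smoothing=0.0)
        _, ok = estimate_b0_shift(f, window=1.0, method="argmin")
        assert not ok

    def test_equivariance_under_translation(self):
        """Translating the spectrum by delta moves the estimate by delta
        and leaves the corrected ST% unchanged."""
        spec = small_spec()
        delta = 0.23
        z0 = region_spectrum(spec, "post", "tumor", OFFS)
        z1 = region_spectrum(spec, "post", "tumor", OFFS, b0=delta)
        f0 = fit_zspectrum(z0, OFFS, smoothing=0.0)
        f1 = fit_zspectrum(z1, OFFS, smoothing=0.0)
        s0, _ = estimate_b0_shift(f0)
        s1, _ = estimate_b0_shift(f1)
        assert s1 - s0 == pytest.approx(delta, abs=0.01)
        st0 = compute_st(f0, s0)
        st1 = compute_st(f1, s1)
        assert st1 == pytest.approx(st0, abs=0.05)


class TestST:
    def test_symmetric_spectrum_gives_zero(self):
        f = fit_zspectrum(lorentzian(OFFS), OFFS, smoothing=0.0)
        assert compute_st(f, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_stated_formula_arithmetic(self):
        # Z(-4.2) = 0.90, Z(+4.2) = 0.72 -> 20%
        y = np.where(OFFS > 0, 0.72, 0.90)
        y[np.abs(OFFS) < 1.0] = 0.5  # water dip, irrelevant at 4.2
        f = fit_zspectrum(y, OFFS, smoothing=0.0)
        assert compute_st(f, 0.0) == pytest.approx(20.0, abs=0.1)

    def test_water_only_st_small_after_correction(self):
        sat = SaturationParams()
        from cestpipe import simulate_zspectrum

        for b0 in (-0.3, 0.0, 0.3):
            z = simulate_zspectrum([water_pool()], sat, OFFS, b0_shift=b0)
            f = fit_zspectrum(z, OFFS, smoothing=0.0)
            shift, ok = estimate_b0_shift(f)
            assert ok
            assert abs(compute_st(f, shift)) < 0.1

    def test_nonpositive_reference_point_gives_nan(self):
        y = np.where(OFFS < 0, -0.1, 0.5)
        f = fit_zspectrum(y, OFFS, smoothing=0.0)
        assert np.isnan(compute_st(f, 0.0))


class TestSTMap:
    def test_phantom_recovery_and_masking(self, small_noiseless_phantom):
        ds = small_noiseless_phantom
        st_pre, _ = compute_st_map(ds.cest_pre, smoothing=0.0, kind=MapKind.ST_PRE)
        st_post, b0 = compute_st_map(ds.cest_post, smoothing=0.0, kind=MapKind.ST_POST)
        # zero-reference voxels (outside brain) excluded
        assert not st_post.valid_mask[~ds.truth_brain_mask].any()
        # B0 recovered against ground truth
        sel = b0.valid_mask & ds.truth_brain_mask
        assert np.abs(b0.shift - ds.truth_b0)[sel].max() <= 0.02
        # dST recovered in the tumor within 10% of ground truth
        delta = compute_delta_st(st_post, st_pre)
        sel = ds.truth_tumor_mask & delta.valid_mask
        truth = ds.truth_delta_st[sel]
        assert np.abs(delta.values[sel] - truth).max() / truth.mean() < 0.10

    def test_schedule_volume_mismatch_raises(self, small_noiseless_phantom):
        ds = small_noiseless_phantom
        with pytest.raises(ValueError):
            ZSpectrumStack(
                ds.cest_pre.intensities[..., :-1],
                ds.cest_pre.schedule,
                ds.cest_pre.reference_volume,
            )


class TestDeltaAndEnh:
    def _map(self, values, kind=MapKind.ST_POST):
        v = np.asarray(values, dtype=float)
        return ContrastMap(v, kind, np.isfinite(v))

    def test_identical_maps_give_zero(self):
        a = self._map(np.full((4, 4, 2), 3.0))
        assert np.all(compute_delta_st(a, a).values[a.valid_mask] == 0)

    def test_antisymmetry(self, rng):
        a = self._map(rng.normal(size=(5, 5, 2)), MapKind.ST_POST)
        b = self._map(rng.normal(size=(5, 5, 2)), MapKind.ST_PRE)
        d1 = compute_delta_st(a, b)
        d2 = compute_delta_st(b, a)
        assert np.allclose(d1.values[d1.valid_mask], -d2.values[d2.valid_mask])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_delta_st(self._map(np.ones((3, 3, 1))), self._map(np.ones((4, 3, 1))))

    def test_kind_checked(self):
        enh = self._map(np.ones((3, 3, 1)), MapKind.ENH)
        with pytest.raises(ValueError):
            compute_delta_st(enh, enh)

    def test_enh_arithmetic(self):
        pre = np.full((4, 4, 1), 50.0)
        post = np.full((4, 4, 1), 65.0)
        m = compute_enh_map(pre, post)
        assert np.allclose(m.values[m.valid_mask], 30.0)
        assert np.allclose(compute_enh_map(pre, 2 * pre).values[m.valid_mask], 100.0)
        assert np.allclose(compute_enh_map(pre, pre).values[m.valid_mask], 0.0)

    def test_enh_invalid_where_pre_nonpositive(self):
        pre = np.array([[[0.0, 50.0]]])
        post = np.array([[[10.0, 60.0]]])
        m = compute_enh_map(pre, post)
        assert not m.valid_mask[0, 0, 0] and m.valid_mask[0, 0, 1]
        assert np.isnan(m.values[0, 0, 0])

    def test_finiteness_on_valid_mask(self, small_noisy_phantom):
        ds = small_noisy_phantom
        st, _ = compute_st_map(ds.cest_post, kind=MapKind.ST_POST)
        assert np.isfinite(st.values[st.valid_mask]).all()
        assert np.isnan(st.values[~st.valid_mask]).all()
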