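"""Preprocessing chain: dropping, detrending, FD, nuisance design, band-pass,
masked smoothing — each against an independent oracle where one exists."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemifc import preprocess as pp


class TestDropInitial:
    def test_drops_five_of_164(self):
        bold = np.zeros((2, 2, 2, 164))
        assert pp.drop_initial(bold, 5).shape[-1] == 159

    def test_zero_is_identity(self, rng):
        x = rng.normal(size=(3, 10))
        assert np.array_equal(pp.drop_initial(x, 0), x)

    def test_motion_truncated_identically(self, rng):
        motion = rng.normal(size=(20, 6))
        assert pp.drop_initial(motion, 5, time_axis=0).shape == (15, 6)

    def test_dropping_everything_rejected(self):
        with pytest.raises(ValueError):
            pp.drop_initial(np.zeros((2, 8)), 8)


class TestDetrend:
    def test_pure_line_removed(self):
        t = np.arange(50.0)
        out = pp.detrend_linear(2.0 + 0.5 * t)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_constant_removed(self):
        assert np.allclose(pp.detrend_linear(np.full((4, 30), 7.0)), 0.0, atol=1e-10)

    def test_residual_orthogonal_to_line(self, rng):
        x = rng.normal(size=(5, 5, 40))
        out = pp.detrend_linear(x)
        t = np.arange(40.0)
        X = np.column_stack([np.ones(40), t])
        coefs = np.linalg.lstsq(X, out.reshape(-1, 40).T, rcond=None)[0]
        assert np.abs(coefs).max() < 1e-10

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pp.detrend_linear(np.zeros(2))


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        assert np.array_equal(pp.compute_fd(np.zeros((10, 6))), np.zeros(10))

    def test_translation_step(self):
        motion = np.zeros((5, 6))
        motion[3:, 0] = 1.0  # 1 mm x step at frame 3
        fd = pp.compute_fd(motion)
        assert fd[3] == pytest.approx(1.0)
        assert fd[[0, 1, 2, 4]].max() == 0.0

    def test_rotation_arc_on_50mm_sphere(self):
        motion = np.zeros((3, 6))
        motion[1:, 4] = 0.02  # rad
        assert pp.compute_fd(motion)[1] == pytest.approx(50 * 0.02)

    def test_hand_computed_mixed_frame(self):
        # frame 1: |0.3| + |-0.1| + 50*(|0.004| + |0.002|) = 0.4 + 0.3 = 0.7
        motion = np.zeros((2, 6))
        motion[1] = [0.3, -0.1, 0.0, 0.004, -0.002, 0.0]
        assert pp.compute_fd(motion)[1] == pytest.approx(0.7)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            pp.compute_fd(np.zeros((10, 5)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_fd_nonnegative_and_zero_at_first_frame(self, seed):
        motion = np.random.default_rng(seed).normal(size=(12, 6))
        fd = pp.compute_fd(motion)
        assert fd[0] == 0.0 and (fd >= 0).all()


class TestFriston24:
    def test_zero_motion_zero_matrix(self):
        assert not pp.friston24(np.zeros((8, 6))).any()

    def test_width_always_24(self, rng):
        assert pp.friston24(rng.normal(size=(30, 6))).shape == (30, 24)

    def test_lag_and_square_columns(self):
        motion = np.zeros((5, 6))
        motion[:, 0] = np.arange(5.0)
        out = pp.friston24(motion)
        assert np.array_equal(out[:, 0], np.arange(5.0))            # p(t)
        assert np.array_equal(out[:, 6], [0, 0, 1, 2, 3])           # p(t-1), p(-1)=0
        assert np.array_equal(out[:, 12], np.arange(5.0) ** 2)      # p(t)^2
        assert np.array_equal(out[:, 18], [0, 0, 1, 4, 9])          # p(t-1)^2


class TestSpikeRegressors:
    def test_no_spikes(self):
        assert pp.spike_regressors(np.full(10, 0.3)).shape == (10, 0)

    def test_two_spike_columns_are_indicators(self):
        fd = np.zeros(60)
        fd[[10, 50]] = 1.5
        out = pp.spike_regressors(fd)
        assert out.shape == (60, 2)
        assert np.array_equal(out.sum(axis=0), [1.0, 1.0])
        assert out[10, 0] == 1.0 and out[50, 1] == 1.0

    def test_zero_threshold_counts_all_nonzero_frames(self, rng):
        fd = np.abs(rng.normal(size=30))
        fd[0] = 0.0
        assert pp.spike_regressors(fd, 0.0).shape[1] == int((fd > 0).sum())


class TestNuisanceRegression:
    def test_design_column_regresses_to_zero(self, rng):
        design = np.column_stack([np.ones(40), rng.normal(size=40)])
        bold = np.tile(design[:, 1], (2, 2, 2, 1))
        assert np.allclose(pp.regress_nuisance(bold, design), 0.0, atol=1e-10)

    def test_intercept_only_demeans(self, rng):
        x = rng.normal(size=(3, 3, 3, 25))
        out = pp.regress_nuisance(x, np.ones((25, 1)))
        assert np.allclose(out, x - x.mean(axis=-1, keepdims=True))

    def test_residuals_orthogonal_to_design(self, rng):
        design = np.column_stack([np.ones(50), rng.normal(size=(50, 5))])
        bold = rng.normal(size=(4, 4, 2, 50))
        resid = pp.regress_nuisance(bold, design)
        dots = np.einsum("tk,xyzt->kxyz", design, resid)
        assert np.abs(dots).max() < 1e-8

    def test_collinear_columns_dropped_with_warning(self, rng, caplog):
        col = rng.normal(size=40)
        design = np.column_stack([np.ones(40), col, 2 * col])
        bold = rng.normal(size=(2, 2, 2, 40))
        with caplog.at_level("WARNING"):
            resid = pp.regress_nuisance(bold, design)
        assert "collinear" in caplog.text
        assert np.abs(np.einsum("t,xyzt->xyz", col, resid)).max() < 1e-8

    def test_spike_frames_residual_exactly_zero(self, rng):
        fd = np.zeros(30)
        fd[12] = 2.0
        design, _ = pp.build_nuisance_design(rng.normal(0, 0.01, size=(30, 6)), fd=fd)
        bold = rng.normal(size=(2, 2, 2, 30))
        resid = pp.regress_nuisance(bold, design)
        assert np.abs(resid[..., 12]).max() < 1e-9

    def test_spike_only_regression_preserves_other_frame_correlations(self, rng):
        # adding spike indicators to an intercept-only design must not change
        # the correlation of the remaining frames
        T = 60
        x, y = rng.normal(size=(2, T))
        fd = np.zeros(T)
        fd[[7, 33]] = 3.0
        design = np.column_stack([np.ones(T), pp.spike_regressors(fd)])
        bold = np.stack([x, y])[:, None, None, :]
        resid = pp.regress_nuisance(bold, design)
        keep = np.setdiff1d(np.arange(T), [7, 33])
        expected = np.corrcoef(x[keep], y[keep])[0, 1]
        got = np.corrcoef(resid[0, 0, 0, keep], resid[1, 0, 0, keep])[0, 1]
        assert got == pytest.approx(expected, abs=1e-12)


class TestBandpass:
    def _energy(self, x):
        return float((x**2).sum())

    def test_in_band_sinusoid_retained(self):
        T, tr = 159, 2.2
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * 0.05 * t)
        out = pp.bandpass(x, 0.01, 0.1, tr)
        assert self._energy(out) / self._energy(x) > 0.95

    def test_out_of_band_sinusoid_suppressed(self):
        T, tr = 159, 2.2
        t = np.arange(T) * tr
        x = np.sin(2 * np.pi * 0.2 * t)
        out = pp.bandpass(x, 0.01, 0.1, tr)
        assert self._energy(out) < 0.05 * self._energy(x)

    def test_constant_series_zeroed(self):
        out = pp.bandpass(np.full(100, 5.0), 0.01, 0.1, 2.2)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_matches_explicit_fft_mask(self, rng):
        x = rng.normal(size=80)
        tr = 2.0
        out = pp.bandpass(x, 0.01, 0.1, tr)
        freqs = np.fft.rfftfreq(80, tr)
        spec = np.fft.rfft(x)
        spec[(freqs < 0.01) | (freqs > 0.1)] = 0
        assert np.allclose(out, np.fft.irfft(spec, 80), atol=1e-12)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass(np.zeros(50), 0.01, 0.25, 2.2)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass(np.zeros(50), 0.1, 0.01, 2.2)


def _brute_force_masked_smooth(vol, mask, sigma, radius):
    """Direct truncated-Gaussian convolution oracle (normalization cancels)."""
    out = np.zeros_like(vol, dtype=float)
    shape = vol.shape
    offsets = [
        (dx, dy, dz)
        for dx in range(-radius, radius + 1)
        for dy in range(-radius, radius + 1)
        for dz in range(-radius, radius + 1)
    ]
    for i in np.argwhere(mask):
        num = den = 0.0
        for dx, dy, dz in offsets:
            j = i + (dx, dy, dz)
            if np.any(j < 0) or np.any(j >= shape):
                continue
            if not mask[tuple(j)]:
                continue
            w = np.exp(-(dx**2 + dy**2 + dz**2) / (2 * sigma**2))
            num += w * vol[tuple(j)]
            den += w
        out[tuple(i)] = num / den
    return out


class TestMaskedSmooth:
    def test_constant_inside_mask_unchanged(self, rng):
        mask = np.zeros((9, 9, 9), bool)
        mask[2:7, 2:7, 2:7] = True
        out = pp.masked_smooth(np.full((9, 9, 9), 3.5), mask, fwhm_mm=4, voxel_size_mm=3)
        assert np.allclose(out[mask], 3.5)
        assert np.allclose(out[~mask], 0.0)

    def test_matches_brute_force_convolution_on_9cube(self, rng):
        mask = np.zeros((9, 9, 9), bool)
        mask[1:8, 2:8, 1:7] = True
        mask[4, 4, 4] = False  # hole: smoothing must not read it
        vol = rng.normal(size=(9, 9, 9))
        fwhm, voxel = 4.0, 3.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
        radius = int(4.0 * sigma + 0.5)  # same truncation as the implementation
        expected = _brute_force_masked_smooth(vol, mask, sigma, radius)
        out = pp.masked_smooth(vol, mask, fwhm, voxel)
        assert np.allclose(out, expected, atol=1e-10)

    def test_outside_mask_values_never_leak_in(self, rng):
        mask = np.zeros((9, 9, 9), bool)
        mask[3:6, 3:6, 3:6] = True
        vol = rng.normal(size=(9, 9, 9))
        out1 = pp.masked_smooth(vol, mask)
        vol2 = vol.copy()
        vol2[~mask] += rng.normal(size=int((~mask).sum())) * 100
        out2 = pp.masked_smooth(vol2, mask)
        assert np.array_equal(out1, out2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pp.masked_smooth(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            pp.masked_smooth(np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool), fwhm_mm=0)


class TestPreprocessSubject:
    def test_stage_order_recorded(self, small_cohort, compartments):
        s = small_cohort.subjects[0]
        res = pp.preprocess_subject(
            s.bold, s.motion, s.tissue_probs["csf"] >= 0.5,
            {"wm": compartments["wm"]}, tr_s=small_cohort.spec.tr_s,
        )
        assert tuple(res["provenance"]["stages"]) == pp.STAGE_ORDER
        assert res["tissue"]["wm"].shape[-1] == small_cohort.spec.n_timepoints - 5

    def test_motion_bold_mismatch_rejected(self, small_cohort, compartments):
        s = small_cohort.subjects[0]
        with pytest.raises(ValueError, match="frame count"):
            pp.preprocess_subject(s.bold, s.motion[:-1], compartments["csf"],
                                  {"wm": compartments["wm"]})
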