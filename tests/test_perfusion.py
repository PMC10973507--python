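"""Truncated-SVD deconvolution, kinetic constants, and map-level recovery."""

import numpy as np
import pytest
from scipy.linalg import solve_triangular

from bhdsc import perfusion as perf
from bhdsc.input_functions import InputFunction
from bhdsc.params import raised_cosine
from bhdsc.preprocess import RelaxationSeries

KH_OVER_RHO = 1.45 / 1.05


def _fn(kind, t, tc, start, end):
    return InputFunction(kind=kind, voxel_indices=[(0, 0, 0)], timecourse=tc,
                         t=t, bolus_start=start, bolus_end=end)


class TestKineticConstants:
    def test_defaults_match_published_analysis(self):
        c = perf.KineticConstants()
        assert (c.k_H, c.rho, c.svd_threshold) == (1.45, 1.05, 0.20)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            perf.KineticConstants(svd_threshold=1.5)


class TestTruncateWindow:
    def test_sample_arithmetic(self):
        t = np.arange(40) * 2.0
        rs = RelaxationSeries(np.ones((1, 1, 1, 40)), t, TR=2.0, TE=0.02)
        aif = _fn("AIF", t, np.ones(40), 10.0, 30.0)
        vof = _fn("VOF", t, np.ones(40), 40.0, 60.0)
        t_w, c_w, _ = perf.truncate_window(rs, aif, vof)
        assert len(t_w) == 26  # [10, 60] s inclusive at TR 2
        assert t_w[0] == 10.0 and t_w[-1] == 60.0

    def test_full_window_is_identity(self):
        t = np.arange(20) * 2.0
        rs = RelaxationSeries(np.ones((1, 1, 1, 20)), t, TR=2.0, TE=0.02)
        aif = _fn("AIF", t, np.ones(20), 0.0, 10.0)
        vof = _fn("VOF", t, np.ones(20), 20.0, 38.0)
        t_w, c_w, _ = perf.truncate_window(rs, aif, vof)
        assert len(t_w) == 20

    def test_inverted_window_rejected(self):
        t = np.arange(20) * 2.0
        rs = RelaxationSeries(np.ones((1, 1, 1, 20)), t, TR=2.0, TE=0.02)
        aif = _fn("AIF", t, np.ones(20), 30.0, 36.0)
        vof = _fn("VOF", t, np.ones(20), 0.0, 10.0)
        with pytest.raises(ValueError, match="inverted"):
            perf.truncate_window(rs, aif, vof)

    def test_window_captures_tissue_auc_on_phantom(self, pipeline_clean, layout):
        out = pipeline_clean
        rs = out.relaxation
        _, _, sl = perf.truncate_window(rs, out.aif_scaled, out.vof)
        tissue = layout.mask("gm") | layout.mask("wm")
        full = np.abs(np.trapezoid(rs.dR2s, rs.t, axis=-1))[tissue]
        wind = np.abs(np.trapezoid(rs.dR2s[..., sl], rs.t[sl], axis=-1))[tissue]
        assert np.all(wind / full >= 0.99)


class TestConvolutionMatrix:
    def test_impulse_gives_scaled_identity(self):
        aif = np.zeros(8)
        aif[0] = 1.0
        A = perf.build_convolution_matrix(aif, 2.0)
        assert np.allclose(A, 2.0 * np.eye(8))

    def test_constant_residue_gives_cumulative_sum(self):
        aif = np.random.default_rng(3).random(10)
        A = perf.build_convolution_matrix(aif, 0.5)
        k = np.full(10, 2.0)
        assert np.allclose(A @ k, 0.5 * np.cumsum(aif) * 2.0)

    def test_forward_model_reproduces_phantom_construction(self):
        dt = 0.5
        t = np.arange(0, 60, dt)
        aif = raised_cosine(t, 5.0, 20.0)
        R = np.exp(-t / 4.0)
        tissue = 0.01 * dt * np.convolve(aif, R)[: t.size]
        A = perf.build_convolution_matrix(aif, dt)
        assert np.allclose(A @ (0.01 * R), tissue, atol=1e-12)

    def test_nonuniform_dt_rejected(self):
        with pytest.raises(ValueError):
            perf.build_convolution_matrix(np.ones(4), -1.0)


class TestSvdDeconvolve:
    def _system(self, n=32):
        t = np.arange(n) * 2.0
        aif = np.exp(-(((t - 14) / 8.0) ** 2)) + 0.3
        A = perf.build_convolution_matrix(aif, 2.0)
        k_true = np.exp(-t / 6.0)
        return A, k_true, A @ k_true

    def test_threshold_zero_matches_triangular_solve(self):
        """Untruncated SVD inversion equals the direct triangular-solve
        oracle to 1e-8 relative error on a 32-sample problem."""
        A, k_true, c = self._system()
        k_svd = perf.svd_deconvolve(c, A, perf.KineticConstants(svd_threshold=0.0))
        k_tri = solve_triangular(A, c, lower=True)
        rel = np.linalg.norm(k_svd - k_tri) / np.linalg.norm(k_tri)
        assert rel < 1e-8
        assert np.allclose(k_svd, k_true, atol=1e-8)

    def test_tissue_equal_to_aif_gives_discrete_delta(self):
        t = np.arange(32) * 2.0
        aif = np.exp(-(((t - 14) / 8.0) ** 2)) + 0.3
        A = perf.build_convolution_matrix(aif, 2.0)
        k = perf.svd_deconvolve(aif, A, perf.KineticConstants(svd_threshold=0.0))
        assert k[0] == pytest.approx(1.0 / 2.0, rel=1e-6)
        assert np.max(np.abs(k[1:])) < 1e-6

    def test_long_bolus_with_truncation_underestimates_cbf(self):
        """With the 20% threshold and a 35 s bolus, max(k) falls below the
        true residue maximum (systematic CBF underestimation)."""
        dt = 2.0
        t = np.arange(0, 80, dt)
        aif = raised_cosine(t, 5.0, 35.0)
        cbf, mtt = 0.01, 4.0
        R = np.exp(-t / mtt)
        tissue = cbf * dt * np.convolve(aif, R)[: t.size]
        A = perf.build_convolution_matrix(aif, dt)
        k = perf.svd_deconvolve(tissue, A, perf.KineticConstants())
        assert k.max() < cbf * R.max()

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular values"):
            perf.svd_deconvolve(np.zeros(4), np.zeros((4, 4)))


class TestCbvCbfMtt:
    def test_tissue_equal_to_aif_gives_constant_ratio(self):
        t = np.arange(30) * 2.0
        aif = np.sin(np.linspace(0, np.pi, 30))
        cbv = perf.compute_cbv(aif, aif, t)
        assert cbv == pytest.approx(1.3809523809523810)

    def test_linearity_of_cbv(self):
        t = np.arange(30) * 2.0
        aif = np.sin(np.linspace(0, np.pi, 30))
        cbv = perf.compute_cbv(0.04 * aif, aif, t)
        assert cbv == pytest.approx(0.05523809523809524)

    def test_opposite_sign_tissue_invalidated(self):
        t = np.arange(30) * 2.0
        aif = np.sin(np.linspace(0, np.pi, 30))
        cbv = perf.compute_cbv(-0.1 * aif, aif, t)
        k = np.full((1, 30), -0.1)
        cbf, mtt, valid = perf.compute_cbf_mtt(k, np.array([cbv]))
        assert cbv < 0 and not valid.any()

    def test_delta_residue_closed_form(self):
        dt = 2.0
        k = np.zeros(20)
        k[0] = 1.0 / dt
        cbv = np.array(KH_OVER_RHO)
        cbf, mtt, valid = perf.compute_cbf_mtt(k, cbv)
        assert cbf == pytest.approx(KH_OVER_RHO / dt)
        assert mtt == pytest.approx(dt)
        assert valid

    def test_zero_aif_integral_rejected(self):
        t = np.arange(10) * 2.0
        with pytest.raises(ValueError, match="zero AIF"):
            perf.compute_cbv(np.ones(10), np.zeros(10), t)


class TestPerfusionMaps:
    def test_scaling_tissue_scales_cbv_cbf_not_mtt(self, pipeline_clean, layout):
        out = pipeline_clean
        rs = out.relaxation
        scaled = RelaxationSeries(3.0 * rs.dR2s, rs.t, rs.TR, rs.TE,
                                  brain_mask=rs.brain_mask)
        a = perf.perfusion_maps(rs, out.aif_scaled, out.vof)
        b = perf.perfusion_maps(scaled, out.aif_scaled, out.vof)
        m = layout.mask("gm") & a.valid_mask & b.valid_mask
        assert np.allclose(b.CBV[m], 3.0 * a.CBV[m])
        assert np.allclose(b.CBF[m], 3.0 * a.CBF[m])
        assert np.allclose(b.MTT[m], a.MTT[m])

    def test_central_volume_identity_within_valid_mask(self, pipeline_clean):
        res = pipeline_clean.perfusion
        m = res.valid_mask
        assert np.allclose(res.MTT[m], res.CBV[m] / res.CBF[m])

    def test_all_zero_tissue_warns_and_empties_mask(self, pipeline_clean):
        out = pipeline_clean
        rs = out.relaxation
        zero = RelaxationSeries(np.zeros_like(rs.dR2s), rs.t, rs.TR, rs.TE,
                                brain_mask=rs.brain_mask)
        with pytest.warns(UserWarning, match="zero"):
            res = perf.perfusion_maps(zero, out.aif_scaled, out.vof)
        assert not res.valid_mask.any()

    def test_noise_free_recovery_against_ground_truth(
            self, pipeline_clean, phantom_clean, layout):
        """GM CBV 4%, WM 2%, MTT 4 s: CBV recovered within 10% of truth and
        the GM/WM ratio within 5% of 2."""
        _, gt = phantom_clean
        res = pipeline_clean.perfusion
        gm = layout.mask("gm") & res.valid_mask
        wm = layout.mask("wm") & res.valid_mask
        cbv_gm = np.nanmean(res.CBV[gm])
        cbv_wm = np.nanmean(res.CBV[wm])
        assert cbv_gm == pytest.approx(0.04, rel=0.10)
        assert cbv_wm == pytest.approx(0.02, rel=0.10)
        assert cbv_gm / cbv_wm == pytest.approx(2.0, rel=0.05)

    def test_bolus_duration_inflates_mtt(self):
        """The same ground truth deconvolved from a 35 s bolus yields a
        higher MTT than from a 5 s bolus."""
        def recovered_mtt(width):
            dt = 0.5
            t = np.arange(0, 120, dt)
            aif = raised_cosine(t, 20.0, width)
            R = np.exp(-t / 4.0)
            tissue = 0.01 * dt * np.convolve(aif, R)[: t.size]
            A = perf.build_convolution_matrix(aif, dt)
            k = perf.svd_deconvolve(tissue, A, perf.KineticConstants())
            cbv = np.trapezoid(tissue, t) / np.trapezoid(aif, t)
            return cbv / k.max()

        short, long_ = recovered_mtt(5.0), recovered_mtt(35.0)
        assert long_ > short
        assert short == pytest.approx(4.0, rel=0.25)
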