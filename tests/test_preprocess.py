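"""Detrending/smoothing, bolus averaging, and the dS / CNR / dR2*
conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bhdsc import preprocess as pre
from bhdsc.params import BreathHoldProtocol
from bhdsc.phantom import PhantomLayout, generate_phantom

# Normalized length-5 Gaussian (sigma = 1 sample), computed independently
# from w_k = exp(-k^2/2), k = -2..2, w / sum(w).
EXPECTED_KERNEL = np.array([
    0.054488684549642945,
    0.24420134200323332,
    0.40261994689424736,
    0.24420134200323332,
    0.054488684549642945,
])


def _ts(arr, TR=2.0, TE=0.02):
    data = np.asarray(arr, float).reshape(1, 1, 1, -1)
    return pre.TimeSeries4D(data, TR=TR, TE=TE, brain_mask=np.ones((1, 1, 1), bool))


class TestDetrendAndSmooth:
    def test_constant_series_unchanged(self):
        out = pre.detrend_and_smooth(_ts(np.full(20, 7.0)))
        assert np.allclose(out.data, 7.0)

    def test_linear_ramp_becomes_mean(self):
        ramp = np.arange(21, dtype=float)
        out = pre.detrend_and_smooth(_ts(ramp))
        assert np.allclose(out.data, ramp.mean())

    def test_impulse_reproduces_kernel_weights(self):
        x = np.zeros(11)
        x[5] = 1.0  # centered: zero detrend slope
        out = pre.detrend_and_smooth(_ts(x)).data.ravel()
        assert np.allclose(out[3:8], EXPECTED_KERNEL, atol=1e-12)
        assert out.sum() == pytest.approx(1.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="5 time points"):
            pre.detrend_and_smooth(_ts([1.0, 2.0, 3.0]))


@pytest.fixture(scope="module")
def clean_small(protocol=None):
    prot = BreathHoldProtocol()
    from bhdsc.params import FieldParams

    lay = PhantomLayout.default()
    ts, gt = generate_phantom(prot, FieldParams.from_field(7), layout=lay,
                              noise_sd=0.0, seed=0)
    return prot, lay, ts, gt


class TestAverageBoluses:
    def test_identical_boluses_average_to_single_window(self, clean_small):
        prot, lay, ts, _ = clean_small
        b8 = pre.average_boluses(ts, prot, n_use=8)
        b1 = pre.average_boluses(ts, prot, n_use=1)
        gm = lay.mask("gm")
        assert np.allclose(b8.data[gm], b1.data[gm], atol=1e-9)

    def test_ninth_bolus_ignored(self, clean_small, rng=None):
        prot, lay, ts, _ = clean_small
        spoiled = ts.data.copy()
        # corrupt only the ninth block: averaging the first 8 must not change
        i0 = int((prot.block_start_s(8) + 25.0) / prot.TR)  # ninth response
        spoiled[..., i0 : i0 + 15] *= 5.0
        ts2 = pre.TimeSeries4D(spoiled, ts.TR, ts.TE, brain_mask=ts.brain_mask)
        a = pre.average_boluses(ts, prot, n_use=8)
        b = pre.average_boluses(ts2, prot, n_use=8)
        assert np.allclose(a.data, b.data)

    def test_n_use_exceeding_blocks_rejected(self, clean_small):
        prot, _, ts, _ = clean_small
        with pytest.raises(ValueError, match="n_use"):
            pre.average_boluses(ts, prot, n_use=10)

    def test_noise_reduction_sqrt8(self, clean_small, ):
        """Averaging 8 boluses of iid noise leaves baseline noise ~ sd/sqrt(8)."""
        prot, lay, ts, _ = clean_small
        rng = np.random.default_rng(7)
        sd = 0.5
        noisy = ts.data + sd * rng.standard_normal(ts.data.shape)
        ts2 = pre.TimeSeries4D(noisy, ts.TR, ts.TE, brain_mask=ts.brain_mask)
        bav = pre.average_boluses(ts2, prot, n_use=8)
        tissue = lay.mask("gm") | lay.mask("wm")
        ratio = np.mean(bav.eps_t[tissue]) / (sd / np.sqrt(8))
        assert ratio == pytest.approx(1.0, abs=0.10)

    def test_averaging_is_linear(self, clean_small):
        prot, _, ts, _ = clean_small
        ts2 = pre.TimeSeries4D(2.0 * ts.data + 5.0, ts.TR, ts.TE,
                               brain_mask=ts.brain_mask)
        a = pre.average_boluses(ts, prot)
        b = pre.average_boluses(ts2, prot)
        assert np.allclose(b.data, 2.0 * a.data + 5.0)


class TestDeltaSAndCnr:
    def _bav(self, s0, s_ext, sign=1, eps=0.5):
        shp = (1, 1, 1)
        return pre.BolusAverageMap(
            data=np.zeros(shp + (36,)), S0=np.full(shp, s0),
            S_ext=np.full(shp, s_ext), sign=np.full(shp, sign),
            eps_t=np.full(shp, eps), t=np.arange(36) * 2.0, TR=2.0, TE=0.02,
            n_boluses_used=8, brain_mask=np.ones(shp, bool),
        )

    def test_two_percent_rise(self):
        ds, sign = pre.delta_s(self._bav(100.0, 102.0))
        assert ds[0, 0, 0] == pytest.approx(2.0)
        assert sign[0, 0, 0] == 1

    def test_three_percent_dip_keeps_negative_flag(self):
        ds, sign = pre.delta_s(self._bav(100.0, 97.0, sign=-1))
        assert ds[0, 0, 0] == pytest.approx(3.0)
        assert sign[0, 0, 0] == -1

    def test_null_change(self):
        ds, _ = pre.delta_s(self._bav(100.0, 100.0))
        assert ds[0, 0, 0] == 0.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            pre.delta_s(self._bav(0.0, 1.0))

    def test_cnr_value(self):
        c, valid = pre.cnr(self._bav(100.0, 103.0, eps=0.5))
        assert c[0, 0, 0] == pytest.approx(6.0)
        assert valid.all()

    def test_cnr_zero_noise_flagged_invalid(self):
        c, valid = pre.cnr(self._bav(100.0, 103.0, eps=0.0))
        assert not valid.any()
        assert np.isnan(c[0, 0, 0])

    def test_cnr_matches_planted_contrast(self, rng):
        """A peak planted 2 sigma above iid baseline noise reads CNR ~ 2."""
        n_vox = 400
        sd = 1.0
        base = rng.standard_normal((n_vox, 36))
        bolus = 2.0 * sd * np.exp(-0.5 * ((np.arange(36) - 18) / 4.0) ** 2)
        data = (100.0 + base + bolus).reshape(n_vox, 1, 1, 36)
        bav = pre.BolusAverageMap(
            data=data, S0=np.full((n_vox, 1, 1), 100.0),
            S_ext=data[..., 18].copy(),  # signal at the known peak location
            sign=np.ones((n_vox, 1, 1)), eps_t=np.full((n_vox, 1, 1), sd),
            t=np.arange(36) * 2.0, TR=2.0, TE=0.02, n_boluses_used=1,
            brain_mask=np.ones((n_vox, 1, 1), bool))
        c, _ = pre.cnr(bav)
        assert np.mean(c) == pytest.approx(2.0, abs=0.6)


def test_gw_contrast_values():
    assert pre.gw_contrast(6.2, 4.0) == pytest.approx(2.2)
    assert pre.gw_contrast(8.52, 4.8) == pytest.approx(3.72)
    assert pre.gw_contrast(5.0, 5.0) == 0.0
    with pytest.raises(ValueError):
        pre.gw_contrast(np.nan, 1.0)


class TestDeltaR2Star:
    def test_constant_signal_gives_zero(self):
        rs = pre.delta_r2star(np.full(10, 50.0), 50.0, TE=0.03)
        assert np.allclose(rs.dR2s, 0.0)

    def test_closed_form_inversion(self):
        rs = pre.delta_r2star(np.array([np.exp(-0.6)]), 1.0, TE=0.030)
        assert rs.dR2s[0] == pytest.approx(20.0)
        rs = pre.delta_r2star(np.array([1.02]), 1.0, TE=0.020)
        assert rs.dR2s[0] == pytest.approx(-0.9901313648089856)

    def test_nonpositive_sample_names_voxel(self):
        s = np.ones((2, 3, 1, 5))
        s[1, 2, 0, 3] = -1.0
        with pytest.raises(ValueError, match=r"\(1, 2, 0, 3\)"):
            pre.delta_r2star(s, np.ones((2, 3, 1)), TE=0.02)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-30.0, 30.0), min_size=3, max_size=20))
    def test_round_trip_recovers_relaxation(self, dr2):
        dr2 = np.asarray(dr2)
        TE = 0.02
        s = 100.0 * np.exp(-TE * dr2)
        rs = pre.delta_r2star(s, 100.0, TE=TE)
        assert np.allclose(rs.dR2s, dr2, atol=1e-10)


class TestAucMap:
    def test_zero_series(self):
        rs = pre.RelaxationSeries(np.zeros((2, 2, 1, 10)), np.arange(10) * 2.0,
                                  TR=2.0, TE=0.02)
        assert np.allclose(pre.auc_map(rs), 0.0)

    def test_rectangle_area(self):
        d = np.full(6, 2.0)  # 2 1/s sustained over a 10 s span (TR 2)
        rs = pre.RelaxationSeries(d, np.arange(6) * 2.0, TR=2.0, TE=0.02)
        assert pre.auc_map(rs) == pytest.approx(20.0)

    def test_artery_positive_vein_negative_on_phantom(self, pipeline_clean, layout):
        auc = pipeline_clean.relaxation.auc()
        assert np.all(auc[layout.mask("artery")] > 0)
        assert np.all(auc[layout.mask("vein")] < 0)
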