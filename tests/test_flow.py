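"""Flow waveforms, offset correction, and dimensionless numbers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import csfhydro as ch
from csfhydro.errors import ValidationError

from conftest import sinusoid_waveform


class TestWaveformFromPixels:
    def test_uniform_field_arithmetic(self):
        # 10 pixels x 0.2 mm^2 x 1 cm/s = 2 mm^2 cm/s = 0.02 ml/s
        roi = ch.VelocityROISeries(
            z_mm=0.0, pixel_area_mm2=0.2,
            pixel_xy=np.column_stack([np.arange(10), np.arange(10)]),
            velocities=np.ones((10, 24)), period_s=0.5)
        w = ch.waveform_from_pixels(roi)
        np.testing.assert_allclose(w.q_ml_s, 0.02)

    def test_zero_velocities_give_zero_flow(self):
        roi = ch.VelocityROISeries(
            z_mm=0.0, pixel_area_mm2=0.2, pixel_xy=np.zeros((3, 2), dtype=int),
            velocities=np.zeros((3, 24)), period_s=0.5)
        assert not ch.waveform_from_pixels(roi).q_ml_s.any()

    def test_empty_roi_rejected(self):
        with pytest.raises(ValidationError):
            ch.VelocityROISeries(z_mm=0.0, pixel_area_mm2=0.2,
                                 pixel_xy=np.zeros((0, 2), dtype=int),
                                 velocities=np.zeros((0, 24)), period_s=0.5)


class TestOffsetCorrect:
    def test_constant_bias_removed(self):
        w = sinusoid_waveform(q0=1.0)
        biased = ch.FlowWaveform(z_mm=0.0, q_ml_s=w.q_ml_s + 0.1, period_s=w.period_s)
        res = ch.offset_correct(biased)
        assert res.offset_ml_s == pytest.approx(0.1)
        np.testing.assert_allclose(res.waveform.q_ml_s, w.q_ml_s, atol=1e-12)

    def test_zero_mean_waveform_unchanged(self):
        w = sinusoid_waveform()
        res = ch.offset_correct(w)
        assert res.offset_ml_s == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(res.waveform.q_ml_s, w.q_ml_s, atol=1e-15)

    @given(offset=st.floats(-5, 5), q0=st.floats(0.01, 5), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_corrected_waveform_has_zero_net_flow(self, offset, q0, seed):
        rng = np.random.default_rng(seed)
        q = q0 * rng.normal(size=24) + offset
        res = ch.offset_correct(ch.FlowWaveform(z_mm=0, q_ml_s=q, period_s=0.5))
        qmax = np.max(np.abs(res.waveform.q_ml_s))
        assert abs(np.mean(res.waveform.q_ml_s)) <= 1e-9 * max(qmax, 1e-12)


class TestResampleCycle:
    def test_identity_when_period_unchanged(self):
        w = sinusoid_waveform(period=0.5)
        out = ch.resample_cycle(w, 0.5)
        np.testing.assert_allclose(out.q_ml_s, w.q_ml_s)
        assert out.period_s == 0.5

    def test_sinusoid_rescales_period_and_preserves_amplitude(self):
        w = sinusoid_waveform(q0=1.0, period=0.4)
        out = ch.resample_cycle(w, 0.6)
        assert out.period_s == pytest.approx(0.6)
        expected = np.sin(2 * np.pi * out.times / 0.6)
        np.testing.assert_allclose(out.q_ml_s, expected, atol=0.01)

    def test_stroke_volume_scales_with_period(self):
        w = sinusoid_waveform(q0=0.5, period=0.4)
        sv1 = ch.waveform_features(w, a_sas_mm2=30.0).sv
        sv2 = ch.waveform_features(ch.resample_cycle(w, 0.6), a_sas_mm2=30.0).sv
        assert sv2 == pytest.approx(sv1 * 0.6 / 0.4, rel=1e-9)


class TestWaveformFeatures:
    def test_sinusoid_closed_forms(self):
        # Q = -0.5 sin(2 pi t / T), T = 0.5 s, generic sampling alignment
        # (a quarter-sample phase offset keeps waveform zeros off the grid)
        w = sinusoid_waveform(q0=-0.5, period=0.5, phase=2 * np.pi * 0.25 / 24)
        f = ch.waveform_features(w, a_sas_mm2=25.0, d_h_mm=2.0)
        assert f.q_sys == pytest.approx(-0.5, rel=0.005)
        assert f.q_dia == pytest.approx(0.5, rel=0.005)
        assert f.q_a == pytest.approx(1.0, rel=0.005)
        # SV = integral |Q| dt = 2 q0 T / pi = 0.159 ml
        assert f.sv == pytest.approx(2 * 0.5 * 0.5 / np.pi, rel=0.005)
        # zero-aligned sampling hits the |Q| kinks: a slightly larger,
        # known discretization error (~0.6% low at 24 phases)
        w0 = sinusoid_waveform(q0=-0.5, period=0.5)
        f0 = ch.waveform_features(w0, a_sas_mm2=25.0, d_h_mm=2.0)
        assert f0.sv == pytest.approx(2 * 0.5 * 0.5 / np.pi, rel=0.01)

    def test_sv_half_convention_flag(self):
        w = sinusoid_waveform(q0=0.5)
        full = ch.waveform_features(w, a_sas_mm2=25.0).sv
        half = ch.waveform_features(w, a_sas_mm2=25.0, sv_half=True).sv
        assert half == pytest.approx(full / 2)

    def test_zero_waveform_all_features_zero_except_alpha(self):
        w = ch.FlowWaveform(z_mm=0, q_ml_s=np.zeros(24), period_s=0.5)
        f = ch.waveform_features(w, a_sas_mm2=25.0, d_h_mm=2.0)
        assert f.q_sys == f.q_dia == f.q_a == f.sv == 0.0
        assert f.u_sys == f.u_dia == f.re == 0.0
        assert f.alpha > 0

    def test_reynolds_hand_computed(self):
        # |U| = 2.69 cm/s, D_h = 2.04 mm, nu = 0.693e-6 m^2/s -> Re = 79.2
        re = 2.69e-2 * 2.04e-3 / ch.CSF_DEFAULT.nu_m2_s
        assert re == pytest.approx(79.2, abs=0.05)
        # and through the feature path: pick A_sas so that Q_sys/A = -2.69 cm/s
        a_sas = 22.0
        q0 = 2.69 * a_sas / 100.0
        w = sinusoid_waveform(q0=-q0, period=0.55, n=4)  # phase grid hits +-q0
        f = ch.waveform_features(w, a_sas_mm2=a_sas, d_h_mm=2.04)
        assert f.u_sys == pytest.approx(-2.69, rel=1e-9)
        assert f.re == pytest.approx(79.2, abs=0.1)

    def test_womersley_hand_computed(self):
        # D_h = 2.68 mm, T = 0.55 s -> alpha = 5.43
        w = sinusoid_waveform(period=0.55)
        f = ch.waveform_features(w, a_sas_mm2=25.0, d_h_mm=2.68)
        expected = (2.68e-3 / 2) * math.sqrt(2 * math.pi / 0.55 / 0.693e-6)
        assert f.alpha == pytest.approx(expected, rel=1e-12)
        assert f.alpha == pytest.approx(5.43, abs=0.02)
        assert 4.15 <= f.alpha <= 7.67

    @given(scale=st.floats(0.1, 10))
    @settings(max_examples=20, deadline=None)
    def test_re_linear_in_velocity_and_diameter(self, scale):
        w = sinusoid_waveform(q0=-0.5, period=0.5)
        base = ch.waveform_features(w, a_sas_mm2=25.0, d_h_mm=2.0)
        scaled_q = ch.FlowWaveform(z_mm=0, q_ml_s=w.q_ml_s * scale, period_s=0.5)
        f_q = ch.waveform_features(scaled_q, a_sas_mm2=25.0, d_h_mm=2.0)
        f_d = ch.waveform_features(w, a_sas_mm2=25.0, d_h_mm=2.0 * scale)
        assert f_q.re == pytest.approx(base.re * scale, rel=1e-9)
        assert f_d.re == pytest.approx(base.re * scale, rel=1e-9)
        assert f_d.alpha == pytest.approx(base.alpha * scale, rel=1e-9)

    def test_alpha_scales_with_inverse_sqrt_period(self):
        w1 = sinusoid_waveform(period=0.4)
        w2 = sinusoid_waveform(period=1.6)
        a1 = ch.waveform_features(w1, a_sas_mm2=25.0, d_h_mm=2.0).alpha
        a2 = ch.waveform_features(w2, a_sas_mm2=25.0, d_h_mm=2.0).alpha
        assert a1 == pytest.approx(2 * a2, rel=1e-9)

    def test_invalid_geometry_marks_features_undefined(self):
        w = sinusoid_waveform(q0=0.5)
        f = ch.waveform_features(w, a_sas_mm2=0.0, d_h_mm=None)
        assert math.isnan(f.u_sys) and math.isnan(f.re) and math.isnan(f.alpha)
        assert f.q_a > 0  # flow-only features remain defined
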