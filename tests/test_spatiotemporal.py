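"""Q(z,t) surface fitting, peak-arrival timing, and PWV estimation."""

import numpy as np
import pytest

import csfhydro as ch
from csfhydro.errors import ValidationError
from csfhydro.spatiotemporal import ArrivalCurve

from conftest import sinusoid_waveform


def _travelling_wave_slices(cfg, zs):
    t = np.arange(cfg.n_phases) * cfg.period_s / cfg.n_phases
    return [ch.FlowWaveform(z_mm=z, q_ml_s=cfg.q_true(z, t), period_s=cfg.period_s)
            for z in zs]


class TestFitSpatiotemporal:
    def test_constant_in_z_field_reproduced(self):
        ws = [sinusoid_waveform(q0=0.5, z=z) for z in [0, 50, 100, 150, 200, 250]]
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        for row in stf.q:
            np.testing.assert_allclose(row, ws[0].q_ml_s, atol=0.01 * 0.5)

    def test_travelling_wave_interpolation_error(self):
        cfg = ch.PhantomConfig()
        ws = _travelling_wave_slices(cfg, [0, 16.3, 38.7, 84.2, 148.9, 237.1])
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        zz, tt = np.meshgrid(stf.z, stf.t, indexing="ij")
        q_true = cfg.q_true(zz.ravel(), tt.ravel()).reshape(zz.shape)
        rms = np.sqrt(np.mean((stf.q - q_true) ** 2))
        assert rms <= 0.05 * np.abs(q_true).max()

    def test_linear_amplitude_decay_interpolated(self):
        zs = np.array([0.0, 50, 100, 150, 200, 250])
        ws = [sinusoid_waveform(q0=1.0 - z / 500.0, z=z) for z in zs]
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        mids = (zs[:-1] + zs[1:]) / 2
        for zm in mids:
            i = np.argmin(np.abs(stf.z - zm))
            amp = np.ptp(stf.q[i]) / 2
            expected = 1.0 - zm / 500.0
            assert amp == pytest.approx(expected, rel=0.05)

    def test_surface_rows_keep_zero_net_flow(self):
        cfg = ch.PhantomConfig()
        ws = _travelling_wave_slices(cfg, [0, 40, 90, 150, 200, 250])
        stf = ch.fit_spatiotemporal(ws)
        np.testing.assert_allclose(stf.q.mean(axis=1), 0.0, atol=1e-12)

    def test_surface_spans_data_only(self):
        ws = [sinusoid_waveform(z=z) for z in [10, 50, 90]]
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        assert stf.z[0] >= 10.0 and stf.z[-1] <= 90.0

    def test_too_few_or_duplicate_slices_rejected(self):
        ws = [sinusoid_waveform(z=z) for z in [0, 50]]
        with pytest.raises(ValidationError):
            ch.fit_spatiotemporal(ws)
        ws = [sinusoid_waveform(z=z) for z in [0, 50, 50]]
        with pytest.raises(ValidationError):
            ch.fit_spatiotemporal(ws)

    def test_mixed_periods_rejected(self):
        ws = [sinusoid_waveform(z=0), sinusoid_waveform(z=50),
              sinusoid_waveform(z=100, period=0.6)]
        with pytest.raises(ValidationError):
            ch.fit_spatiotemporal(ws)


class TestPeakArrival:
    def test_known_delay_recovered_within_half_phase(self):
        cfg = ch.PhantomConfig(pwv_m_s=2.0)  # tau(z) = z/2000 s
        ws = _travelling_wave_slices(cfg, [0, 50, 100, 150, 200, 250])
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        arr = ch.peak_arrival(stf)
        dt = cfg.period_s / cfg.n_phases
        expected = 0.2 * cfg.period_s + stf.z / 2000.0
        # compare modulo the cycle, at the fitted slices (no blend error)
        for z in [0, 50, 100, 150, 200, 250]:
            i = np.argmin(np.abs(stf.z - z))
            assert abs(arr.t_arrival[i] - expected[i]) < dt / 2

    def test_zero_delay_field_constant_arrival(self):
        ws = [sinusoid_waveform(q0=-1.0, z=z) for z in [0, 60, 120, 180, 240]]
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        arr = ch.peak_arrival(stf)
        assert np.nanstd(arr.t_arrival) < 1e-6

    def test_flat_row_excluded_others_unchanged(self):
        ws = [sinusoid_waveform(q0=-1.0, z=z) for z in [0, 60, 120, 180, 240]]
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        stf.q[3, :] = 0.0  # degenerate interpolated row
        arr = ch.peak_arrival(stf)
        assert not arr.valid[3]
        assert arr.valid.sum() == stf.z.size - 1

    def test_arrival_from_waveforms_matches_prescribed_delays(self):
        cfg = ch.PhantomConfig(pwv_m_s=1.0)
        zs = [0, 40, 90, 150, 200, 250]
        arr = ch.arrival_from_waveforms(_travelling_wave_slices(cfg, zs))
        slopes = np.diff(arr.t_arrival) / np.diff(arr.z)
        np.testing.assert_allclose(slopes, 1e-3, rtol=0.02)  # 1 m/s = 1e-3 s/mm


class TestPulseWaveVelocity:
    def test_constructed_line_gives_exact_pwv(self):
        z = np.arange(0.0, 301.0)
        arr = ArrivalCurve(z=z, t_arrival=0.1 + z / 2000.0)
        pw = ch.pulse_wave_velocity(arr)
        assert pw.pwv_m_s == pytest.approx(2.0, rel=1e-12)
        assert pw.r_squared == pytest.approx(1.0)

    def test_constant_arrival_flagged_undefined(self):
        z = np.arange(0.0, 100.0)
        arr = ArrivalCurve(z=z, t_arrival=np.full_like(z, 0.25))
        pw = ch.pulse_wave_velocity(arr)
        assert not pw.defined

    def test_z_range_restricts_fit(self):
        z = np.arange(0.0, 301.0)
        t = 0.1 + z / 2000.0
        t[200:] = 0.1 + z[200:] / 1000.0  # kink
        pw = ch.pulse_wave_velocity(ArrivalCurve(z=z, t_arrival=t), z_range=(0, 199))
        assert pw.pwv_m_s == pytest.approx(2.0, rel=1e-9)

    def test_too_few_points_rejected(self):
        arr = ArrivalCurve(z=np.array([0.0]), t_arrival=np.array([0.1]))
        with pytest.raises(ValidationError):
            ch.pulse_wave_velocity(arr)

    @pytest.mark.parametrize("pwv", [0.5, 1.13, 2.0, 5.0])
    def test_noise_free_phantom_recovery_within_2pct(self, pwv):
        cfg = ch.PhantomConfig(pwv_m_s=pwv)
        series, _ = ch.generate_flow(cfg)
        ws = [ch.offset_correct(ch.waveform_from_pixels(s)).waveform for s in series]
        pw = ch.pulse_wave_velocity(ch.arrival_from_waveforms(ws))
        assert pw.pwv_m_s == pytest.approx(pwv, rel=0.02)


class TestHydrodynamicProfile:
    def test_constant_case_matches_single_slice_features(self):
        ws = [sinusoid_waveform(q0=-0.5, z=z) for z in [0, 50, 100, 150, 200]]
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        z = np.arange(0.0, 201.0)
        geom = ch.GeometricProfile(z=z, a_cord=np.full_like(z, 5.0),
                                   a_dura=np.full_like(z, 30.0),
                                   p_cord=np.full_like(z, 8.0),
                                   p_dura=np.full_like(z, 19.0))
        hp = ch.hydrodynamic_profile(stf, geom)
        ref = ch.waveform_features(ws[0], a_sas_mm2=25.0,
                                   d_h_mm=float(geom.d_h[0]))
        np.testing.assert_allclose(hp.sv, ref.sv, rtol=0.01)
        np.testing.assert_allclose(hp.re, ref.re, rtol=0.01)
        np.testing.assert_allclose(hp.alpha, ref.alpha, rtol=1e-9)

    def test_velocity_inverse_in_area(self):
        ws = [sinusoid_waveform(q0=-0.5, z=z) for z in [0, 50, 100]]
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        z = np.arange(0.0, 101.0)
        mk = lambda a: ch.GeometricProfile(
            z=z, a_cord=np.zeros_like(z), a_dura=np.full_like(z, a),
            p_cord=np.zeros_like(z), p_dura=np.full_like(z, 20.0))
        h1 = ch.hydrodynamic_profile(stf, mk(20.0))
        h2 = ch.hydrodynamic_profile(stf, mk(40.0))
        np.testing.assert_allclose(h2.u_sys, h1.u_sys / 2, rtol=1e-9)

    def test_empty_overlap_rejected(self):
        ws = [sinusoid_waveform(z=z) for z in [0, 50, 100]]
        stf = ch.fit_spatiotemporal(ws, smoothing=0.0)
        z = np.arange(500.0, 601.0)
        geom = ch.GeometricProfile(z=z, a_cord=np.zeros_like(z),
                                   a_dura=np.full_like(z, 30.0),
                                   p_cord=np.zeros_like(z),
                                   p_dura=np.full_like(z, 19.0))
        with pytest.raises(ValidationError):
            ch.hydrodynamic_profile(stf, geom)

    def test_sv_profile_peak_location_recovered(self):
        cfg = ch.PhantomConfig()
        seg, _ = ch.generate_geometry(cfg)
        series, ft = ch.generate_flow(cfg)
        res = ch.analyze_subject(seg, series)
        h = res.hydrodynamic
        z_peak = h.z[np.nanargmax(h.sv)]
        assert abs(z_peak - ft.sv_peak_z_mm) <= 3.0
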