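import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from syconpump.geometry import reference_geometry
from syconpump.kinematics import (
    BeatKinematics,
    sheet_state,
    waveform,
    waveform_velocity,
)

BASE = BeatKinematics()
INCREASED = BeatKinematics(amplitude=5.0, envelope_scale=22.0)


class TestWaveform:
    def test_clamped_base(self):
        for t in np.linspace(0, BASE.period, 7):
            assert waveform(0.0, t, BASE) == 0.0

    def test_increased_amplitude_peaks_at_two_microns_at_tip(self):
        k = INCREASED
        t = np.linspace(0, k.period, 400)
        peak = np.max(np.abs([waveform(k.flagellum_length, ti, k) for ti in t]))
        assert peak == pytest.approx(2.0, abs=0.02)

    def test_base_case_envelope_saturates(self):
        k = BASE
        t = np.linspace(0, k.period, 400)
        for s in (3.0, 8.0, k.flagellum_length):
            peak = np.max(np.abs([waveform(s, ti, k) for ti in t]))
            assert peak == pytest.approx(1.0, rel=1e-3)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            waveform(-0.1, 0.0, BASE)
        with pytest.raises(ValueError):
            waveform(BASE.flagellum_length + 1.0, 0.0, BASE)

    @given(
        s=st.floats(0.0, BASE.flagellum_length),
        t=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_periodicity_and_bound(self, s, t):
        d0 = waveform(s, t, BASE)
        d1 = waveform(s, t + BASE.period, BASE)
        assert d0 == pytest.approx(d1, abs=1e-9)
        envelope = BASE.amplitude * (1 - np.exp(-((s / BASE.envelope_scale) ** 2)))
        assert abs(d0) <= envelope + 1e-12

    def test_zero_phase_average(self):
        k = BASE
        t = np.arange(64) * k.period / 64
        for s in (0.5, 2.5, 10.0):
            mean = np.mean([waveform(s, ti, k) for ti in t])
            assert abs(mean) < 1e-10

    def test_velocity_matches_central_difference(self):
        k = BASE
        dt = 1e-6
        s = np.linspace(0, k.flagellum_length, 30)
        for t in (0.0, 0.013):
            fd = (waveform(s, t + dt, k) - waveform(s, t - dt, k)) / (2 * dt)
            assert np.max(np.abs(waveform_velocity(s, t, k) - fd)) < 1e-3


class TestSheetState:
    def test_centerline_length_nearly_constant_over_period(self):
        """The prescribed-motion sheet stretches only a few percent over
        the cycle: the traveling wave moves the steep portions along the
        flagellum with little change of the integrated arclength (~1.6%
        for the base beat, ~3.4% for the amplitude-modulated one)."""
        from syconpump.kinematics import centerline_length

        for k, bound in ((BASE, 0.02), (BASE.increased_amplitude(), 0.04)):
            lengths = [
                centerline_length(t, k)
                for t in np.linspace(0, k.period, 11)
            ]
            assert np.ptp(lengths) / np.mean(lengths) < bound

    def test_velocity_consistent_with_position_difference(self):
        geom = reference_geometry()
        dt = 1e-6
        a = sheet_state(0.005 - dt, BASE, geom, n_points=50)[0]
        b = sheet_state(0.005 + dt, BASE, geom, n_points=50)[0]
        mid = sheet_state(0.005, BASE, geom, n_points=50)[0]
        fd = (b.points - a.points) / (2 * dt)
        assert np.max(np.abs(mid.velocities - fd)) < 1e-2

    def test_presence_masks(self):
        import dataclasses

        geom = reference_geometry()
        unc = dataclasses.replace(BASE, presence_mask="unconfined-only")
        con = dataclasses.replace(BASE, presence_mask="confined-only")
        s_unc = sheet_state(0.0, unc, geom)[0]
        s_con = sheet_state(0.0, con, geom)[0]
        assert s_unc.points[:, 1].min() > geom.collar_length
        assert s_con.points[:, 1].max() <= geom.collar_length

    def test_piecewise_vane_width(self):
        import dataclasses

        geom = reference_geometry()
        k = dataclasses.replace(
            BASE, vane_width_confined=0.7, vane_width_unconfined=1.4
        )
        sh = sheet_state(0.0, k, geom)[0]
        y = sh.points[:, 1]
        assert np.all(sh.half_width[y <= geom.collar_length] == 0.35)
        assert np.all(sh.half_width[y > geom.collar_length] == 0.7)

    def test_confined_wave_fits_inside_collar(self):
        geom = reference_geometry()
        r_in = geom.collar_diameter / 2
        for t in np.linspace(0, BASE.period, 9):
            sh = sheet_state(t, BASE, geom)[0]
            confined = sh.points[:, 1] <= geom.collar_length
            cx, cz = geom.collar_centers()[0]
            d = np.hypot(sh.points[confined, 0] - cx, sh.points[confined, 2] - cz)
            assert np.all(d <= r_in + 1e-9)

    def test_beat_plane_azimuth(self):
        import dataclasses

        geom = reference_geometry()
        n = len(geom.collar_centers())
        k = dataclasses.replace(
            BASE, beat_plane_azimuths=tuple([np.pi / 2] * n)
        )
        sh = sheet_state(0.004, k, geom)[0]
        cx, cz = geom.collar_centers()[0]
        # displacement now lies along z, not x
        assert np.max(np.abs(sh.points[:, 0] - cx)) < 1e-9
        assert np.max(np.abs(sh.points[:, 2] - cz)) > 0.1

    def test_randomized_phases_deterministic(self):
        k1 = BASE.randomized_phases(24, seed=7)
        k2 = BASE.randomized_phases(24, seed=7)
        assert k1.phase_offsets == k2.phase_offsets
        assert len(set(k1.phase_offsets)) > 20
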