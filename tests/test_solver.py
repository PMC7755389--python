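import dataclasses

import numpy as np
import pytest

from syconpump.geometry import build_unit_cell, reference_geometry
from syconpump.kinematics import BeatKinematics
from syconpump import solver as sv

from conftest import poiseuille_tube_problem


class TestStokesCore:
    def test_no_forcing_gives_zero_flow(self, base_geometry, base_kinematics):
        cfg = sv.SolverConfig(h=1.0, rtol=1e-6)
        prob, _ = sv.chamber_problem(base_geometry, base_kinematics, cfg, 0.0)
        prob.marker_target = np.zeros_like(prob.marker_target)
        prob.__post_init__()
        u, v, w, p, info = sv.solve_stokes(prob, rtol=1e-6)
        assert np.all(u == 0) and np.all(v == 0) and np.all(w == 0)
        assert info["iterations"] == 0

    def test_superposition_of_body_forces(self):
        prob = poiseuille_tube_problem(7.0, 7.0 / 8)
        shape, h = prob.shape, prob.h
        f1 = [np.zeros(shape) for _ in range(3)]
        f2 = [np.zeros(shape) for _ in range(3)]
        f1[1][:, :4, :] = 1e-3
        f2[1][:, 4:, :] = 2e-3
        sols = []
        for body in (f1, f2, [a + b for a, b in zip(f1, f2)]):
            p2 = dataclasses.replace(prob, body=tuple(body))
            u, v, w, p, _ = sv.solve_stokes(p2, rtol=1e-9)
            sols.append(v)
        joint = sols[2]
        assert np.allclose(sols[0] + sols[1], joint, atol=1e-6 * np.abs(joint).max() + 1e-12)

    def test_linearity_in_sheet_velocity(self, base_geometry, base_kinematics):
        cfg = sv.SolverConfig(h=1.0, rtol=1e-8)
        prob, _ = sv.chamber_problem(base_geometry, base_kinematics, cfg, 0.0)
        masks = build_unit_cell(base_geometry, 1.0)
        u, v, w, p, _ = sv.solve_stokes(prob, rtol=1e-8)
        q1 = sv.ostium_flux(
            sv.FlowField(u, v, w, p, 1.0, 0.0, 0, 0.0, 0), masks
        )
        prob2, _ = sv.chamber_problem(base_geometry, base_kinematics, cfg, 0.0)
        prob2.marker_target = 2.0 * prob2.marker_target
        prob2.__post_init__()
        u2, v2, w2, p2, _ = sv.solve_stokes(prob2, rtol=1e-8)
        q2 = sv.ostium_flux(
            sv.FlowField(u2, v2, w2, p2, 1.0, 0.0, 0, 0.0, 0), masks
        )
        assert q2 == pytest.approx(2 * q1, rel=1e-4)

    def test_back_pressure_reduces_pumping(self, base_geometry, base_kinematics):
        masks = build_unit_cell(base_geometry, 1.0)
        qs = []
        for dp in (0.0, 0.08):
            cfg = sv.SolverConfig(h=1.0, rtol=1e-6, back_pressure=dp)
            fld, _ = sv.solve_phase(base_geometry, base_kinematics, cfg, 0.0)
            qs.append(sv.ostium_flux(fld, masks))
        assert qs[1] < qs[0]


class TestDiagnostics:
    def test_mass_conservation_across_planes(self, coarse_case):
        masks, mean = coarse_case["masks"], coarse_case["mean"]
        q_ost = coarse_case["rates"].Q_ost
        ny = mean.v.shape[1]
        fluxes = [sv.plane_flux(mean, j) for j in range(ny)]
        assert np.max(np.abs(np.array(fluxes) - q_ost)) < 0.005 * abs(q_ost)

    def test_divergence_free(self, coarse_case):
        f = coarse_case["fields"][0]
        prob = coarse_case["probs"][0]
        div = sv._div(f.u, f.v, f.w, f.h)
        speed = np.abs(prob.marker_target).max()
        assert np.abs(div[prob.active_p]).max() < 1e-4 * speed / f.h

    def test_sheet_slip_bounded(self, coarse_case):
        """The compliance-regularized sheet constraints track the target
        velocities to within 20% rms at the coarse profile."""
        fld = coarse_case["fields"][0]
        prob = coarse_case["probs"][0]
        nm = prob.n_markers
        num = den = 0.0
        for c, vel in enumerate((fld.u, fld.v, fld.w)):
            ju = prob.con_J[c][:nm] @ vel.ravel()
            ut = prob.con_target[c][:nm]
            num += float(np.sum((ju - ut) ** 2))
            den += float(np.sum(ut**2))
        assert np.sqrt(num / den) < 0.20

    def test_energy_balance(self, coarse_case):
        rates = coarse_case["rates"]
        assert rates.P_flagella == pytest.approx(rates.P_dissipation, rel=0.05)
        assert rates.P_flagella > 0

    def test_refiltration(self, coarse_case):
        rates = coarse_case["rates"]
        assert rates.Q_col > rates.Q_ost > 0

    def test_stagnation_zone_near_collar_tips(self, coarse_case):
        stag = sv.stagnation_height(coarse_case["mean"], coarse_case["masks"])
        lcol = coarse_case["masks"].collar_length
        assert stag is not None
        assert 0 < stag < 2 * lcol

    def test_strong_coflow_removes_stagnation(self, coarse_case):
        mean = coarse_case["mean"]
        forced = dataclasses.replace(mean, v=mean.v + 500.0)
        assert sv.stagnation_height(forced, coarse_case["masks"]) is None

    def test_mirror_is_an_involution(self, coarse_case):
        f = coarse_case["fields"][0]
        ff = sv.mirror_x(sv.mirror_x(f))
        assert np.allclose(ff.u, f.u) and np.allclose(ff.v, f.v)

    def test_time_average_requires_full_period(self, coarse_case):
        with pytest.raises(ValueError):
            sv.time_average(
                coarse_case["fields"][:3], coarse_case["probs"][:3],
                coarse_case["masks"],
            )

    def test_grid_convergence_needs_three_resolutions(self, base_geometry, base_kinematics, coarse_cfg):
        with pytest.raises(ValueError):
            sv.grid_convergence(base_geometry, base_kinematics, coarse_cfg, [1.0, 0.5])


class TestConfigValidation:
    def test_phase_count_floor(self):
        with pytest.raises(ValueError):
            sv.SolverConfig(phases_per_period=4)

    def test_tolerance_ceiling(self):
        with pytest.raises(ValueError):
            sv.SolverConfig(rtol=1e-4)
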