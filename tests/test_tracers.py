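import numpy as np
import pytest

from syconpump.geometry import UnitCellMasks
from syconpump.solver import FlowField
from syconpump import tracers as tr


def open_box_masks(h=1.0, n=16):
    """Obstacle-free periodic box with no collars (synthetic fixture)."""
    shape = (n, n, n)
    return UnitCellMasks(
        h=h,
        shape=shape,
        solid=np.zeros(shape, bool),
        alpha=np.zeros(shape),
        y_floor_top=0.0,
        y_floor_bot=0.0,
        y_mouth_index=1,
        y_force=(0.0, 1.0),
        y_exit=n * h - 2.0,
        collar_centers=np.zeros((0, 2)),
        collar_inner_radius=1.0,
        collar_outer_radius=1.5,
        collar_length=4.8,
        ostium_center=(n * h / 2, n * h / 2),
        ostium_radius=3.5,
        extent=(n * h, n * h, n * h),
    )


def uniform_field(masks, v=10.0):
    shape = masks.shape
    return FlowField(
        u=np.zeros(shape), v=np.full(shape, v), w=np.zeros(shape),
        p=np.zeros(shape), h=masks.h, t=0.0, phase_index=0,
        residual=0.0, iterations=0,
    )


class TestUniformTransport:
    def test_straight_lines_and_no_capture(self):
        masks = open_box_masks()
        fld = uniform_field(masks, v=10.0)
        ens = tr.seed_particles(masks, fld, n=50, seed=0, flux_weighted=False)
        x0 = ens.positions.copy()
        period = 1.0 / 30
        tr.advect(ens, [fld] * 8, masks, period, n_periods=1.0)
        moved = ens.positions[:, 1] - x0[:, 1]
        live = ens.fate != tr.FATE_EXITED
        # vertical drift matches v*t for particles still in flight
        assert np.allclose(moved[live], 10.0 * period, atol=1e-9)
        assert np.allclose(ens.positions[:, 0], x0[:, 0])
        counts = ens.counts()
        assert counts["captured"] == 0

    def test_everything_exits_eventually(self):
        masks = open_box_masks()
        fld = uniform_field(masks, v=50.0)
        ens = tr.seed_particles(masks, fld, n=40, seed=1, flux_weighted=False)
        tr.advect(ens, [fld] * 8, masks, period=1.0 / 30, n_periods=20)
        assert ens.counts()["exited"] == 40

    def test_timestep_cap_enforced(self):
        masks = open_box_masks()
        fld = uniform_field(masks)
        ens = tr.seed_particles(masks, fld, n=5, seed=0)
        with pytest.raises(ValueError):
            tr.advect(ens, [fld] * 8, masks, period=1.0 / 30, dt=1.0)


class TestChamberTransport:
    def test_determinism(self, coarse_case):
        masks, fields = coarse_case["masks"], coarse_case["fields"]
        period = 1.0 / 30
        fates = []
        for _ in range(2):
            ens = tr.seed_particles(masks, fields[0], n=100, seed=42)
            tr.advect(ens, fields, masks, period, dt=period / 100, n_periods=4)
            fates.append(ens.fate.copy())
        assert np.array_equal(fates[0], fates[1])

    def test_most_particles_resolve_onto_the_filter(self, coarse_case):
        masks, fields = coarse_case["masks"], coarse_case["fields"]
        ens = tr.seed_particles(masks, fields[0], n=200, seed=3)
        tr.advect(ens, fields, masks, 1.0 / 30, dt=1.0 / 3000, n_periods=10)
        eff, counts = tr.encounter_efficiency(ens)
        assert counts["captured"] + counts["exited"] > 0.7 * 200
        assert eff > 0.8

    def test_flux_weighted_and_uniform_estimators_agree(self, coarse_case):
        masks, fields = coarse_case["masks"], coarse_case["fields"]
        effs = {}
        for fw in (True, False):
            ens = tr.seed_particles(
                masks, fields[0], n=300, seed=1, flux_weighted=fw
            )
            tr.advect(ens, fields, masks, 1.0 / 30, dt=1.0 / 3000, n_periods=10)
            effs[fw], _ = tr.encounter_efficiency(ens)
        # both estimators target the flux-weighted encounter probability
        assert effs[True] == pytest.approx(effs[False], abs=0.08)
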