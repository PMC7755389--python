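import numpy as np
import pytest

from syconpump.geometry import (
    ChamberGeometry,
    InvalidGeometryError,
    build_unit_cell,
    collar_resistance,
    collar_resistance_profile,
    reference_geometry,
)


class TestReferenceGeometry:
    def test_printed_dimensions(self):
        g = reference_geometry()
        assert g.ostium_diameter == 7.0
        assert g.ostium_length == 3.0
        assert g.collar_diameter == 2.5
        assert g.collar_length == 4.8
        assert g.microvillus_diameter == 0.1
        assert g.microvillus_spacing == 0.05
        assert g.flagella_spacing == 5.0
        assert g.n_choanocytes == 24
        assert g.chamber_diameter == 85.0
        assert not g.gasket_present

    def test_collar_lattice(self):
        g = reference_geometry()
        centers = g.collar_centers()
        assert len(centers) == 24
        # the ostium sits at the vacant central lattice site
        cx, cz = g.ostium_center()
        d = np.hypot(centers[:, 0] - cx, centers[:, 1] - cz)
        assert d.min() >= g.flagella_spacing - 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ostium_diameter": -1.0},
            {"collar_length": 0.0},
            {"collar_diameter": 6.0},       # wider than flagella spacing
            {"microvillus_spacing": 10.0},  # larger than half circumference
            {"n_choanocytes": 10},          # not an odd-square lattice
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(InvalidGeometryError):
            g = ChamberGeometry(**kwargs)
            g.collar_centers()


class TestCollarResistance:
    def test_positive_and_physical_porosity(self):
        cp = collar_resistance(0.05, 0.1)
        assert cp.resistance_coefficient > 0
        assert 0 < cp.porosity < 1
        assert cp.porosity == pytest.approx(1 / 3)

    def test_monotone_in_gap(self):
        a1 = collar_resistance(0.05, 0.1).resistance_coefficient
        a2 = collar_resistance(0.025, 0.1).resistance_coefficient
        a3 = collar_resistance(0.1, 0.1).resistance_coefficient
        assert a2 > a1 > a3

    def test_vanishes_for_wide_gaps(self):
        tight = collar_resistance(0.05, 0.1).resistance_coefficient
        wide = collar_resistance(50.0, 0.1).resistance_coefficient
        assert wide < 1e-3 * tight

    @pytest.mark.parametrize("l,d", [(-0.1, 0.1), (0.0, 0.1), (0.05, 0.0)])
    def test_invalid_inputs(self, l, d):
        with pytest.raises(InvalidGeometryError):
            collar_resistance(l, d)

    def test_base_to_tip_profile(self):
        import dataclasses

        g = dataclasses.replace(
            reference_geometry(), microvillus_spacing=0.08,
            microvillus_spacing_tip=0.02,
        )
        perm = collar_resistance_profile(g)
        # tighter spacing toward the tip means higher resistance there
        assert perm.alpha_at(1.0) > perm.alpha_at(0.0)


class TestUnitCellMasks:
    def test_partition(self):
        masks = build_unit_cell(reference_geometry(), h=0.5)
        solid, porous, fluid = masks.solid, masks.porous, masks.fluid
        assert not np.any(solid & porous)
        assert np.array_equal(fluid, ~(solid | porous))

    def test_collar_shell_volume(self):
        g = reference_geometry()
        h = 0.125
        masks = build_unit_cell(g, h=h)
        alpha_grid = (
            collar_resistance(g.microvillus_spacing, g.microvillus_diameter)
            .resistance_coefficient
            * g.microvillus_diameter
            / h
        )
        # coverage-weighted shell volume (partially cut cells count
        # fractionally, carrying proportionally reduced resistance)
        vol = float(np.sum(masks.alpha)) / alpha_grid * h**3
        r = g.collar_diameter / 2
        expected = g.n_choanocytes * 2 * np.pi * r * h * g.collar_length
        assert vol == pytest.approx(expected, rel=0.02)

    def test_ostium_hole_in_floor(self):
        g = reference_geometry()
        masks = build_unit_cell(g, h=0.5)
        j = masks.y_mouth_index - 1  # top floor-cell layer
        layer = masks.solid[:, j, :]
        x, _, z = masks.cell_centers()
        r2 = (x[:, None] - masks.ostium_center[0]) ** 2 + (
            z[None, :] - masks.ostium_center[1]
        ) ** 2
        hole = r2 < (masks.ostium_radius - masks.h) ** 2
        assert not np.any(layer[hole])
        assert np.all(layer[~hole & (r2 > (masks.ostium_radius + masks.h) ** 2)])

    def test_gasket_spans_between_collars(self):
        import dataclasses

        g = dataclasses.replace(reference_geometry(), gasket_present=True)
        masks = build_unit_cell(g, h=0.5)
        yg = masks.y_floor_top + g.collar_length + 0.25
        j = int(yg / masks.h)
        layer = masks.solid[:, j, :]
        x, _, z = masks.cell_centers()
        # solid midway between two collars, open on a collar axis
        assert layer[np.argmin(np.abs(x - 5.0)), np.argmin(np.abs(z - 2.5))]
        cx, cz = g.collar_centers()[0]
        assert not layer[np.argmin(np.abs(x - cx)), np.argmin(np.abs(z - cz))]

    def test_zero_length_ostium(self):
        import dataclasses

        g = dataclasses.replace(reference_geometry(), ostium_length=0.0)
        masks = build_unit_cell(g, h=0.5)
        # no tube shell hanging below the wall slab
        below = masks.solid[:, : int(masks.y_floor_bot / masks.h) - 1, :]
        assert not np.any(below)

    def test_overlapping_collars_rejected(self):
        g = ChamberGeometry(collar_diameter=4.8)
        with pytest.raises(InvalidGeometryError):
            build_unit_cell(g, h=0.5)
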