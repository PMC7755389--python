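"""Unit-cell geometry of a syconoid flagellated chamber.

The modeled object is the periodic repeating unit of an ascon/sycon-type
flagellated chamber: one inlet pore (ostium) through the chamber wall,
surrounded by a 5 x 5 lattice of choanocytes (24 collars + flagella, the
central lattice site being the ostium itself).  The cylindrical chamber wall
is flattened into the floor of a rectangular box that is periodic in both
horizontal directions; the chamber core lies above the flagellar tips.

Unit system: lengths in um, time in s, viscosity in Pa s, pressure in Pa,
volume flow in um^3/s.  Water viscosity defaults to 1.0e-3 Pa s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

WATER_VISCOSITY = 1.0e-3  # Pa s


class InvalidGeometryError(ValueError):
    """Raised for non-physical chamber dimensions."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Parametric description of the flagellated-chamber unit cell.

    All lengths in um.  The reference configuration has 24 choanocytes on a
    square lattice (5 um pitch) around a central ostium of diameter 7 um and
    length 3 um; collars are 2.5 um wide and 4.8 um long, homogenized porous
    shells standing in for a ring of 0.1 um microvilli with 0.05 um clear
    gaps.
    """

    chamber_diameter: float = 85.0
    ostium_diameter: float = 7.0
    ostium_length: float = 3.0
    collar_diameter: float = 2.5
    collar_length: float = 4.8
    microvillus_diameter: float = 0.1
    microvillus_spacing: float = 0.05       # clear gap between microvilli
    microvillus_spacing_tip: float | None = None  # optional base->tip profile
    flagella_spacing: float = 5.0
    n_choanocytes: int = 24
    gasket_present: bool = False
    gasket_height: float | None = None      # defaults to collar_length
    core_headroom: float = 4.0              # open water above flagellar tips
    plenum_height: float = 2.5              # return plenum below the wall
    floor_thickness: float = 1.0            # chamber-wall slab thickness

    def __post_init__(self) -> None:
        positive = {
            "chamber_diameter": self.chamber_diameter,
            "ostium_diameter": self.ostium_diameter,
            "collar_diameter": self.collar_diameter,
            "collar_length": self.collar_length,
            "microvillus_diameter": self.microvillus_diameter,
            "microvillus_spacing": self.microvillus_spacing,
            "flagella_spacing": self.flagella_spacing,
            "floor_thickness": self.floor_thickness,
        }
        for name, value in positive.items():
            if not value > 0:
                raise InvalidGeometryError(f"{name} must be > 0, got {value}")
        if self.ostium_length < 0:
            raise InvalidGeometryError("ostium_length must be >= 0")
        if self.collar_diameter >= self.flagella_spacing:
            raise InvalidGeometryError(
                "collars must be narrower than the flagella spacing"
            )
        circumference = np.pi * self.collar_diameter
        if self.microvillus_spacing >= circumference / 2:
            raise InvalidGeometryError("microvillus spacing too large for collar")
        if self.n_choanocytes < 1:
            raise InvalidGeometryError("need at least one choanocyte")

    # --- derived quantities ---------------------------------------------

    @property
    def lattice_side(self) -> int:
        """Choanocytes sit on a side x side lattice with the ostium central."""
        side = int(round(np.sqrt(self.n_choanocytes + 1)))
        if side * side != self.n_choanocytes + 1 or side % 2 == 0:
            raise InvalidGeometryError(
                "n_choanocytes + 1 must be an odd perfect square "
                f"(got {self.n_choanocytes})"
            )
        return side

    @property
    def cell_extent(self) -> tuple[float, float, float]:
        """(Lx, Ly, Lz) of the rectangular unit cell in um (y vertical)."""
        lxz = self.lattice_side * self.flagella_spacing
        ly = (
            self.plenum_height
            + self.ostium_length
            + self.floor_thickness
            + _FLAGELLUM_HEADROOM_HINT
            + self.core_headroom
        )
        return (lxz, ly, lxz)

    @property
    def gasket_y(self) -> float:
        return self.gasket_height if self.gasket_height is not None else self.collar_length

    def collar_centers(self) -> np.ndarray:
        """(n, 2) horizontal collar-axis positions; ostium at the cell center."""
        side = self.lattice_side
        s = self.flagella_spacing
        xs = (np.arange(side) + 0.5) * s
        pts = [(x, z) for x in xs for z in xs]
        cx = cz = side * s / 2.0
        return np.array([p for p in pts if not np.allclose(p, (cx, cz))])

    def ostium_center(self) -> tuple[float, float]:
        lxz = self.lattice_side * self.flagella_spacing
        return (lxz / 2.0, lxz / 2.0)


# Vertical room reserved for flagella in the default cell extent; the solver
# grid recomputes the exact height from the kinematics it is given.
_FLAGELLUM_HEADROOM_HINT = 15.7


def reference_geometry() -> ChamberGeometry:
    """Base-case chamber: all dimensions of the reference configuration."""
    return ChamberGeometry()


@dataclass(frozen=True)
class CollarPermeability:
    """Darcy-type resistance of the homogenized microvillar collar wall.

    ``resistance_coefficient`` (alpha, Pa s / um^2) is defined such that the
    pressure drop for normal through-flow at superficial speed U across a
    wall of physical thickness t (one microvillus diameter) is alpha * U * t.
    """

    resistance_coefficient: float
    porosity: float
    wall_thickness: float
    profile: Callable[[float], float] | None = None  # arclength frac -> alpha

    def alpha_at(self, frac: float) -> float:
        if self.profile is None:
            return self.resistance_coefficient
        return self.profile(frac)


def row_drag_expansion(t: float) -> float:
    """Dilute-row drag F/(mu U) from the classical small-t expansion,
    t = 2 pi a / b.  Valid for t well below ~1.6; used as a limit check of
    the full grating solution, not as the production formula."""
    lam = 1.0 - 2.0 * np.log(t) + t**2 / 6.0 - t**4 / 144.0
    if lam <= 0:
        raise InvalidGeometryError("row too dense for the dilute expansion")
    return 8.0 * np.pi / lam


def collar_resistance(
    l: float, d_mv: float, mu: float = WATER_VISCOSITY
) -> CollarPermeability:
    """Homogenized resistance of a collar wall of parallel microvilli.

    Parameters
    ----------
    l : clear gap between neighboring microvilli, um.
    d_mv : microvillus diameter, um.
    mu : dynamic viscosity, Pa s.

    The collar wall is a single row of equally spaced parallel cylinders
    (center-to-center spacing b = l + d_mv).  The pressure drop per row at
    superficial normal speed U is F/b with F the drag per unit cylinder
    length from the classical grating solution (periodic Stokeslet-row
    singularity method, :mod:`syconpump.grating`); it is expressed as a
    Darcy coefficient over the physical wall thickness d_mv.
    """
    if l <= 0 or d_mv <= 0:
        raise InvalidGeometryError("microvillus gap and diameter must be > 0")
    if mu <= 0:
        raise InvalidGeometryError("viscosity must be > 0")
    from .grating import row_drag_coefficient

    b = l + d_mv
    coef = row_drag_coefficient(l / d_mv)           # F/(mu U), dimensionless
    drop_per_speed = coef * mu / b                  # Pa per (um/s)
    alpha = drop_per_speed / d_mv
    porosity = l / b
    return CollarPermeability(
        resistance_coefficient=float(alpha),
        porosity=float(porosity),
        wall_thickness=float(d_mv),
    )


def collar_resistance_profile(
    geom: ChamberGeometry, mu: float = WATER_VISCOSITY
) -> CollarPermeability:
    """Collar permeability honoring an optional base->tip gap profile.

    When ``microvillus_spacing_tip`` is set, the clear gap is interpolated
    linearly from the base value to the tip value along the collar height and
    alpha is recomputed per height fraction.
    """
    base = collar_resistance(geom.microvillus_spacing, geom.microvillus_diameter, mu)
    if geom.microvillus_spacing_tip is None:
        return base

    l0, l1 = geom.microvillus_spacing, geom.microvillus_spacing_tip

    def profile(frac: float) -> float:
        l_here = l0 + (l1 - l0) * float(np.clip(frac, 0.0, 1.0))
        return collar_resistance(l_here, geom.microvillus_diameter, mu).resistance_coefficient

    return replace(base, profile=profile)


# ---------------------------------------------------------------------------
# Discrete masks


@dataclass(frozen=True)
class VerticalLayout:
    """Vertical stacking of the periodic unit cell (all in um, y upward).

    Bottom to top: return plenum (the periodic wrap from the chamber core),
    hanging ostium tube, chamber-wall slab with the central perforation,
    collars + flagella, open core headroom.
    """

    y_floor_bot: float
    y_floor_top: float
    tube_len: float
    ly: float
    y_tip: float
    y_force: tuple[float, float]
    y_exit: float


def vertical_layout(
    geom: ChamberGeometry, h: float, flagellum_length: float
) -> VerticalLayout:
    t_floor = max(geom.floor_thickness, 2 * h)
    tube_len = max(geom.ostium_length - t_floor, 0.0)
    y_floor_bot = geom.plenum_height + tube_len
    y_floor_top = y_floor_bot + t_floor
    y_tip = y_floor_top + flagellum_length
    ly_raw = y_tip + geom.core_headroom
    ly = int(np.ceil(ly_raw / h - 1e-9)) * h
    return VerticalLayout(
        y_floor_bot=y_floor_bot,
        y_floor_top=y_floor_top,
        tube_len=tube_len,
        ly=ly,
        y_tip=y_tip,
        y_force=(0.5, 1.5),
        y_exit=y_tip + geom.core_headroom / 2.0,
    )


def solid_at(
    geom: ChamberGeometry,
    layout: VerticalLayout,
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    pad: float = 0.0,
    min_wall: float = 0.0,
) -> np.ndarray:
    """Rigid-region indicator at arbitrary points (broadcastable coords).

    ``pad`` grows every solid by a fixed margin (the wall-placement
    convention of the staggered-grid solver: the no-slip surface of the
    discrete obstacle sits about half a constrained-point spacing inside
    the outermost constrained points, so solids are grown by that margin
    when selecting which face unknowns to constrain).  ``min_wall`` keeps
    thin structures at least that thick.
    """
    cx, cz = geom.ostium_center()
    r_ost = geom.ostium_diameter / 2.0
    r2_ost = (X - cx) ** 2 + (Z - cz) ** 2

    solid = np.zeros(np.broadcast_shapes(X.shape, Y.shape, Z.shape), dtype=bool)

    # chamber wall slab with the ostium perforation
    in_slab = (Y >= layout.y_floor_bot - pad) & (Y < layout.y_floor_top + pad)
    solid |= in_slab & (r2_ost >= (r_ost - pad) ** 2)

    # ostium tube: rigid shell hanging below the wall
    if layout.tube_len > 0:
        wall = max(min_wall, 1.0)
        in_band = (Y >= geom.plenum_height - pad) & (Y < layout.y_floor_bot + pad)
        shell = (r2_ost >= (r_ost - pad) ** 2) & (
            r2_ost < (r_ost + wall + pad) ** 2
        )
        solid |= in_band & shell

    # optional impermeable gasket baffle spanning between collar tips; its
    # openings match the collar interiors so the porous wall annulus is
    # sealed and all through-flow must cross the collar filter
    if geom.gasket_present:
        yg = layout.y_floor_top + geom.gasket_y
        tg = max(min_wall, 1.0)
        in_gasket = (Y >= yg - pad) & (Y < yg + tg + pad)
        gasket = np.broadcast_to(in_gasket, solid.shape).copy()
        # openings match the rasterized collar interior (the shell band is
        # min_wall/2 thick on each side of the nominal radius); growing the
        # solid by pad shrinks the holes, consistent with every other shape
        r_hole = geom.collar_diameter / 2.0 - min_wall / 4.0
        for cxy, czy in geom.collar_centers():
            r2 = (X - cxy) ** 2 + (Z - czy) ** 2
            gasket &= ~np.broadcast_to(
                r2 < max(r_hole - pad, 0.0) ** 2, solid.shape
            )
        solid |= gasket

    return solid


def alpha_at(
    geom: ChamberGeometry,
    layout: VerticalLayout,
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    shell_thickness: float,
    mu: float = WATER_VISCOSITY,
    antialias: bool = True,
) -> np.ndarray:
    """Brinkman resistance field (Pa s / um^2) of the porous collar shells.

    The homogenized shell is ``shell_thickness`` thick on the grid; the
    coefficient is rescaled so the integrated wall resistance matches the
    physical one (alpha_phys * microvillus diameter).  Cells partially cut
    by the thin annulus carry a proportionally reduced coefficient
    (anti-aliased coverage, 3 x 3 in-plane subsampling), so the integrated
    shell volume and resistance are insensitive to how the ring falls on
    the grid.
    """
    perm = collar_resistance_profile(geom, mu)
    r_col = geom.collar_diameter / 2.0
    t = shell_thickness
    shape = np.broadcast_shapes(X.shape, Y.shape, Z.shape)
    y0 = layout.y_floor_top
    y1 = y0 + geom.collar_length
    # fractional vertical coverage of the sampling cell at the band edges
    in_band = np.clip((y1 - Y) / t + 0.5, 0.0, 1.0) * np.clip(
        (Y - y0) / t + 0.5, 0.0, 1.0
    )
    frac = np.clip((Y - y0) / geom.collar_length, 0.0, 1.0)
    if perm.profile is None:
        alpha_y = np.full(shape, perm.resistance_coefficient)
    else:
        alpha_y = np.vectorize(perm.alpha_at)(frac)
    alpha_y = alpha_y * perm.wall_thickness / t
    offsets = (
        np.array([-1.0, 0.0, 1.0]) * (t / 3.0) if antialias else np.array([0.0])
    )
    coverage = np.zeros(shape, dtype=float)
    for cxy, czy in geom.collar_centers():
        cov = np.zeros(shape, dtype=float)
        for ox in offsets:
            for oz in offsets:
                r2 = (X + ox - cxy) ** 2 + (Z + oz - czy) ** 2
                cov += (r2 >= (r_col - t / 2) ** 2) & (r2 < (r_col + t / 2) ** 2)
        coverage = np.maximum(coverage, cov / len(offsets) ** 2)
    return in_band * coverage * alpha_y


@dataclass
class UnitCellMasks:
    """Labeled cell-centered masks of the unit cell on a uniform grid.

    Axis order is (x, y, z) with y vertical.  The box is periodic in all
    three directions; the vertical period closes the flow loop chamber core
    -> plenum -> ostium -> chamber.  ``solid`` marks rigid impermeable cells
    (chamber wall, ostium tube, optional gasket), ``alpha`` is the Brinkman
    resistance field of the porous collar shells (zero elsewhere).
    """

    h: float
    shape: tuple[int, int, int]
    solid: np.ndarray          # bool, rigid cells
    alpha: np.ndarray          # float, Pa s / um^2, porous collar shells
    y_floor_top: float         # um, chamber-wall top (collar bases)
    y_floor_bot: float
    y_mouth_index: int         # v-face index of the ostium mouth plane
    y_force: tuple[float, float]   # back-pressure body-force layer bounds
    y_exit: float              # tracer exit plane toward the chamber core
    collar_centers: np.ndarray
    collar_inner_radius: float
    collar_outer_radius: float
    collar_length: float
    ostium_center: tuple[float, float]
    ostium_radius: float
    extent: tuple[float, float, float]

    @property
    def porous(self) -> np.ndarray:
        return self.alpha > 0

    @property
    def fluid(self) -> np.ndarray:
        return ~self.solid & ~self.porous

    def cell_centers(self):
        nx, ny, nz = self.shape
        h = self.h
        x = (np.arange(nx) + 0.5) * h
        y = (np.arange(ny) + 0.5) * h
        z = (np.arange(nz) + 0.5) * h
        return x, y, z


def build_unit_cell(
    geom: ChamberGeometry,
    h: float,
    mu: float = WATER_VISCOSITY,
    flagellum_length: float = _FLAGELLUM_HEADROOM_HINT,
) -> UnitCellMasks:
    """Rasterize the unit-cell geometry onto a uniform periodic grid.

    The vertical stack, bottom to top: return plenum, hanging ostium tube,
    chamber-wall slab with the central perforation, collars + flagella, open
    core headroom.  Collar shells become Brinkman cells; everything rigid
    becomes solid cells.
    """
    lxz = geom.lattice_side * geom.flagella_spacing
    nxz = int(round(lxz / h))
    if not np.isclose(nxz * h, lxz):
        raise InvalidGeometryError(
            f"grid spacing {h} does not divide the cell extent {lxz}"
        )
    layout = vertical_layout(geom, h, flagellum_length)
    ny = int(round(layout.ly / h))

    shape = (nxz, ny, nxz)
    x, y, z = [(np.arange(n) + 0.5) * h for n in shape]
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    solid = solid_at(geom, layout, X, Y, Z, pad=0.0, min_wall=2 * h)
    t_shell = h
    alpha = alpha_at(geom, layout, X, Y, Z, shell_thickness=t_shell, mu=mu)
    alpha[solid] = 0.0

    # sanity: disjoint collar shells
    r_col = geom.collar_diameter / 2.0
    centers = geom.collar_centers()
    if len(centers) > 1:
        dmin = np.min(
            [np.hypot(*(a - b)) for i, a in enumerate(centers) for b in centers[:i]]
        )
        if dmin < 2 * (r_col + t_shell / 2):
            raise InvalidGeometryError("collar shells overlap")

    cx, cz = geom.ostium_center()
    return UnitCellMasks(
        h=h,
        shape=shape,
        solid=solid,
        alpha=alpha,
        y_floor_top=layout.y_floor_top,
        y_floor_bot=layout.y_floor_bot,
        y_mouth_index=int(round(layout.y_floor_top / h)),
        y_force=layout.y_force,
        y_exit=layout.y_exit,
        collar_centers=centers,
        collar_inner_radius=r_col - t_shell / 2,
        collar_outer_radius=r_col + t_shell / 2,
        collar_length=geom.collar_length,
        ostium_center=(cx, cz),
        ostium_radius=geom.ostium_diameter / 2.0,
        extent=(lxz, layout.ly, lxz),
    )
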