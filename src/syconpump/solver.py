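"""Quasi-steady Stokes flow in the flagellated-chamber unit cell.

At chamber scales (tens of um, 30 Hz) the Reynolds number is ~1e-3 and the
oscillatory (Womersley) parameter is far below one, so the flow field at
each instant of the beat cycle is the steady Stokes solution for the
instantaneous sheet configuration and velocity ("quasi-static" stepping
through the beat period).

Discretization: uniform staggered (MAC) grid, periodic in all three
directions.  The vertical period closes the flow loop (chamber core ->
plenum -> ostium -> chamber), standing in for the uniform-pressure inlet
and core boundaries: pressure in the plenum and the core is uniform to
discretization accuracy because both regions are wide open.  Stationary
rigid surfaces (chamber wall, ostium tube, gasket) are eliminated face
unknowns; the beating sheets are immersed-boundary marker constraints and
the porous collars regularized Brinkman constraints (-alpha*u).  The
grad-div-augmented saddle system is solved by LGMRES with an exact FFT
inverse of the constant-coefficient periodic Stokes operator on the
velocity/pressure block and per-sheet mobility blocks on the multipliers.

A back-pressure load on the pumping unit is imposed as a uniform vertical
body-force layer spanning the plenum cross-section: circulating once around
the periodic loop, the pressure drops by exactly the integrated force, which
is the adverse pressure the pump must overcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.sparse.linalg import LinearOperator, lgmres

from .geometry import (
    ChamberGeometry,
    UnitCellMasks,
    VerticalLayout,
    WATER_VISCOSITY,
    alpha_at,
    solid_at,
    vertical_layout,
)
from .kinematics import BeatKinematics, sheet_point_cloud, sheet_state

#: Wall-placement convention: solids are grown by this fraction of h when
#: selecting which face unknowns to constrain, so that the effective no-slip
#: surface of the stair-stepped obstacle coincides with the nominal one
#: (verified against the Poiseuille closed form, see tests).
WALL_PAD_FRACTION = 0.35


class SolverError(RuntimeError):
    """Linear solve failed to reach the requested residual."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the unit-cell flow solver."""

    h: float = 0.625               # um grid spacing
    phases_per_period: int = 8
    rtol: float = 1e-7             # Krylov relative tolerance
    viscosity: float = WATER_VISCOSITY
    back_pressure: float = 0.0     # Pa, adverse load on the pumping unit
    maxiter: int = 30000
    use_symmetry: bool = True      # exploit the half-period mirror symmetry
    compliance_factor: float = 1e-3  # sheet-constraint Tikhonov compliance
    inner_m: int = 200             # Krylov restart depth (LGMRES inner space)

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.phases_per_period < 8:
            raise ValueError("need at least 8 phases per period")
        if self.rtol > 1e-6:
            raise ValueError("linear-solve tolerance must be <= 1e-6")


# ---------------------------------------------------------------------------
# generic staggered-grid Stokes problem


@dataclass
class StokesProblem:
    """One steady Stokes solve: constraints, Brinkman field, body force.

    Stationary rigid surfaces are eliminated face unknowns; the moving
    flagellar sheets are immersed-boundary markers whose trilinearly
    interpolated velocity is constrained to the sheet velocity through
    Lagrange multipliers (point forces spread by the transposed
    interpolation).  A small compliance regularizes nearly coincident
    markers at sub-grid vane widths.
    """

    shape: tuple[int, int, int]
    h: float
    nu: float
    rigid: tuple[np.ndarray, np.ndarray, np.ndarray]       # bool per face comp
    target: tuple[np.ndarray, np.ndarray, np.ndarray]      # imposed velocities
    alpha: tuple[np.ndarray, np.ndarray, np.ndarray]       # Brinkman, per face
    body: tuple[np.ndarray, np.ndarray, np.ndarray]        # force density, Pa/um
    marker_J: tuple | None = None          # sparse (m, N) per component
    marker_target: np.ndarray | None = None  # (m, 3) sheet velocities
    marker_points: np.ndarray | None = None  # (m, 3) positions, um
    marker_groups: np.ndarray | None = None  # (m,) sheet id per marker
    group_centers: np.ndarray | None = None  # (n, 2) collar axes (x, z)
    compliance_factor: float = 3e-3        # x h^2/mu Tikhonov compliance
    grad_div_factor: float = 30.0          # augmented-Lagrangian gamma / nu

    def __post_init__(self) -> None:
        import scipy.sparse as sp

        self.free = tuple(~r for r in self.rigid)
        all6 = self.rigid[0] & np.roll(self.rigid[0], -1, 0)
        all6 &= self.rigid[1] & np.roll(self.rigid[1], -1, 1)
        all6 &= self.rigid[2] & np.roll(self.rigid[2], -1, 2)
        self.active_p = ~all6
        self.n_markers = 0 if self.marker_target is None else len(self.marker_target)
        self.compliance = self.compliance_factor * self.h**2 / self.nu
        self.gamma = self.grad_div_factor * self.nu  # grad-div augmentation
        # unified constraint blocks per component: sheet markers (trilinear
        # rows, Tikhonov compliance) followed by Brinkman faces (identity
        # rows with compliance 1/alpha, the regularized-multiplier form of
        # the resistance term: g = alpha u, keeping the velocity operator a
        # pure Laplacian that the FFT preconditioner inverts exactly)
        N = int(np.prod(self.shape))
        self.con_J, self.con_target, self.con_C = [], [], []
        for c in range(3):
            Js, ts, Cs = [], [], []
            if self.n_markers:
                Js.append(self.marker_J[c])
                ts.append(self.marker_target[:, c])
                Cs.append(np.full(self.n_markers, self.compliance))
            a = self.alpha[c].ravel()
            idx = np.flatnonzero(a > 0)
            if len(idx):
                Js.append(
                    sp.csr_matrix(
                        (np.ones(len(idx)), (np.arange(len(idx)), idx)),
                        shape=(len(idx), N),
                    )
                )
                ts.append(np.zeros(len(idx)))
                Cs.append(1.0 / a[idx])
            if Js:
                self.con_J.append(sp.vstack(Js).tocsr())
                self.con_target.append(np.concatenate(ts))
                self.con_C.append(np.concatenate(Cs))
            else:
                self.con_J.append(None)
                self.con_target.append(np.zeros(0))
                self.con_C.append(np.zeros(0))
        self.n_con = [len(t) for t in self.con_target]
        # constraint-row positions and cluster ids (per component), used by
        # the block preconditioner: each choanocyte unit (sheet + its
        # collar shell) forms one strongly coupled cluster
        self.con_pos, self.con_group = [], []
        h = self.h
        for c in range(3):
            pos_parts = []
            if self.n_markers:
                pos_parts.append(self.marker_points)
            a = self.alpha[c].ravel()
            idx = np.flatnonzero(a > 0)
            if len(idx):
                ijk = np.array(np.unravel_index(idx, self.shape), dtype=float).T
                offs = np.full(3, 0.5)
                offs[c] = 0.0
                pos_parts.append((ijk + offs) * h)
            if not pos_parts:
                self.con_pos.append(np.zeros((0, 3)))
                self.con_group.append(np.zeros(0, dtype=int))
                continue
            pos = np.concatenate(pos_parts)
            self.con_pos.append(pos)
            if self.group_centers is not None and len(self.group_centers):
                d2 = (
                    (pos[:, 0, None] - self.group_centers[None, :, 0]) ** 2
                    + (pos[:, 2, None] - self.group_centers[None, :, 1]) ** 2
                )
                self.con_group.append(np.argmin(d2, axis=1))
            else:
                self.con_group.append(np.zeros(len(pos), dtype=int))
        self.sizes = (
            [int(m.sum()) for m in self.free]
            + [int(self.active_p.sum())]
            + [sum(self.n_con)]
        )


@dataclass
class FlowField:
    """Velocity/pressure solution at one beat phase on the staggered grid."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    h: float
    t: float
    phase_index: int
    residual: float
    iterations: int
    mirrored: bool = False  # synthesized from the half-period symmetry
    g: np.ndarray | None = None  # (m, 3) sheet constraint forces

    def face_centers(self, comp: int):
        n = self.u.shape
        h = self.h
        coords = []
        for ax in range(3):
            if ax == comp:
                coords.append(np.arange(n[ax]) * h)
            else:
                coords.append((np.arange(n[ax]) + 0.5) * h)
        return coords


def _lap(a: np.ndarray, h: float) -> np.ndarray:
    out = -6.0 * a
    for ax in range(3):
        out += np.roll(a, 1, ax) + np.roll(a, -1, ax)
    return out / (h * h)


def _div(u, v, w, h):
    return (
        np.roll(u, -1, 0) - u + np.roll(v, -1, 1) - v + np.roll(w, -1, 2) - w
    ) / h


def _grad(p, h):
    return (
        (p - np.roll(p, 1, 0)) / h,
        (p - np.roll(p, 1, 1)) / h,
        (p - np.roll(p, 1, 2)) / h,
    )


def _momentum(prob: StokesProblem, u, v, w, p):
    # the Brinkman resistance is handled as regularized constraints, not here
    gx, gy, gz = _grad(p, prob.h)
    nu = prob.nu
    return (
        -nu * _lap(u, prob.h) + gx,
        -nu * _lap(v, prob.h) + gy,
        -nu * _lap(w, prob.h) + gz,
    )


class _SaddleOperator:
    """Matrix-free symmetric saddle operator on the free unknowns.

    The preconditioner is the exact FFT inverse of the constant-coefficient
    periodic Stokes operator (velocity Laplacian + discrete grad/div
    coupling), which is exact away from the constrained surfaces and the
    collar shells; the Krylov iteration only has to resolve those.
    """

    def __init__(self, prob: StokesProblem):
        self.prob = prob
        self.n = sum(prob.sizes)
        h = prob.h
        d = []
        lam = 0.0
        for ax, n_ax in enumerate(prob.shape):
            k = np.fft.rfftfreq(n_ax) if ax == 2 else np.fft.fftfreq(n_ax)
            sym = (1.0 - np.exp(-2j * np.pi * k)) / h  # discrete gradient
            sh = [1, 1, 1]
            sh[ax] = -1
            d.append(sym.reshape(sh))
            lam = lam + np.abs(sym.reshape(sh)) ** 2
        self.d = d
        self.lam = lam
        # response scale for the zero (mean-flow) mode: comparable to the
        # smallest nonzero Laplacian eigenvalue (wall friction sets it in
        # the constrained problem; it only needs the right order)
        lam_pos = lam[lam > 0]
        self.eps = prob.nu * float(lam_pos.min())
        # per-constraint Schur scale: local point-force mobility weighted by
        # how much of the row acts on free unknowns, plus the compliance
        self.con_scale = []
        self.row_weight = []
        for c in range(3):
            J = prob.con_J[c]
            if J is None:
                self.con_scale.append(np.zeros(0))
                self.row_weight.append(np.zeros(0))
                continue
            freew = prob.free[c].ravel().astype(float)
            rn = np.asarray((J.power(2) @ freew)).ravel()
            self.row_weight.append(rn)
            self.con_scale.append(
                0.13 * h**2 / prob.nu * rn + prob.con_C[c]
            )
        self._build_marker_blocks()

    def _build_marker_blocks(self):
        """Dense approximate Schur blocks for the sheet markers, one per
        flagellum and component.

        Nearly coincident sheet markers (sub-grid vane widths, crowded
        chunk rows) make the marker Schur complement strongly
        non-diagonal.  Because the saddle solve enforces incompressibility,
        the velocity response to a marker force is the projected
        (Stokeslet-like) mobility; the component-averaged regularized
        Stokeslet 1/re (an inverse multiquadric, hence positive definite)
        with blob size ~ the grid spacing approximates it well enough for
        preconditioning.  Brinkman shell rows keep the diagonal scale.
        """
        from scipy.linalg import cho_factor

        self.marker_blocks = None
        pr = self.prob
        if not pr.n_markers or pr.marker_points is None:
            return
        h, nu = pr.h, pr.nu
        kreg = 1.2
        pts = pr.marker_points
        groups = pr.marker_groups
        if groups is None:
            groups = np.zeros(len(pts), dtype=int)
        blocks = [[] for _ in range(3)]
        for gid in np.unique(groups):
            idx = np.flatnonzero(groups == gid)
            dr = pts[idx, None, :] - pts[None, idx, :]
            re = np.sqrt(np.sum(dr**2, axis=-1) + (kreg * h) ** 2)
            G = h**3 / (6.0 * np.pi * nu * re)
            for c in range(3):
                rw = self.row_weight[c][idx]
                S = G * np.sqrt(np.outer(rw, rw)) + np.diag(pr.con_C[c][idx])
                try:
                    blocks[c].append((idx, cho_factor(S)))
                except np.linalg.LinAlgError:
                    pass
        self.marker_blocks = blocks

    # -- packing helpers
    def pack(self, u, v, w, p, g=None):
        pr = self.prob
        parts = [u[pr.free[0]], v[pr.free[1]], w[pr.free[2]], p[pr.active_p]]
        for c in range(3):
            if pr.n_con[c]:
                if g is None or g[c] is None or len(g[c]) != pr.n_con[c]:
                    parts.append(np.zeros(pr.n_con[c]))
                else:
                    parts.append(g[c])
        return np.concatenate(parts)

    def unpack(self, x):
        pr = self.prob
        out = []
        i = 0
        for m in pr.free:
            a = np.zeros(pr.shape)
            n = int(m.sum())
            a[m] = x[i : i + n]
            i += n
            out.append(a)
        p = np.zeros(pr.shape)
        np_ = int(pr.active_p.sum())
        p[pr.active_p] = x[i : i + np_]
        i += np_
        g = []
        for c in range(3):
            g.append(x[i : i + pr.n_con[c]])
            i += pr.n_con[c]
        return (*out, p, g)

    def matvec(self, x):
        pr = self.prob
        u, v, w, p, g = self.unpack(x)
        ru, rv, rw = _momentum(pr, u, v, w, p)
        # grad-div augmentation gamma * G G^T u (vanishes at the solution)
        rp = -_div(u, v, w, pr.h)
        gdx, gdy, gdz = _grad(rp, pr.h)
        ru += pr.gamma * gdx
        rv += pr.gamma * gdy
        rw += pr.gamma * gdz
        parts_g = []
        for c, (a, r) in enumerate(zip((u, v, w), (ru, rv, rw))):
            J = pr.con_J[c]
            if J is None:
                continue
            r += (J.T @ g[c]).reshape(pr.shape)
            parts_g.append(J @ a.ravel() - pr.con_C[c] * g[c])
        rp_a = rp[pr.active_p]
        rp_a -= rp_a.mean()
        out = [ru[pr.free[0]], rv[pr.free[1]], rw[pr.free[2]], rp_a]
        out.extend(parts_g)
        return np.concatenate(out)

    def precond(self, x):
        pr = self.prob
        u, v, w, p, g = self.unpack(x)
        nu = pr.nu
        gam = pr.gamma
        ru = [np.fft.rfftn(a) for a in (u, v, w)]
        rp = np.fft.rfftn(p)
        lam, d = self.lam, self.d
        lam_safe = np.where(lam == 0, 1.0, lam)
        dHr = sum(np.conj(d[c]) * ru[c] for c in range(3))
        ph = dHr / lam_safe - (nu + gam) * rp
        denom = nu * lam_safe
        # (A + gamma d d^H)^-1 via Sherman-Morrison on each wavenumber
        sm = gam / (denom * (denom + gam * lam))
        dHx = dHr - lam * ph
        uh = [
            (ru[c] - d[c] * ph) / denom - d[c] * sm * dHx for c in range(3)
        ]
        zero = lam == 0
        for c in range(3):
            uh[c][zero] = ru[c][zero] / self.eps
        ph[zero] = 0.0
        axes = (0, 1, 2)
        out_u = [np.fft.irfftn(a, s=pr.shape, axes=axes) for a in uh]
        out_p = np.fft.irfftn(ph, s=pr.shape, axes=axes)
        out_pa = out_p[pr.active_p]
        out_pa -= out_pa.mean()
        parts = [out_u[0][pr.free[0]], out_u[1][pr.free[1]],
                 out_u[2][pr.free[2]], out_pa]
        from scipy.linalg import cho_solve

        for c in range(3):
            if not pr.n_con[c]:
                continue
            gc = g[c] / self.con_scale[c]
            if self.marker_blocks is not None:
                for idx, fac in self.marker_blocks[c]:
                    gc[idx] = cho_solve(fac, g[c][idx])
            parts.append(gc)
        return np.concatenate(parts)


def solve_stokes(
    prob: StokesProblem,
    rtol: float = 1e-7,
    maxiter: int = 30000,
    warm: tuple | None = None,
    inner_m: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """Solve one steady Stokes problem; returns full-grid (u, v, w, p).

    Krylov iteration (LGMRES) on the free unknowns, preconditioned by the
    constant-coefficient periodic Stokes inverse; convergence is verified on
    the true residual and the solve restarts with a tighter inner tolerance
    if needed.
    """
    op = _SaddleOperator(prob)
    pr = prob

    ubc = [np.where(pr.rigid[c], pr.target[c], 0.0) for c in range(3)]
    fu, fv, fw = _momentum(pr, ubc[0], ubc[1], ubc[2], np.zeros(pr.shape))
    div_bc = _div(ubc[0], ubc[1], ubc[2], pr.h)
    gbx, gby, gbz = _grad(div_bc, pr.h)
    rhs_u = pr.body[0] - fu + pr.gamma * gbx
    rhs_v = pr.body[1] - fv + pr.gamma * gby
    rhs_w = pr.body[2] - fw + pr.gamma * gbz
    rhs_p = div_bc[pr.active_p]
    rhs_p -= rhs_p.mean()
    parts = [rhs_u[pr.free[0]], rhs_v[pr.free[1]], rhs_w[pr.free[2]], rhs_p]
    for c in range(3):
        if pr.n_con[c]:
            parts.append(pr.con_target[c] - pr.con_J[c] @ ubc[c].ravel())
    b = np.concatenate(parts)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        zero = np.zeros(pr.shape)
        return ubc[0], ubc[1], ubc[2], zero, {
            "iterations": 0, "residual": 0.0, "g": None,
        }

    A = LinearOperator((op.n, op.n), matvec=op.matvec)
    M = LinearOperator((op.n, op.n), matvec=op.precond)

    it = 0

    def cb(_):
        nonlocal it
        it += 1

    x = op.pack(*warm) if warm is not None else None
    inner_rtol = rtol
    res = np.inf
    res_prev = np.inf
    im = inner_m
    for attempt in range(5):
        x, _info = lgmres(
            A, b, x0=x, rtol=inner_rtol, atol=0.0,
            maxiter=max(min(maxiter, 9000) // im, 5), inner_m=im, outer_k=8,
            M=M, callback=cb,
        )
        res = float(np.linalg.norm(op.matvec(x) - b) / bnorm)
        if res <= rtol:
            break
        # a stalled restart cycle usually yields to a deeper Krylov space
        if res > 0.3 * res_prev:
            im = min(3 * im, 600)
        res_prev = res
        inner_rtol /= 100.0
    if res > 100 * rtol:
        raise SolverError(
            f"linear solve stalled: relative residual {res:.2e} "
            f"after {it} outer iterations"
        )
    u, v, w, p, g = op.unpack(x)
    u += ubc[0]
    v += ubc[1]
    w += ubc[2]
    return u, v, w, p, {"iterations": it, "residual": res, "g": g}


# ---------------------------------------------------------------------------
# chamber problem assembly


def _face_coords(shape, h, comp):
    coords = []
    for ax, n in enumerate(shape):
        c = np.arange(n) * h if ax == comp else (np.arange(n) + 0.5) * h
        sh = [1, 1, 1]
        sh[ax] = -1
        coords.append(c.reshape(sh))
    return coords


def interp_matrix(shape, h, comp, pts):
    """Sparse trilinear interpolation matrix (m, prod(shape)) for one
    staggered component at points (m, 3), periodic in all directions."""
    import scipy.sparse as sp

    m = len(pts)
    idx0, frac = [], []
    for ax in range(3):
        off = 0.0 if ax == comp else 0.5
        f = pts[:, ax] / h - off
        i0 = np.floor(f).astype(int)
        idx0.append(i0)
        frac.append(f - i0)
    rows, cols, vals = [], [], []
    r = np.arange(m)
    for dx in (0, 1):
        wx = frac[0] if dx else 1 - frac[0]
        ii = np.mod(idx0[0] + dx, shape[0])
        for dy in (0, 1):
            wy = frac[1] if dy else 1 - frac[1]
            jj = np.mod(idx0[1] + dy, shape[1])
            for dz in (0, 1):
                wz = frac[2] if dz else 1 - frac[2]
                kk = np.mod(idx0[2] + dz, shape[2])
                rows.append(r)
                cols.append(np.ravel_multi_index((ii, jj, kk), shape))
                vals.append(wx * wy * wz)
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, int(np.prod(shape))),
    )


def chamber_problem(
    geom: ChamberGeometry,
    kin: BeatKinematics,
    cfg: SolverConfig,
    t: float,
) -> tuple[StokesProblem, VerticalLayout]:
    """Assemble the unit-cell Stokes problem at beat phase time t."""
    layout = vertical_layout(geom, cfg.h, kin.flagellum_length)
    lxz = geom.lattice_side * geom.flagella_spacing
    nxz = int(round(lxz / cfg.h))
    ny = int(round(layout.ly / cfg.h))
    shape = (nxz, ny, nxz)
    h = cfg.h
    pad = WALL_PAD_FRACTION * h

    rigid, target, alpha, body = [], [], [], []
    for comp in range(3):
        X, Y, Z = _face_coords(shape, h, comp)
        r = solid_at(geom, layout, X, Y, Z, pad=pad, min_wall=2 * h)
        # binary shell rasterization for the constraint rows: fractional
        # sliver coverage would add thousands of near-void constraints
        a = alpha_at(
            geom, layout, X, Y, Z, shell_thickness=h, mu=cfg.viscosity,
            antialias=False,
        )
        rigid.append(np.broadcast_to(r, shape).copy())
        alpha.append(np.where(r, 0.0, np.broadcast_to(a, shape)))
        target.append(np.zeros(shape))
        f = np.zeros(shape)
        if comp == 1 and cfg.back_pressure != 0.0:
            # adverse load: lower the inlet-side (plenum) pressure relative
            # to the chamber-core side by dP across the force layer
            y0, y1 = layout.y_force
            in_layer = (Y >= y0) & (Y < y1)
            f -= np.broadcast_to(in_layer, shape) * (
                cfg.back_pressure / (y1 - y0)
            )
        body.append(f)

    sheets = sheet_state(t, kin, geom, ds_target=0.75 * h)
    for sh in sheets:
        sh.points[:, 1] += layout.y_floor_top
    pts, vels, gids, avg = _sheet_markers(sheets, h)
    marker_J = None
    if len(pts):
        marker_J = tuple(
            (avg @ interp_matrix(shape, h, c, pts)).tocsr() for c in range(3)
        )

    m_pos = avg @ pts if len(pts) else pts
    prob = StokesProblem(
        shape=shape,
        h=h,
        nu=cfg.viscosity,
        rigid=tuple(rigid),
        target=tuple(target),
        alpha=tuple(alpha),
        body=tuple(body),
        marker_J=marker_J,
        marker_target=vels if len(pts) else None,
        marker_points=m_pos if len(pts) else None,
        marker_groups=gids if len(pts) else None,
        group_centers=geom.collar_centers(),
        compliance_factor=cfg.compliance_factor,
    )
    return prob, layout


def _sheet_markers(sheets, h: float):
    """Constraint markers for the vaned sheets.

    The vane cross-section at each arclength station is sampled finely
    (lateral spacing ~0.35 h) and the samples are aggregated into chunks of
    about one grid spacing: each chunk becomes one constraint row (the mean
    of the trilinear interpolation rows over its samples).  Sub-grid vane
    widths then enter smoothly through the sample positions while the
    constraint rows stay well separated and well conditioned.

    Returns (fine points (M,3), marker velocities (m,3), marker sheet ids
    (m,), averaging matrix (m, M)).
    """
    import scipy.sparse as sp

    fine_pts, vels, gids = [], [], []
    rows, cols, vals = [], [], []
    n_fine_total = 0
    n_markers = 0
    for gid, sh in enumerate(sheets):
        for i in range(len(sh.points)):
            w_half = sh.half_width[i]
            width = 2 * w_half
            if width <= 0:
                offs = np.array([0.0])
                n_chunk = 1
            else:
                n_samp = max(int(np.ceil(width / (0.35 * h))) + 1, 2)
                offs = np.linspace(-w_half, w_half, n_samp)
                n_chunk = max(int(np.ceil(width / h)), 1)
            chunk_id = np.minimum(
                (np.arange(len(offs)) * n_chunk) // max(len(offs), 1),
                n_chunk - 1,
            )
            pts_i = sh.points[i] + offs[:, None] * sh.vane_dir
            fine_pts.append(pts_i)
            for ch in range(n_chunk):
                sel = np.flatnonzero(chunk_id == ch)
                rows.append(np.full(len(sel), n_markers))
                cols.append(n_fine_total + sel)
                vals.append(np.full(len(sel), 1.0 / len(sel)))
                vels.append(sh.velocities[i])
                gids.append(gid)
                n_markers += 1
            n_fine_total += len(offs)
    if n_fine_total == 0:
        z = np.zeros((0, 3))
        return z, z, np.zeros(0, dtype=int), sp.csr_matrix((0, 0))
    avg = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_markers, n_fine_total),
    )
    return (
        np.concatenate(fine_pts),
        np.array(vels),
        np.array(gids, dtype=int),
        avg,
    )


def solve_phase(
    geom: ChamberGeometry,
    kin: BeatKinematics,
    cfg: SolverConfig,
    t: float,
    phase_index: int = 0,
    warm: tuple | None = None,
) -> tuple[FlowField, StokesProblem]:
    """Solve the unit-cell flow at one beat phase."""
    prob, _ = chamber_problem(geom, kin, cfg, t)
    u, v, w, p, info = solve_stokes(
        prob, rtol=cfg.rtol, maxiter=cfg.maxiter, warm=warm,
        inner_m=cfg.inner_m,
    )
    fld = FlowField(
        u=u, v=v, w=w, p=p, h=cfg.h, t=t, phase_index=phase_index,
        residual=info["residual"], iterations=info["iterations"],
        g=info.get("g"),
    )
    return fld, prob


# ---------------------------------------------------------------------------
# diagnostics / functionals


@dataclass
class PumpRates:
    """Period-averaged pumping diagnostics of the unit cell."""

    Q_ost: float        # um^3/s through the ostium mouth
    Q_col: float        # um^3/s filtered through the 24 collars
    P_flagella: float   # W (Pa um^3 / s = 1e-18 W); rate of work on the fluid
    P_dissipation: float
    residual_max: float = 0.0


def ostium_flux(fld: FlowField, masks: UnitCellMasks) -> float:
    """Instantaneous volume flux through the ostium mouth plane (um^3/s)."""
    h = fld.h
    j = masks.y_mouth_index
    nx, _, nz = fld.v.shape
    x = (np.arange(nx) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    cx, cz = masks.ostium_center
    r2 = (x[:, None] - cx) ** 2 + (z[None, :] - cz) ** 2
    hole = r2 < masks.ostium_radius**2
    return float(np.sum(fld.v[:, j, :] * hole) * h * h)


def collar_flux(fld: FlowField, masks: UnitCellMasks) -> float:
    """Instantaneous filtered flux: upward flow out of the collar interiors
    at collar-tip height, summed over collars (um^3/s)."""
    h = fld.h
    j = int(round((masks.y_floor_top + masks.collar_length) / h))
    nx, _, nz = fld.v.shape
    x = (np.arange(nx) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    total = 0.0
    for cx, cz in masks.collar_centers:
        r2 = (x[:, None] - cx) ** 2 + (z[None, :] - cz) ** 2
        inside = r2 < masks.collar_inner_radius**2
        total += float(np.sum(fld.v[:, j, :] * inside) * h * h)
    return total


def plane_flux(fld: FlowField, j: int) -> float:
    return float(np.sum(fld.v[:, j, :]) * fld.h**2)


def flagella_power(fld: FlowField, prob: StokesProblem) -> float:
    """Instantaneous rate of work of the sheets on the fluid (Pa um^3/s).

    The force density spread to the grid by a constraint multiplier g is
    -J^T g; only the part landing on free fluid faces does work (forces on
    rigid faces are absorbed by the wall).  Brinkman rows have zero target
    velocity and are excluded (their work is the porous dissipation).
    """
    if fld.g is None:
        return 0.0
    total = 0.0
    nm = prob.n_markers
    for c, vel in enumerate((fld.u, fld.v, fld.w)):
        if not prob.n_con[c] or nm == 0:
            continue
        J = prob.con_J[c][:nm]
        force = np.asarray((J.T @ fld.g[c][:nm])).reshape(prob.shape)
        total += float(np.sum(force[prob.free[c]] * vel[prob.free[c]]))
    return -total * fld.h**3


def brinkman_dissipation(fld: FlowField, prob: StokesProblem) -> float:
    """Dissipation rate inside the porous collar shells (Pa um^3/s)."""
    h3 = fld.h**3
    total = 0.0
    for a, al in zip((fld.u, fld.v, fld.w), prob.alpha):
        total += float(np.sum(al * a * a)) * h3
    return total


def dissipation(fld: FlowField, prob: StokesProblem) -> float:
    """Viscous + Brinkman dissipation rate over the whole box (Pa um^3/s)."""
    h3 = fld.h**3
    total = 0.0
    for a, al in zip((fld.u, fld.v, fld.w), prob.alpha):
        total += float(np.sum(a * (-prob.nu * _lap(a, fld.h)))) * h3
        total += float(np.sum(al * a * a)) * h3
    return total


def mirror_x(fld: FlowField) -> FlowField:
    """Field mirrored through the vertical mid-plane normal to x.

    For in-phase beating in a common x-oriented beat plane, the chamber at
    phase t + T/2 is the mirror image of the chamber at phase t, so the
    second half-period of the cycle need not be solved.
    """
    u = -np.roll(fld.u[::-1, :, :], 1, axis=0)
    v = fld.v[::-1, :, :]
    w = fld.w[::-1, :, :]
    p = fld.p[::-1, :, :]
    return replace(fld, u=u, v=v, w=w, p=p, t=fld.t + 0.0)


def _mirrorable(kin: BeatKinematics) -> bool:
    uniform_phase = kin.phase_offsets is None or len(set(kin.phase_offsets)) == 1
    plane_x = kin.beat_plane_azimuths is None or all(
        np.isclose(a % np.pi, 0.0) for a in kin.beat_plane_azimuths
    )
    return uniform_phase and plane_x


def run_period(
    geom: ChamberGeometry,
    kin: BeatKinematics,
    cfg: SolverConfig,
    progress: Callable[[str], None] | None = None,
    warm_fields: Sequence[FlowField] | None = None,
) -> tuple[list[FlowField], list[StokesProblem], UnitCellMasks]:
    """Solve all beat phases over one period.

    When the configuration has the half-period mirror symmetry (in-phase
    beating in a common beat plane), only the first half is solved and the
    second half is generated by mirroring.  ``warm_fields`` (for example
    the fields of a nearby back-pressure run) seed the Krylov iterations
    phase by phase.
    """
    from .geometry import build_unit_cell

    np_ = cfg.phases_per_period
    T = kin.period
    use_mirror = cfg.use_symmetry and _mirrorable(kin) and np_ % 2 == 0
    n_solve = np_ // 2 if use_mirror else np_

    masks = build_unit_cell(
        geom, cfg.h, mu=cfg.viscosity, flagellum_length=kin.flagellum_length
    )
    fields: list[FlowField] = []
    probs: list[StokesProblem] = []
    warm = None
    for k in range(n_solve):
        t = k * T / np_
        if warm_fields is not None and k < len(warm_fields):
            wf = warm_fields[k]
            warm = (wf.u, wf.v, wf.w, wf.p, wf.g)
        fld, prob = solve_phase(geom, kin, cfg, t, phase_index=k, warm=warm)
        warm = (
            fld.u - np.where(prob.rigid[0], prob.target[0], 0.0),
            fld.v - np.where(prob.rigid[1], prob.target[1], 0.0),
            fld.w - np.where(prob.rigid[2], prob.target[2], 0.0),
            fld.p,
            fld.g,
        )
        fields.append(fld)
        probs.append(prob)
        if progress:
            progress(
                f"phase {k + 1}/{n_solve}: {fld.iterations} iterations, "
                f"residual {fld.residual:.2e}"
            )
    if use_mirror:
        for k in range(n_solve):
            fld = mirror_x(fields[k])
            fld = replace(
                fld, t=fields[k].t + T / 2, phase_index=k + n_solve,
                mirrored=True,
            )
            fields.append(fld)
            probs.append(probs[k])
    return fields, probs, masks


def time_average(
    fields: Sequence[FlowField],
    probs: Sequence[StokesProblem],
    masks: UnitCellMasks,
) -> tuple[FlowField, PumpRates]:
    """Arithmetic phase average of fields and pumping diagnostics."""
    if len(fields) < 8:
        raise ValueError("need a full period of phase solutions (>= 8)")
    u = np.mean([f.u for f in fields], axis=0)
    v = np.mean([f.v for f in fields], axis=0)
    w = np.mean([f.w for f in fields], axis=0)
    p = np.mean([f.p for f in fields], axis=0)
    mean = FlowField(
        u=u, v=v, w=w, p=p, h=fields[0].h, t=np.nan, phase_index=-1,
        residual=max(f.residual for f in fields),
        iterations=sum(f.iterations for f in fields),
    )
    q_ost = float(np.mean([ostium_flux(f, masks) for f in fields]))
    q_col = float(np.mean([collar_flux(f, masks) for f in fields]))
    # a mirrored phase has the same scalar functionals as its source phase,
    # but its sheet masks are mirrored too, so evaluate power only on the
    # actually solved phases (their mean equals the full-period mean)
    solved = [(f, pr) for f, pr in zip(fields, probs) if not f.mirrored]
    power = float(np.mean([flagella_power(f, pr) for f, pr in solved]))
    diss = float(np.mean([dissipation(f, pr) for f, pr in solved]))
    rates = PumpRates(
        Q_ost=q_ost,
        Q_col=q_col,
        P_flagella=power,
        P_dissipation=diss,
        residual_max=max(f.residual for f in fields),
    )
    return mean, rates


def stagnation_height(
    mean: FlowField, masks: UnitCellMasks
) -> float | None:
    """Height above the chamber wall where the mean vertical flow reverses.

    Scans the vertical line through the ostium center; the first sign change
    from upward (inflow from the ostium) to downward (backflow from the
    chamber core) marks the stagnation zone acting as the hydrodynamic
    gasket.  Returns None when there is no reversal (no gasket: through-flow
    dominates all the way to the core).
    """
    h = mean.h
    cx, cz = masks.ostium_center
    nx, ny, nz = mean.v.shape
    # average the four face columns around the ostium axis
    i0 = int(np.floor(cx / h - 0.5)) % nx
    k0 = int(np.floor(cz / h - 0.5)) % nz
    cols = [
        mean.v[i, :, k]
        for i in (i0, (i0 + 1) % nx)
        for k in (k0, (k0 + 1) % nz)
    ]
    vline = np.mean(cols, axis=0)
    y = np.arange(ny) * h
    j0 = masks.y_mouth_index + 1
    j1 = int(round(masks.y_exit / h))
    for j in range(j0, j1):
        if vline[j] > 0 and vline[j + 1] < 0:
            # linear interpolation of the zero crossing
            frac = vline[j] / (vline[j] - vline[j + 1])
            return float(y[j] + frac * h - masks.y_floor_top)
    return None


def grid_convergence(
    geom: ChamberGeometry,
    kin: BeatKinematics,
    cfg: SolverConfig,
    h_values: Sequence[float],
):
    """Repeat the period-averaged run on a ladder of grids.

    Returns a list of dicts (h, Q_ost, Q_col) plus the Richardson-style
    observed order and the relative Q_ost change between the two finest
    grids.
    """
    if len(h_values) < 3:
        raise ValueError("need at least three resolutions")
    rows = []
    for h in sorted(h_values, reverse=True):
        c = replace(cfg, h=h)
        fields, probs, masks = run_period(geom, kin, c)
        _, rates = time_average(fields, probs, masks)
        rows.append({"h": h, "Q_ost": rates.Q_ost, "Q_col": rates.Q_col})
    q = [r["Q_ost"] for r in rows]
    order = np.nan
    if len(q) >= 3 and (q[-2] - q[-3]) != 0 and (q[-1] - q[-2]) != 0:
        ratio = abs((q[-2] - q[-3]) / (q[-1] - q[-2]))
        hs = [r["h"] for r in rows]
        rh = hs[-2] / hs[-1]
        if ratio > 0 and rh > 1:
            order = float(np.log(ratio) / np.log(rh))
    finest_change = abs(q[-1] - q[-2]) / abs(q[-1]) if q[-1] else np.nan
    return rows, order, finest_change
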