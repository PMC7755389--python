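"""Independent 2-D Stokes oracle: flow normal to a periodic row of cylinders.

A direct sparse finite-difference solve (MAC grid, periodic box, volume
penalization of the cylinder, uniform body force driving the flow) of the
drag per unit length on one cylinder in an infinite row.  Used to validate
the closed-form collar-wall resistance; deliberately a separate
implementation from the package's 3-D matrix-free solver.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def row_drag_coefficient(
    gap_over_d: float, cells_per_gap: int = 8, box_lengths: float = 8.0
) -> float:
    """Numerical F/(mu*U) for one cylinder in a row, flow normal to the row.

    gap_over_d: clear gap between cylinders divided by their diameter.
    The box is one spacing b wide (periodic images form the row) and
    ``box_lengths`` * b long (periodic images of the row itself are spaced
    far enough apart that their interaction is negligible).
    """
    d = 1.0
    a = d / 2.0
    b = d * (1.0 + gap_over_d)
    gap = d * gap_over_d
    h = gap / cells_per_gap
    nx = max(int(round(b / h)), 8)
    h = b / nx
    ny = int(round(box_lengths * b / h))

    n = nx * ny

    def idx(i, j):
        return (i % nx) * ny + (j % ny)

    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    nu = 1.0

    def shift(axis, s):
        ii = I + (s if axis == 0 else 0)
        jj = J + (s if axis == 1 else 0)
        return sp.csr_matrix(
            (np.ones(n), (idx(I, J).ravel(), idx(ii, jj).ravel())), shape=(n, n)
        )

    lap = (
        shift(0, 1) + shift(0, -1) + shift(1, 1) + shift(1, -1)
        - 4.0 * sp.eye(n)
    ) / h**2
    A = -nu * lap

    # discrete gradient/divergence consistent with the MAC layout
    gx = (sp.eye(n) - shift(0, -1)) / h     # p -> u faces
    gy = (sp.eye(n) - shift(1, -1)) / h     # p -> v faces
    dx = (shift(0, 1) - sp.eye(n)) / h      # u -> cells
    dy = (shift(1, 1) - sp.eye(n)) / h      # v -> cells

    # face centers
    xc, yc = b / 2.0, box_lengths * b / 2.0
    xu = I * h
    yu = (J + 0.5) * h
    xv = (I + 0.5) * h
    yv = J * h
    pad = 0.35 * h
    r2u = (xu - xc) ** 2 + (yu - yc) ** 2
    r2v = (xv - xc) ** 2 + (yv - yc) ** 2
    rig_u = (r2u.ravel() <= (a + pad) ** 2).astype(float)
    rig_v = (r2v.ravel() <= (a + pad) ** 2).astype(float)

    big = 1e8
    Au = A + sp.diags(big * rig_u)
    Av = A + sp.diags(big * rig_v)

    Z = sp.csr_matrix((n, n))
    K = sp.bmat(
        [
            [Au, Z, gx],
            [Z, Av, gy],
            [dx, dy, -1e-12 * sp.eye(n)],
        ],
        format="csc",
    )
    g = 1.0  # body force density in y
    rhs = np.concatenate([np.zeros(n), g * (1.0 - rig_v), np.zeros(n)])
    sol = spla.spsolve(K, rhs)
    v = sol[n : 2 * n]
    U = float(np.mean(v))
    drag = g * float(np.sum(1.0 - rig_v)) * h * h
    return drag / (nu * U)
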