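import numpy as np
import pytest

from syconpump.geometry import reference_geometry, build_unit_cell
from syconpump.kinematics import BeatKinematics
from syconpump import solver as sv


@pytest.fixture(scope="session")
def coarse_cfg():
    """Coarse test profile: h = 1 um, 8 phases, minutes on one CPU."""
    return sv.SolverConfig(h=1.0, phases_per_period=8, rtol=1e-6)


@pytest.fixture(scope="session")
def base_geometry():
    return reference_geometry()


@pytest.fixture(scope="session")
def base_kinematics():
    return BeatKinematics()


@pytest.fixture(scope="session")
def coarse_case(base_geometry, base_kinematics, coarse_cfg):
    """Period-resolved base-case flow at the coarse profile (shared)."""
    fields, probs, masks = sv.run_period(base_geometry, base_kinematics, coarse_cfg)
    mean, rates = sv.time_average(fields, probs, masks)
    return {
        "fields": fields,
        "probs": probs,
        "masks": masks,
        "mean": mean,
        "rates": rates,
        "cfg": coarse_cfg,
    }


@pytest.fixture(scope="session")
def case_library(base_geometry, base_kinematics, coarse_cfg, coarse_case):
    """Memoized period-averaged runs of the chamber variants (coarse grid).

    Each named case is simulated once per session no matter how many tests
    consult it; the base case reuses the shared fixture.
    """
    import dataclasses

    from syconpump.pipeline import simulate_case

    amp = base_kinematics.increased_amplitude()
    recipes = {
        "vane0.3": (base_geometry, base_kinematics.with_vane_width(0.3)),
        "vane1.4": (base_geometry, base_kinematics.with_vane_width(1.4)),
        "amp": (base_geometry, amp),
        "amp_gasket": (
            dataclasses.replace(base_geometry, gasket_present=True), amp
        ),
        "amp_wide": (
            base_geometry,
            dataclasses.replace(amp, vane_width_unconfined=1.4),
        ),
        "unconfined": (
            base_geometry,
            dataclasses.replace(base_kinematics, presence_mask="unconfined-only"),
        ),
        "confined": (
            base_geometry,
            dataclasses.replace(base_kinematics, presence_mask="confined-only"),
        ),
        "short_collar": (
            dataclasses.replace(base_geometry, collar_length=2.4),
            base_kinematics,
        ),
        "narrow_ostium": (
            dataclasses.replace(
                base_geometry, ostium_diameter=5.0, ostium_length=6.0
            ),
            base_kinematics,
        ),
    }
    cache = {
        "base": {
            "rates": coarse_case["rates"],
            "stagnation_height": sv.stagnation_height(
                coarse_case["mean"], coarse_case["masks"]
            ),
        }
    }
    last_fields = {"fields": coarse_case["fields"]}

    def get(name):
        if name not in cache:
            geom, kin = recipes[name]
            warm = last_fields["fields"]
            if warm and warm[0].p.shape[1] != int(
                round(
                    sv.vertical_layout(geom, coarse_cfg.h, kin.flagellum_length).ly
                    / coarse_cfg.h
                )
            ):
                warm = None  # different vertical extent, no warm start
            res = simulate_case(geom, kin, coarse_cfg, warm_fields=warm)
            cache[name] = {
                "rates": res["rates"],
                "stagnation_height": res["stagnation_height"],
            }
            last_fields["fields"] = res["fields"]
        return cache[name]

    return get


def poiseuille_tube_problem(D: float, h: float, G: float = 1e-3, nu: float = 1e-3):
    """Periodic tube along y driven by a uniform pressure gradient G."""
    wall = 1.0
    L = D + 2 * wall
    nx = int(round(L / h))
    shape = (nx, 8, nx)
    pad = sv.WALL_PAD_FRACTION * h
    rigid, target, alpha, body = [], [], [], []
    for comp in range(3):
        X, Y, Z = sv._face_coords(shape, h, comp)
        r2 = (X - L / 2) ** 2 + (Z - L / 2) ** 2
        r = np.broadcast_to(r2 >= (D / 2 - pad) ** 2, shape).copy()
        rigid.append(r)
        target.append(np.zeros(shape))
        alpha.append(np.zeros(shape))
        body.append(np.full(shape, G) if comp == 1 else np.zeros(shape))
    return sv.StokesProblem(
        shape=shape, h=h, nu=nu, rigid=tuple(rigid), target=tuple(target),
        alpha=tuple(alpha), body=tuple(body),
    )


def poiseuille_flux_error(D: float, h: float) -> float:
    """Relative error of the simulated tube flux vs the closed form."""
    G, nu = 1e-3, 1e-3
    prob = poiseuille_tube_problem(D, h, G, nu)
    u, v, w, p, info = sv.solve_stokes(prob, rtol=1e-8)
    Q = float(np.sum(v[:, 0, :]) * h * h)
    Q_exact = np.pi * (D / 2) ** 4 * G / (8 * nu)
    return Q / Q_exact - 1.0
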