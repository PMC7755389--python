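"""Orchestration of simulation sweeps and analysis stages.

Each entry point executes a sequence of stages from one config dict (as
returned by :func:`syconpump.config.load_config`), writes delimited tables
and field exports under an output directory, and records a manifest with
config snapshot, seeds, per-stage residuals and output hashes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import experiment as ex
from .config import dump_config
from .geometry import ChamberGeometry
from .io import RunManifest, write_table, write_vtk
from .kinematics import BeatKinematics
from .pump import (
    PumpCharacteristic,
    SystemCurve,
    characterize_pump,
    operating_point,
    poiseuille_resistance,
)
from .solver import (
    SolverConfig,
    run_period,
    stagnation_height,
    time_average,
)
from .synthetic import generate_flux, generate_inex
from .tracers import advect, encounter_efficiency, seed_particles


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _snapshot(components: dict) -> dict:
    snap = {}
    for key, val in components.items():
        snap[key] = dataclasses.asdict(val) if dataclasses.is_dataclass(val) else val
    return snap


def simulate_case(
    geom: ChamberGeometry,
    kin: BeatKinematics,
    cfg: SolverConfig,
    progress=None,
    warm_fields=None,
) -> dict:
    """One period-averaged unit-cell simulation; returns diagnostics."""
    fields, probs, masks = run_period(
        geom, kin, cfg, progress=progress, warm_fields=warm_fields
    )
    mean, rates = time_average(fields, probs, masks)
    stag = stagnation_height(mean, masks)
    return {
        "fields": fields,
        "mean": mean,
        "masks": masks,
        "rates": rates,
        "stagnation_height": stag,
    }


def run_case(components: dict, outdir, tracers: bool = False) -> RunManifest:
    """Full pipeline: geometry -> kinematics -> solve -> diagnostics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_snapshot(components))
    geom: ChamberGeometry = components["geometry"]
    kin: BeatKinematics = components["kinematics"]
    cfg: SolverConfig = components["solver"]

    try:
        result = simulate_case(geom, kin, cfg)
    except Exception as e:  # tag the failing stage, keep a partial manifest
        manifest.log_stage("solve", error=str(e))
        manifest.write(outdir / "manifest.json")
        raise StageError("solve", e) from e
    rates = result["rates"]
    manifest.log_stage(
        "solve",
        residual_max=rates.residual_max,
        iterations=result["mean"].iterations,
    )

    rows = pd.DataFrame(
        [
            {
                "Q_ost_um3_s": rates.Q_ost,
                "Q_col_um3_s": rates.Q_col,
                "P_flagella_pW": rates.P_flagella * 1e-6,
                "P_dissipation_pW": rates.P_dissipation * 1e-6,
                "stagnation_height_um": result["stagnation_height"],
                "collar_length_um": geom.collar_length,
            }
        ]
    )
    write_table(rows, outdir / "pump_rates.tsv")
    manifest.register_output(outdir / "pump_rates.tsv")
    masks = result["masks"]
    write_vtk(
        outdir / "mean_field.vtk",
        result["mean"],
        scalars={
            "solid": masks.solid.astype(float),
            "collar_alpha": masks.alpha,
        },
    )
    manifest.register_output(outdir / "mean_field.vtk")

    if tracers:
        topts = components.get("tracers", {})
        seed = int(topts.get("seed", 0))
        n = int(topts.get("n_particles", 2000))
        ens = seed_particles(result["masks"], result["fields"][0], n, seed)
        advect(ens, result["fields"], result["masks"], kin.period)
        eff, counts = encounter_efficiency(ens)
        manifest.seeds["tracers"] = seed
        manifest.log_stage("tracers", efficiency=eff, **counts)
        write_table(
            pd.DataFrame([{"efficiency": eff, **counts}]),
            outdir / "tracer_fates.tsv",
        )
        manifest.register_output(outdir / "tracer_fates.tsv")

    dump_config(components, outdir / "config.yaml")
    manifest.register_output(outdir / "config.yaml")
    manifest.write(outdir / "manifest.json")
    return manifest


def vane_width_sweep(
    components: dict, widths, piecewise_unconfined: float | None = None
) -> pd.DataFrame:
    """Pumping/filtration rates vs vane width."""
    rows = []
    for wconf in widths:
        kin = components["kinematics"].with_vane_width(
            wconf, piecewise_unconfined
        )
        res = simulate_case(components["geometry"], kin, components["solver"])
        rows.append(
            {
                "vane_width_um": wconf,
                "Q_ost_um3_s": res["rates"].Q_ost,
                "Q_col_um3_s": res["rates"].Q_col,
            }
        )
    return pd.DataFrame(rows)


def collar_length_sweep(
    components: dict, lengths, gasket: bool = False
) -> pd.DataFrame:
    """Pumping rate vs collar length, with or without the physical gasket."""
    rows = []
    for lcol in lengths:
        geom = replace(
            components["geometry"], collar_length=lcol, gasket_present=gasket,
            gasket_height=None,
        )
        res = simulate_case(geom, components["kinematics"], components["solver"])
        rows.append(
            {
                "collar_length_um": lcol,
                "gasket": gasket,
                "Q_ost_um3_s": res["rates"].Q_ost,
                "Q_col_um3_s": res["rates"].Q_col,
            }
        )
    return pd.DataFrame(rows)


def characterize_unit(
    components: dict,
    back_pressures=None,
    p_estimate: float = 0.06,
) -> dict:
    """Pump characteristic of the basic pumping unit.

    The unit is the zero-length-ostium cell; the real ostium tube is
    accounted for separately as the Poiseuille system resistance.  Runs the
    period-averaged simulation at three adverse loads (0, P_est/2, P_est)
    and fits the linear characteristic.
    """
    geom = replace(components["geometry"], ostium_length=0.0)
    cfg: SolverConfig = components["solver"]
    if back_pressures is None:
        back_pressures = (0.0, p_estimate / 2.0, p_estimate)
    samples = []
    warm = None
    for dp in back_pressures:
        res = simulate_case(
            geom, components["kinematics"], replace(cfg, back_pressure=dp),
            warm_fields=warm,
        )
        warm = res["fields"]
        samples.append((dp, res["rates"].Q_ost))
    pump = characterize_pump(samples)
    ref = components["geometry"]
    r_ost = poiseuille_resistance(
        ref.ostium_diameter, ref.ostium_length, cfg.viscosity
    )
    op = operating_point(pump, SystemCurve(r_ost))
    return {
        "samples": samples,
        "pump": pump,
        "R_ost": r_ost,
        "operating_point": op,
        "Q_predicted": op.Q_hat * pump.Q_max,
    }


def run_experiment_analysis(
    components: dict,
    outdir,
    inex: pd.DataFrame | None = None,
    flux: pd.DataFrame | None = None,
    simulated_q_ost: float | None = None,
) -> RunManifest:
    """Retention-efficiency and flux statistics from In-Ex and dye tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_snapshot(components))
    gen = components["synthetic"]
    manifest.seeds["synthetic"] = gen.seed

    if inex is None and flux is None:
        inex = generate_inex(gen)
        flux = generate_flux(gen)
        manifest.log_stage("generate_synthetic", n_sponges=gen.n_sponges)

    if inex is not None:
        try:
            rets = ex.pair_retention(inex)
            summary = ex.retention_summary(rets)
        except Exception as e:
            manifest.log_stage("retention", error=str(e))
            manifest.write(outdir / "manifest.json")
            raise StageError("retention", e) from e
        write_table(rets, outdir / "pair_retention.tsv")
        manifest.register_output(outdir / "pair_retention.tsv")
        sf = summary.as_frame().reset_index(names="prey_class")
        sf["outliers"] = sf["outliers"].astype(str)
        write_table(sf, outdir / "retention_summary.tsv")
        manifest.register_output(outdir / "retention_summary.tsv")
        manifest.log_stage(
            "retention",
            **{c: summary.per_class[c].mean for c in summary.per_class},
        )
    else:
        manifest.log_stage("retention", skipped="no In-Ex table provided")

    if flux is not None:
        rows = []
        for sponge, grp in flux.groupby("sponge"):
            f = ex.excurrent_flow(grp)
            rates = ex.per_unit_rates(f.flow_um3_s, gen.n_ostia)
            rows.append(
                {
                    "sponge": sponge,
                    "jet_speed_mm_s": f.jet_speed_mm_s,
                    "flow_mm3_s": f.flow_mm3_s,
                    "Q_ost_um3_s": rates.Q_ost,
                    "Q_ch_um3_s": rates.Q_ch,
                    "in_leucon_range": rates.in_leucon_range,
                }
            )
        flux_df = pd.DataFrame(rows)
        if simulated_q_ost is not None:
            flux_df["Q_ost_simulated_um3_s"] = simulated_q_ost
            flux_df["ratio_measured_to_simulated"] = (
                flux_df["Q_ost_um3_s"] / simulated_q_ost
            )
        write_table(flux_df, outdir / "flux_results.tsv")
        manifest.register_output(outdir / "flux_results.tsv")
        manifest.log_stage("flux", mean_Q_ost=float(flux_df["Q_ost_um3_s"].mean()))
    else:
        manifest.log_stage("flux", skipped="no flux table provided")

    manifest.write(outdir / "manifest.json")
    return manifest
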