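"""Field/table export and run manifests (plain-text formats only)."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import FlowField


def cell_centered_velocity(fld: FlowField) -> np.ndarray:
    """Average the staggered components to cell centers; (nx,ny,nz,3)."""
    u = 0.5 * (fld.u + np.roll(fld.u, -1, 0))
    v = 0.5 * (fld.v + np.roll(fld.v, -1, 1))
    w = 0.5 * (fld.w + np.roll(fld.w, -1, 2))
    return np.stack([u, v, w], axis=-1)


def write_vtk(path, fld: FlowField, scalars: dict | None = None) -> None:
    """Legacy-VTK ASCII structured-points snapshot of a flow field.

    Writes the cell-centered velocity vector plus pressure and any extra
    scalar fields; readable by ParaView/VisIt and by meshio.
    """
    path = Path(path)
    nx, ny, nz = fld.p.shape
    h = fld.h
    vel = cell_centered_velocity(fld)
    lines = [
        "# vtk DataFile Version 3.0",
        "syconpump flow field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {h / 2} {h / 2} {h / 2}",
        f"SPACING {h} {h} {h}",
        f"POINT_DATA {nx * ny * nz}",
        "VECTORS velocity float",
    ]
    # VTK expects x fastest; our arrays are (x, y, z) C-ordered (z fastest)
    vv = np.transpose(vel, (2, 1, 0, 3)).reshape(-1, 3)
    lines += [" ".join(f"{c:.6g}" for c in row) for row in vv]
    fields = {"pressure": fld.p}
    if scalars:
        fields.update(scalars)
    for name, arr in fields.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.transpose(np.asarray(arr, dtype=float), (2, 1, 0)).ravel()
        lines += [f"{v:.6g}" for v in flat]
    path.write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seeds: dict = dc_field(default_factory=dict)
    stages: list = dc_field(default_factory=list)
    outputs: dict = dc_field(default_factory=dict)   # path -> sha256
    started: float = dc_field(default_factory=time.time)
    wall_time_s: float = 0.0

    def log_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def register_output(self, path) -> None:
        p = Path(path)
        self.outputs[str(p)] = _sha256(p)

    def write(self, path) -> None:
        self.wall_time_s = time.time() - self.started
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "config": self.config,
            "seeds": self.seeds,
            "stages": self.stages,
            "outputs": self.outputs,
            "wall_time_s": round(self.wall_time_s, 3),
        }
        p.write_text(json.dumps(payload, indent=2, default=str) + "\n")
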