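"""File I/O: legacy-VTK structured output, CSV traces, YAML configs."""

from __future__ import annotations

import os
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import yaml

from .stokes import FlowField

__all__ = [
    "write_vtk_field",
    "read_vtk_dimensions",
    "write_traces_csv",
    "read_traces_csv",
    "load_config_yaml",
    "dump_config_yaml",
]


def write_vtk_field(flow: FlowField, path: str) -> None:
    """Write a snapshot as legacy ASCII VTK STRUCTURED_POINTS.

    Cell-centered data on the (r, z) plane: velocity as a 3-vector
    (u_r, u_z, 0) and pressure as a scalar.  The third dimension is 1.
    """
    g = flow.grid
    ur, uz = flow.center_velocity()
    n = g.nr * g.nz
    lines = [
        "# vtk DataFile Version 3.0",
        f"polypflow flow field t={flow.time:.6f}s (r,z axisymmetric plane)",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {g.nr} {g.nz} 1",
        f"ORIGIN {0.5 * g.dr:.9g} {0.5 * g.dz:.9g} 0",
        f"SPACING {g.dr:.9g} {g.dz:.9g} 1",
        f"POINT_DATA {n}",
        "VECTORS velocity double",
    ]
    # VTK varies x (here r) fastest
    for j in range(g.nz):
        for i in range(g.nr):
            lines.append(f"{ur[i, j]:.9e} {uz[i, j]:.9e} 0")
    lines.append("SCALARS pressure double 1")
    lines.append("LOOKUP_TABLE default")
    for j in range(g.nz):
        for i in range(g.nr):
            lines.append(f"{flow.p[i, j]:.9e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk_dimensions(path: str) -> Tuple[int, int, int]:
    """Grid dimensions recorded in a legacy VTK structured file."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("DIMENSIONS"):
                _, a, b, c = line.split()
                return int(a), int(b), int(c)
    raise ValueError(f"no DIMENSIONS record in {path}")


def write_traces_csv(times, z_points, speeds, path: str) -> None:
    """Cut-point speed traces: column t_s, then one column per z (mm)."""
    data = {"t_s": np.asarray(times, dtype=float)}
    for k, z in enumerate(z_points):
        data[f"{z:.2f}"] = np.asarray(speeds[k], dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10e")


def read_traces_csv(path: str):
    df = pd.read_csv(path)
    times = df["t_s"].to_numpy()
    z_points = np.array([float(c) for c in df.columns if c != "t_s"])
    speeds = df.drop(columns="t_s").to_numpy().T
    return times, z_points, speeds


def load_config_yaml(path: str) -> Dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config_yaml(data: Dict, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
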