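"""Matplotlib renderings of traces, velocity fields and vorticity snapshots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import SimulationResult  # noqa: E402
from .postprocess import VorticityField  # noqa: E402
from .stokes import FlowField  # noqa: E402

__all__ = ["plot_traces", "plot_field", "plot_vorticity"]


def plot_traces(result: SimulationResult, path: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, z in enumerate(result.z_points):
        ax.plot(result.times, result.speeds[k], lw=1, label=f"z={z:.2f} mm")
    ax.axvline(result.T_exp, color="k", ls=":", lw=0.8)
    ax.set_xlabel("t (s)")
    ax.set_ylabel("speed (mm/s)")
    ax.set_title(f"cut-point speeds, scenario {result.label}")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_field(flow: FlowField, path: str, stride: int = 4) -> None:
    """Arrow plot; arrow length scales with log of the speed magnitude."""
    g = flow.grid
    ur, uz = flow.center_velocity()
    sp = np.hypot(ur, uz)
    floor = sp.max() / 1000.0 if sp.max() > 0 else 1.0
    scale = np.where(sp > floor, np.log(sp / floor), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = np.where(sp > 0, scale / sp, 0.0)
    fig, ax = plt.subplots(figsize=(4, 7))
    R, Z = np.meshgrid(g.r_centers, g.z_centers, indexing="ij")
    s = slice(None, None, stride)
    ax.quiver(R[s, s], Z[s, s], (ur * fr)[s, s], (uz * fr)[s, s], sp[s, s],
              cmap="viridis", scale=60)
    ax.set_xlabel("r (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_aspect("equal")
    ax.set_title(f"t = {flow.time:.2f} s")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_vorticity(vf: VorticityField, path: str, clim: float = 1e-3) -> None:
    g = vf.grid
    fig, ax = plt.subplots(figsize=(4, 7))
    im = ax.pcolormesh(
        g.r_centers, g.z_centers, vf.omega_star.T,
        cmap="RdBu_r", vmin=-clim, vmax=clim, shading="nearest",
    )
    fig.colorbar(im, ax=ax, label=r"$\omega^{*}$")
    ax.set_xlabel("r (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_aspect("equal")
    ax.set_title(f"t = {vf.time:.2f} s")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
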