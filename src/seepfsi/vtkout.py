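"""Legacy-ASCII VTK structured-grid snapshots of the axisymmetric fields.

Writes the (z, r) plane as a VTK structured grid with cell data (u_z, u_r
interpolated to centres, p, viscosity, zone) for inspection in ParaView.
A deliberately small hand-rolled writer: the legacy ASCII format is a few
header lines plus whitespace-separated tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .constitutive import RheologyParams
from .fluid import FluidState, SolverConfig, _viscosity_fields
from .geometry import Mesh

__all__ = ["write_vtk_snapshot"]


def write_vtk_snapshot(
    path,
    state: FluidState,
    mesh: Mesh,
    rheology: RheologyParams | None = None,
    config: SolverConfig | None = None,
):
    """Write one snapshot; returns the path written."""
    rheology = rheology or RheologyParams()
    config = config or SolverConfig()
    z, r = mesh.node_coordinates()
    nzp, nrp = z.shape
    u_c = 0.5 * (state.u[:-1, :] + state.u[1:, :])
    v_c = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    eta_cell, _, _ = _viscosity_fields(state.u, state.v, mesh, rheology, config)

    lines = [
        "# vtk DataFile Version 3.0",
        f"seepfsi snapshot t={state.time:.6g} s",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nrp} {nzp} 1",
        f"POINTS {nrp * nzp} double",
    ]
    pts = np.column_stack(
        [r.ravel(), z.ravel(), np.zeros(z.size)]
    )  # x = r, y = z for a natural 2D view
    lines += [" ".join(f"{c:.9g}" for c in row) for row in pts]

    ncell = mesh.nz * mesh.nr
    lines.append(f"CELL_DATA {ncell}")

    def scalar(name, arr):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{val:.9g}" for val in np.asarray(arr).ravel())

    scalar("axial_velocity", u_c)
    scalar("radial_velocity", v_c)
    scalar("pressure", state.p)
    scalar("viscosity", eta_cell)
    scalar("zone", np.repeat(mesh.zone[:, None], mesh.nr, axis=1).astype(float))

    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
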