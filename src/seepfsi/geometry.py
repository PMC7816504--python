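"""Axisymmetric two-zone computational domain and ALE mesh motion.

The domain is a straight tube of reference radius R in (r, z): an elastic
"artery" zone of length ``artery_length`` followed by a rigid porous
"microcirculation" zone of length ``micro_length``.  The grid is structured:
``nz`` axial cells of uniform width and ``nr`` radial cells per column,
boundary-fitted by pure radial scaling — column i spans r in
[0, R + d(z_i)] where d is the wall displacement (zero over the porous
zone).  Probe sections S1/S2 (artery) and S3/S4 (porous) are axial stations
snapped to the grid.

Coordinate convention: z grows from the inlet (z=0) to the porous outlet,
r=0 is the symmetry axis; SI units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DivergenceError

__all__ = ["GeometryConfig", "Mesh", "build_mesh", "deform_mesh"]


@dataclass(frozen=True)
class GeometryConfig:
    radius: float = 0.010  # m (R = D/2, D = 20 mm)
    wall_thickness: float = 0.002  # m
    artery_length: float = 0.200  # m (10 D)
    micro_length: float = 0.100  # m (5 D)
    # S1, S2 as fractions of artery_length from the inlet;
    # S3, S4 as fractions of micro_length past the zone interface.
    section_fractions: tuple = (0.25, 0.75, 0.25, 0.75)

    def __post_init__(self):
        for name in ("radius", "wall_thickness", "artery_length", "micro_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        f1, f2, f3, f4 = self.section_fractions
        if not (0 < f1 < f2 < 1 and 0 < f3 < f4 < 1):
            raise ValueError("section fractions must satisfy S1<S2 and S3<S4 within their zones")

    @property
    def total_length(self) -> float:
        return self.artery_length + self.micro_length

    @property
    def section_positions(self) -> np.ndarray:
        """Axial positions of S1..S4 (m from the inlet)."""
        f1, f2, f3, f4 = self.section_fractions
        la = self.artery_length
        return np.array([f1 * la, f2 * la, la + f3 * self.micro_length, la + f4 * self.micro_length])


@dataclass
class Mesh:
    """Structured axisymmetric grid with radial-scaling wall motion.

    The grid is stored in mapped form: axial faces ``z_faces`` (nz+1,), the
    per-column wall radius ``wall_radius`` (nz,) and the reference radius R.
    Radial cell faces of column i sit at j/nr * wall_radius[i], j=0..nr.
    """

    geometry: GeometryConfig
    nz: int
    nr: int
    z_faces: np.ndarray  # (nz+1,)
    wall_radius: np.ndarray  # (nz,) current wall radius per cell column
    wall_radius_faces: np.ndarray  # (nz+1,) interpolated to axial faces
    zone: np.ndarray  # (nz,) 0 = artery, 1 = microcirculation
    interface_face: int  # axial face index of the artery/micro interface
    probe_cells: np.ndarray  # (4,) cell-column index of S1..S4
    probe_faces: np.ndarray  # (4,) axial-face index of S1..S4

    ZONE_ARTERY = 0
    ZONE_MICRO = 1

    # -- derived geometry -------------------------------------------------
    @property
    def dz(self) -> float:
        return float(self.z_faces[1] - self.z_faces[0])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    @property
    def dr_cell(self) -> np.ndarray:
        """(nz,) radial cell size per column."""
        return self.wall_radius / self.nr

    @property
    def dr_face(self) -> np.ndarray:
        """(nz+1,) radial cell size per axial-face column."""
        return self.wall_radius_faces / self.nr

    @property
    def r_centers(self) -> np.ndarray:
        """(nz, nr) physical radius of cell centres."""
        xi = (np.arange(self.nr) + 0.5) / self.nr
        return self.wall_radius[:, None] * xi[None, :]

    @property
    def r_rfaces(self) -> np.ndarray:
        """(nz, nr+1) physical radius of radial faces per column."""
        xi = np.arange(self.nr + 1) / self.nr
        return self.wall_radius[:, None] * xi[None, :]

    @property
    def r_ufaces(self) -> np.ndarray:
        """(nz+1, nr) physical radius of axial-velocity points."""
        xi = (np.arange(self.nr) + 0.5) / self.nr
        return self.wall_radius_faces[:, None] * xi[None, :]

    @property
    def artery_cells(self) -> np.ndarray:
        return np.nonzero(self.zone == self.ZONE_ARTERY)[0]

    @property
    def n_artery(self) -> int:
        return int(np.count_nonzero(self.zone == self.ZONE_ARTERY))

    def cell_volumes(self) -> np.ndarray:
        """(nz, nr) cell volumes per radian (r dr dz)."""
        rc = self.r_centers
        dr = self.dr_cell[:, None]
        return rc * dr * self.dz

    def volume(self, area_expansion: float = 1.0) -> float:
        """Total fluid volume (m^3), porous-zone cross-section scaled by
        ``area_expansion``."""
        v = 2.0 * np.pi * self.cell_volumes()
        scale = np.where(self.zone == self.ZONE_MICRO, area_expansion, 1.0)
        return float(np.sum(v * scale[:, None]))

    def node_coordinates(self):
        """(nz+1, nr+1) arrays of z and r node positions (for VTK export)."""
        xi = np.arange(self.nr + 1) / self.nr
        rw = np.empty(self.nz + 1)
        rw[:] = self.wall_radius_faces
        z = np.repeat(self.z_faces[:, None], self.nr + 1, axis=1)
        r = rw[:, None] * xi[None, :]
        return z, r


def _face_radius(wall_radius: np.ndarray) -> np.ndarray:
    rw_f = np.empty(len(wall_radius) + 1)
    rw_f[1:-1] = 0.5 * (wall_radius[:-1] + wall_radius[1:])
    rw_f[0] = wall_radius[0]
    rw_f[-1] = wall_radius[-1]
    return rw_f


def build_mesh(geometry: GeometryConfig, nz: int, nr: int) -> Mesh:
    """Build the undeformed two-zone grid.

    ``nz`` is the total axial cell count over both zones (>= 20), split
    between the zones in proportion to their lengths with the interface
    snapped to an axial face; ``nr`` >= 8 radial cells.
    """
    if nz < 20:
        raise ValueError(f"nz={nz} below the minimum of 20 axial cells")
    if nr < 8:
        raise ValueError(f"nr={nr} below the minimum of 8 radial cells")
    L = geometry.total_length
    z_faces = np.linspace(0.0, L, nz + 1)
    dz = L / nz
    i_if = int(round(geometry.artery_length / dz))
    i_if = min(max(i_if, 1), nz - 1)
    zone = np.where(np.arange(nz) < i_if, Mesh.ZONE_ARTERY, Mesh.ZONE_MICRO)
    wall_radius = np.full(nz, geometry.radius)
    z_centers = 0.5 * (z_faces[:-1] + z_faces[1:])
    sect = geometry.section_positions
    probe_cells = np.array([int(np.argmin(np.abs(z_centers - s))) for s in sect])
    probe_faces = np.array([int(np.argmin(np.abs(z_faces - s))) for s in sect])
    # keep S1/S2 in the artery zone and S3/S4 in the porous zone after snapping
    probe_cells[0] = min(probe_cells[0], i_if - 1)
    probe_cells[1] = min(probe_cells[1], i_if - 1)
    probe_cells[2] = max(probe_cells[2], i_if)
    probe_cells[3] = max(probe_cells[3], i_if)
    probe_faces[:2] = np.clip(probe_faces[:2], 1, i_if - 1)
    probe_faces[2:] = np.clip(probe_faces[2:], i_if + 1, nz - 1)
    return Mesh(
        geometry=geometry,
        nz=nz,
        nr=nr,
        z_faces=z_faces,
        wall_radius=wall_radius,
        wall_radius_faces=_face_radius(wall_radius),
        zone=zone,
        interface_face=i_if,
        probe_cells=probe_cells,
        probe_faces=probe_faces,
    )


def deform_mesh(
    mesh: Mesh,
    wall_displacement: np.ndarray,
    dt: float,
    previous_displacement: np.ndarray | None = None,
):
    """Return (deformed mesh, wall radial velocity per column).

    ``wall_displacement`` is the radial wall displacement at the artery-zone
    cell columns (length ``mesh.n_artery``); the porous zone is rigid.  The
    grid deforms by algebraic radial scaling, r_new = r_ref (R + d(z)) / R.
    The returned wall velocity is the backward difference
    (d - d_prev)/dt per column (zero over the porous zone); node mesh
    velocities follow from it by the same radial scaling.
    """
    d = np.asarray(wall_displacement, dtype=float)
    n_art = mesh.n_artery
    if d.shape != (n_art,):
        raise ValueError(f"wall_displacement must have shape ({n_art},)")
    R = mesh.geometry.radius
    if np.any(np.abs(d) >= 0.5 * R):
        raise DivergenceError(
            "wall displacement exceeds half the reference radius — FSI instability"
        )
    d_full = np.zeros(mesh.nz)
    d_full[mesh.artery_cells] = d
    wall_radius = R + d_full
    if previous_displacement is None:
        d_prev = np.zeros(n_art)
    else:
        d_prev = np.asarray(previous_displacement, dtype=float)
    wall_vel = np.zeros(mesh.nz)
    wall_vel[mesh.artery_cells] = (d - d_prev) / dt
    new = replace(
        mesh,
        wall_radius=wall_radius,
        wall_radius_faces=_face_radius(wall_radius),
    )
    return new, wall_vel
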