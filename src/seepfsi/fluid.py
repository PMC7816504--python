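"""Incompressible ALE Navier–Stokes on the moving axisymmetric grid.

Artery zone (moving mesh, convection by u - u_m):

    rho (du/dt + ((u - u_m).grad) u) = -grad p + div T,   div u = 0,
    T = 2 eta(gd) D,  D = (grad u + grad u^T)/2,

with the Carreau–Yasuda viscosity eta(gd).  Microcirculation zone (fixed
mesh): the volume-averaged porous equations with constant porosity phi,
written here per intrinsic velocity (the phi-divided form),

    rho (du/dt + (u.grad) u) = -grad p + div T - (phi eta / k) u,
    div (beta u) = 0,

where beta = phi * area_expansion is the superficial flux-area fraction of
the zone (1 in the artery).  The two zones share one discretisation: zone
differences enter only through the cell arrays beta(z) and the Brinkman
sink s(z).  Interface continuity of superficial mass flux and of pressure
is then automatic — the projection enforces div(beta u) = 0 in every cell
and the sink coefficient at the interface face (arithmetic mean of the two
sides) keeps the axial pressure gradient continuous.

Discretisation: MAC staggered grid in mapped coordinates (z, xi = r/R_w)
and BDF2 in time.  The step is linearly implicit: convection coefficients,
viscosity, the Brinkman sink and the van-Leer MUSCL deferred correction
("high_resolution" advection) are evaluated once per step at the
extrapolated (or FSI warm-start) state; first-order upwind convection and
the own-component viscous terms are implicit; the transposed-gradient
viscous terms are explicit at the same frozen state.  Inner iterations
then solve momentum + incremental pressure correction until the relative
field change drops below ``residual_tol``; because every matrix is frozen
within the step, the iteration is a plain linear fixed point and converges
monotonically.  All linear systems are direct banded LU solves.

The pressure-correction mobility includes the sink diagonal
(1 / (rho c0/dt + s), SIMPLE-style) so pressure converges as fast in the
highly-resistive porous zone as in the open lumen; the corrected field is
exactly divergence-free regardless of the mobility.

Mapped-coordinate metric terms proportional to dR_w/dz are neglected: wall
slopes are O(d/L) ~ 1e-4 for physiological compliance, far below the
truncation error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lapack

from .constitutive import (
    PorousParams,
    RheologyParams,
    carreau_yasuda_viscosity,
    shear_rate_magnitude,
)
from .errors import ConvergenceError, DivergenceError
from .geometry import Mesh

__all__ = [
    "FluidState",
    "SolverConfig",
    "advance_fluid",
    "wall_traction",
    "wall_shear_stress",
    "zone_interface_fluxes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    dt: float = 4e-3  # s
    residual_tol: float = 1e-4
    max_inner_iterations: int = 40
    advection: str = "high_resolution"  # or "upwind"
    newtonian_override: float | None = None  # Pa.s, fixed viscosity if set
    inlet_profile: str = "plug"  # or "parabolic"
    porous_viscosity: str = "local"  # or "eta_inf": viscosity in the Brinkman sink

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.residual_tol <= 0:
            raise ValueError("residual_tol must be positive")
        if self.advection not in ("upwind", "high_resolution"):
            raise ValueError("advection must be 'upwind' or 'high_resolution'")
        if self.inlet_profile not in ("plug", "parabolic"):
            raise ValueError("inlet_profile must be 'plug' or 'parabolic'")
        if self.porous_viscosity not in ("local", "eta_inf"):
            raise ValueError("porous_viscosity must be 'local' or 'eta_inf'")
        if self.newtonian_override is not None and self.newtonian_override <= 0:
            raise ValueError("newtonian_override must be positive")


@dataclass
class FluidState:
    """Velocity/pressure fields on the staggered grid.

    ``u`` (nz+1, nr): axial velocity at axial faces x radial centres
    (row 0 is the inlet boundary); ``v`` (nz, nr+1): radial velocity at
    cell columns x radial faces (column 0 the axis, column nr the wall);
    ``p`` (nz, nr) at cell centres.  ``u_prev``/``v_prev`` hold the
    previous time level for BDF2.
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    time: float = 0.0
    u_prev: np.ndarray | None = None
    v_prev: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, mesh: Mesh, time: float = 0.0) -> "FluidState":
        return cls(
            u=np.zeros((mesh.nz + 1, mesh.nr)),
            v=np.zeros((mesh.nz, mesh.nr + 1)),
            p=np.zeros((mesh.nz, mesh.nr)),
            time=time,
        )

    def copy(self) -> "FluidState":
        return FluidState(
            self.u.copy(),
            self.v.copy(),
            self.p.copy(),
            self.time,
            None if self.u_prev is None else self.u_prev.copy(),
            None if self.v_prev is None else self.v_prev.copy(),
            dict(self.diagnostics),
        )


# ---------------------------------------------------------------------------
# banded linear algebra


class _Banded5:
    """LU-factored 5-point operator on an (NI, NJ) grid, j fastest.

    aN/aS couple j+-1, aE/aW couple i+-1; boundary couplings must already
    be zeroed by the assembly.  The unknowns are ordered with the smaller
    dimension fastest so the LU bandwidth is min(NI, NJ); the factorisation
    is reused across the inner pressure-velocity iterations of a step.
    """

    def __init__(self, aP, aN, aS, aE, aW):
        NI, NJ = aP.shape
        self.transposed = NJ > NI
        if self.transposed:
            aP, aN, aS, aE, aW = aP.T, aE.T, aW.T, aN.T, aS.T
            NI, NJ = NJ, aP.shape[1]
        self.shape = (NI, NJ)
        n = NI * NJ
        kl = ku = NJ
        ab = np.zeros((2 * kl + ku + 1, n))
        row0 = kl + ku  # main diagonal row in LAPACK banded storage
        ab[row0, :] = aP.ravel()
        an = aN.ravel()
        ab[row0 - 1, 1:] = an[:-1]
        a_s = aS.ravel()
        ab[row0 + 1, :-1] = a_s[1:]
        ae = aE.ravel()
        ab[row0 - NJ, NJ:] = ae[:-NJ]
        aw = aW.ravel()
        ab[row0 + NJ, :-NJ] = aw[NJ:]
        self.lu, self.ipiv, info = lapack.dgbtrf(ab, kl, ku)
        if info != 0:
            raise np.linalg.LinAlgError(f"banded LU factorisation failed (info={info})")
        self.kl, self.ku = kl, ku

    def solve(self, rhs):
        if self.transposed:
            rhs = rhs.T
        b = np.ascontiguousarray(rhs.reshape(-1))
        x, info = lapack.dgbtrs(self.lu, self.kl, self.ku, b, self.ipiv)
        if info != 0:
            raise np.linalg.LinAlgError(f"banded solve failed (info={info})")
        out = x.reshape(self.shape)
        return out.T if self.transposed else out


def _solve_5band(aP, aN, aS, aE, aW, rhs):
    """One-shot 5-point solve (see _Banded5)."""
    return _Banded5(aP, aN, aS, aE, aW).solve(rhs)


def _vanleer(r):
    return (r + np.abs(r)) / (1.0 + np.abs(r))


def _muscl_correction(q, w, h, axis):
    """(HR - first-order-upwind) advective derivative, for deferred correction.

    ``q`` values along ``axis`` with any Dirichlet boundary rows included;
    the correction is zero wherever the full MUSCL stencil leaves the array.
    Returns an array shaped like q.
    """
    if np.ndim(h) > 0:
        h = np.moveaxis(np.broadcast_to(h, q.shape), axis, 0)
    q = np.moveaxis(q, axis, 0)
    w = np.moveaxis(w, axis, 0)
    n = q.shape[0]
    corr = np.zeros_like(q)
    if n < 4:
        return np.moveaxis(corr, 0, axis)
    d = np.diff(q, axis=0)  # d[i] = q[i+1] - q[i], length n-1
    eps = 1e-300

    def ratio(num, den):
        safe = np.where(np.abs(den) > eps, den, 1.0)
        return np.where(np.abs(den) > eps, num / safe, 0.0)

    h_mid = h[2 : n - 1] if np.ndim(h) > 0 else h
    h_lo = h[1 : n - 2] if np.ndim(h) > 0 else h
    # w > 0 at node i (2 <= i <= n-2): faces (i-1/2), (i+1/2) reconstructed
    # from the upwind side.
    i = np.arange(2, n - 1)
    r_up = ratio(d[i - 1], d[i])  # for face i+1/2, upwind cell i
    r_dn = ratio(d[i - 2], d[i - 1])  # for face i-1/2, upwind cell i-1
    corr_pos = 0.5 * (_vanleer(r_up) * d[i] - _vanleer(r_dn) * d[i - 1]) / h_mid
    # w < 0 at node i (1 <= i <= n-3): upwind side is the downwind index.
    iN = np.arange(1, n - 2)
    rn_up = ratio(d[iN + 1], d[iN])  # face i+1/2, upwind cell i+1
    rn_dn = ratio(d[iN], d[iN - 1])  # face i-1/2, upwind cell i
    corr_neg = 0.5 * (_vanleer(rn_up) * d[iN] - _vanleer(rn_dn) * d[iN - 1]) / h_lo

    corr[2 : n - 1] = np.where(w[2 : n - 1] > 0, corr_pos, 0.0)
    corr[1 : n - 2] += np.where(w[1 : n - 2] < 0, corr_neg, 0.0)
    return np.moveaxis(corr, 0, axis)


# ---------------------------------------------------------------------------
# field helpers


def _zone_arrays(mesh: Mesh, porous: PorousParams):
    """Per-column flux-area fraction beta and a porous mask."""
    is_micro = mesh.zone == Mesh.ZONE_MICRO
    beta = np.where(is_micro, porous.flux_area_fraction, 1.0)
    return beta, is_micro


def _viscosity_fields(u, v, mesh: Mesh, rheology: RheologyParams, config: SolverConfig):
    """(eta_cell (nz,nr), eta_corner (nz+1,nr+1), gd_cell) from the fields."""
    nz, nr = mesh.nz, mesh.nr
    dz = mesh.dz
    dr_c = mesh.dr_cell[:, None]
    dr_f = mesh.dr_face[:, None]

    dudz = (u[1:, :] - u[:-1, :]) / dz  # (nz, nr) at cells
    dvdr = (v[:, 1:] - v[:, :-1]) / dr_c
    v_c = 0.5 * (v[:, 1:] + v[:, :-1])
    v_over_r = v_c / mesh.r_centers

    # du/dr at corners (nz+1, nr+1)
    dudr_cor = np.zeros((nz + 1, nr + 1))
    dudr_cor[:, 1:nr] = (u[:, 1:] - u[:, :-1]) / dr_f
    dudr_cor[:, nr] = (u[:, nr - 2] - 9.0 * u[:, nr - 1]) / (3.0 * dr_f[:, 0])
    # axis: symmetry, du/dr = 0
    # dv/dz at corners
    dvdz_cor = np.zeros((nz + 1, nr + 1))
    dvdz_cor[1:nz, :] = (v[1:, :] - v[:-1, :]) / dz
    dvdz_cor[0, :] = (v[0, :] - 0.0) / (0.5 * dz)  # inlet plane: v = 0
    # outlet: dv/dz = 0

    def cor2cell(a):
        return 0.25 * (a[:-1, :-1] + a[1:, :-1] + a[:-1, 1:] + a[1:, 1:])

    dudr_cell = cor2cell(dudr_cor)
    dvdz_cell = cor2cell(dvdz_cor)
    gd_cell = shear_rate_magnitude(dudz, dudr_cell, dvdz_cell, dvdr, v_over_r)

    if config.newtonian_override is not None:
        eta_cell = np.full((nz, nr), config.newtonian_override)
        eta_corner = np.full((nz + 1, nr + 1), config.newtonian_override)
        return eta_cell, eta_corner, gd_cell

    eta_cell = carreau_yasuda_viscosity(gd_cell, rheology)
    # corners: average the adjacent cells (clamped at boundaries)
    ext = np.pad(eta_cell, ((1, 1), (1, 1)), mode="edge")
    eta_corner = 0.25 * (ext[:-1, :-1] + ext[1:, :-1] + ext[:-1, 1:] + ext[1:, 1:])
    return eta_cell, eta_corner, gd_cell


def _inlet_profile(inlet_velocity, mesh: Mesh, config: SolverConfig):
    nr = mesh.nr
    if np.ndim(inlet_velocity) == 1:
        prof = np.asarray(inlet_velocity, dtype=float)
        if prof.shape != (nr,):
            raise ValueError(f"inlet velocity array must have shape ({nr},)")
        return prof
    U = float(inlet_velocity)
    if not np.isfinite(U):
        raise ValueError("inlet velocity must be finite")
    xi = (np.arange(nr) + 0.5) / nr
    if config.inlet_profile == "plug":
        return np.full(nr, U)
    return 2.0 * U * (1.0 - xi**2)


# ---------------------------------------------------------------------------
# main time step


def advance_fluid(
    state: FluidState,
    mesh: Mesh,
    mesh_velocity,
    inlet_velocity,
    rheology: RheologyParams,
    porous: PorousParams,
    config: SolverConfig,
    *,
    wall_velocity=None,
    warm_start: FluidState | None = None,
    coeff_state: FluidState | None = None,
) -> FluidState:
    """One linearly-implicit time step; returns the state at t + dt.

    ``mesh_velocity``: (nz,) radial wall-node velocity per column (the grid
    moves by radial scaling); ``wall_velocity``: (nz,) no-slip radial
    velocity imposed on the fluid at the wall (defaults to mesh_velocity —
    the FSI driver passes the structural velocity here so the discrete
    kinematic interface condition holds at convergence).
    ``inlet_velocity``: mean inlet speed (profile per config) or an (nr,)
    profile.  ``warm_start``: a better estimate of the end-of-step state
    (FSI sub-iterations), used as the initial iterate.  ``coeff_state``:
    the state at which the nonlinear coefficients are frozen (defaults to
    warm_start, else the extrapolated state); FSI sub-iterations pass a
    fixed one so the interface map stays the same linear operator across
    the sub-iteration loop.
    """
    nz, nr = mesh.nz, mesh.nr
    dz = mesh.dz
    dt = config.dt
    rho = rheology.rho_fluid

    wall_vel_mesh = np.zeros(nz) if mesh_velocity is None else np.asarray(mesh_velocity, float)
    wall_vel_bc = wall_vel_mesh if wall_velocity is None else np.asarray(wall_velocity, float)

    u_in = _inlet_profile(inlet_velocity, mesh, config)

    # BDF coefficients
    if state.u_prev is None:
        c0, c1, c2 = 1.0, 1.0, 0.0
        u_nm1, v_nm1 = state.u, state.v
    else:
        c0, c1, c2 = 1.5, 2.0, 0.5
        u_nm1, v_nm1 = state.u_prev, state.v_prev

    beta_c, is_micro = _zone_arrays(mesh, porous)
    beta_af = np.empty(nz + 1)
    beta_af[1:-1] = 0.5 * (beta_c[:-1] + beta_c[1:])
    beta_af[0], beta_af[-1] = beta_c[0], beta_c[-1]

    xi_c = (np.arange(nr) + 0.5) / nr
    xi_f = np.arange(nr + 1) / nr

    wall_vel_face = np.empty(nz + 1)
    wall_vel_face[1:-1] = 0.5 * (wall_vel_mesh[:-1] + wall_vel_mesh[1:])
    wall_vel_face[0], wall_vel_face[-1] = wall_vel_mesh[0], wall_vel_mesh[-1]

    # v Dirichlet at the wall (structural no-slip; zero over the rigid zone)
    v_wall = np.where(mesh.zone == Mesh.ZONE_ARTERY, wall_vel_bc, 0.0)

    # frozen coefficient state: explicit, else warm start, else extrapolation
    frozen = coeff_state if coeff_state is not None else warm_start
    if frozen is not None:
        u_adv, v_adv = frozen.u.copy(), frozen.v.copy()
    elif state.u_prev is not None:
        u_adv = 2.0 * state.u - state.u_prev
        v_adv = 2.0 * state.v - state.v_prev
    else:
        u_adv, v_adv = state.u.copy(), state.v.copy()
    p_k = (warm_start.p if warm_start is not None else state.p).copy()
    u_adv[0, :] = u_in
    v_adv[:, 0] = 0.0
    v_adv[:, nr] = v_wall

    eta_cell, eta_corner, _ = _viscosity_fields(u_adv, v_adv, mesh, rheology, config)
    if config.porous_viscosity == "eta_inf" and config.newtonian_override is None:
        eta_sink = np.full_like(eta_cell, rheology.eta_inf)
    else:
        eta_sink = eta_cell
    # Brinkman sink per cell (intrinsic-velocity, phi-divided form)
    s_cell = np.where(is_micro[:, None], porous.porosity * eta_sink / porous.permeability, 0.0)
    s_pad = np.concatenate([s_cell, s_cell[-1:, :]], axis=0)
    s_u = 0.5 * (s_cell + s_pad[1:])  # axial faces 1..nz
    s_v = 0.5 * (s_cell[:, :-1] + s_cell[:, 1:])  # interior radial faces

    hr = config.advection == "high_resolution"
    uA, u_rhs0 = _assemble_u(
        state, u_adv, v_adv, u_nm1, u_in, mesh, rho, c0, c1, c2, dt,
        eta_cell, eta_corner, s_u, wall_vel_face, xi_c, hr,
    )
    vA, v_rhs0 = _assemble_v(
        state, u_adv, v_adv, v_nm1, v_wall, mesh, rho, c0, c1, c2, dt,
        eta_cell, eta_corner, s_v, wall_vel_mesh, xi_f, hr,
    )
    pA, m_u, m_v = _assemble_poisson(mesh, beta_c, beta_af, rho, c0, dt, s_u, s_v)
    u_lu = _Banded5(*uA)
    v_lu = _Banded5(*vA)
    p_lu = _Banded5(*pA)

    if warm_start is not None and coeff_state is not None:
        u_k, v_k = warm_start.u.copy(), warm_start.v.copy()
        u_k[0, :] = u_in
        v_k[:, 0] = 0.0
        v_k[:, nr] = v_wall
    else:
        u_k, v_k = u_adv, v_adv
    u_ref = max(np.max(np.abs(u_in)), np.max(np.abs(state.u)), 1e-12)
    residuals = []
    dr_c = mesh.dr_cell

    for it in range(config.max_inner_iterations):
        u_rhs = u_rhs0.copy()
        u_rhs[:-1, :] -= (p_k[1:, :] - p_k[:-1, :]) / dz
        u_rhs[-1, :] += 2.0 * p_k[-1, :] / dz  # outlet face: p = 0 on the boundary
        u_star = np.vstack([u_in[None, :], u_lu.solve(u_rhs)])

        v_rhs = v_rhs0 - (p_k[:, 1:] - p_k[:, :-1]) / dr_c[:, None]
        v_sol = v_lu.solve(v_rhs)
        v_star = np.zeros((nz, nr + 1))
        v_star[:, 1:nr] = v_sol
        v_star[:, nr] = v_wall

        div = _net_outflux(u_star, v_star, mesh, beta_c, beta_af)
        psi = p_lu.solve(div)

        u_new = u_star.copy()
        u_new[1:nz, :] -= m_u[:-1, :] * (psi[1:, :] - psi[:-1, :]) / dz
        u_new[nz, :] -= m_u[-1, :] * (-2.0 * psi[-1, :]) / dz
        v_new = v_star.copy()
        v_new[:, 1:nr] -= m_v * (psi[:, 1:] - psi[:, :-1]) / dr_c[:, None]
        p_new = p_k + psi

        if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(v_new))):
            raise DivergenceError(f"NaN/Inf detected in fluid fields at t={state.time + dt:.6g}")

        res_u = np.max(np.abs(u_new - u_k)) / u_ref
        res_v = np.max(np.abs(v_new - v_k)) / u_ref
        p_scale = max(np.max(np.abs(p_new)), 1.0)
        res_p = np.max(np.abs(psi)) / p_scale
        res = max(res_u, res_v, res_p)
        residuals.append(res)
        u_k, v_k, p_k = u_new, v_new, p_new
        if res < config.residual_tol and it >= 1:
            break
    else:
        raise ConvergenceError(
            f"pressure-velocity iterations did not reach {config.residual_tol:g} "
            f"in {config.max_inner_iterations} iterations at t={state.time + dt:.6g}",
            residual_history=residuals,
        )

    div_res = _divergence_residual(u_k, v_k, mesh, beta_c, beta_af, u_ref)
    cfl = dt * (np.max(np.abs(u_k)) / dz + np.max(np.abs(v_k)) / np.min(dr_c))

    return FluidState(
        u=u_k,
        v=v_k,
        p=p_k,
        time=state.time + dt,
        u_prev=state.u.copy(),
        v_prev=state.v.copy(),
        diagnostics={
            "iterations": len(residuals),
            "residuals": residuals,
            "div_residual": div_res,
            "cfl": float(cfl),
        },
    )


def _assemble_u(
    state, u_adv, v_adv, u_nm1, u_in, mesh, rho, c0, c1, c2, dt,
    eta_cell, eta_corner, s_u, wall_vel_face, xi_c, hr,
):
    """Implicit axial-momentum matrix and pressure-free RHS (faces 1..nz)."""
    nz, nr = mesh.nz, mesh.nr
    dz = mesh.dz
    dr_f = mesh.dr_face  # (nz+1,)
    r_uf = mesh.r_ufaces  # (nz+1, nr)
    Rw_f = mesh.wall_radius_faces

    # arrays over unknown faces i = 1..nz -> index 0..nz-1
    DR = dr_f[1:, None]  # (nz, 1)
    RU = r_uf[1:, :]  # (nz, nr)
    EC = eta_corner[1:, :]  # (nz, nr+1)
    RC = (np.arange(nr + 1) / nr)[None, :] * Rw_f[1:, None]  # corner radii (nz, nr+1)

    aP = np.full((nz, nr), rho * c0 / dt) + s_u
    aN = np.zeros((nz, nr))
    aS = np.zeros((nz, nr))
    aE = np.zeros((nz, nr))
    aW = np.zeros((nz, nr))
    rhs = rho * (c1 * state.u[1:, :] - c2 * u_nm1[1:, :]) / dt

    # --- radial diffusion (implicit); wall flux linear + deferred quadratic
    g_up = RC[:, 1:] * EC[:, 1:] / (DR * DR * RU)  # coefficient of (u_{j+1}-u_j)
    g_dn = RC[:, :-1] * EC[:, :-1] / (DR * DR * RU)
    aN[:, :-1] -= g_up[:, :-1]
    aP[:, :-1] += g_up[:, :-1]
    # wall face (j = nr-1): linear one-sided, u = 0 at distance dr/2
    g_wall = Rw_f[1:] * eta_corner[1:, nr] * 2.0 / (dr_f[1:] ** 2 * RU[:, nr - 1])
    aP[:, nr - 1] += g_wall
    # deferred correction to the quadratic one-sided wall gradient
    u1 = u_adv[1:, nr - 1]
    u2 = u_adv[1:, nr - 2]
    rhs[:, nr - 1] += (
        Rw_f[1:]
        * eta_corner[1:, nr]
        * ((u2 - 9.0 * u1) / (3.0 * dr_f[1:]) + 2.0 * u1 / dr_f[1:])
        / (RU[:, nr - 1] * dr_f[1:])
    )
    # lower faces (j >= 1); the j = 0 face is the axis, r = 0 -> no flux
    aS[:, 1:] -= g_dn[:, 1:]
    aP[:, 1:] += g_dn[:, 1:]

    # --- axial diffusion, d/dz(2 eta du/dz) implicit
    eta_E = np.concatenate([eta_cell[1:, :], eta_cell[-1:, :]], axis=0)
    eta_W = eta_cell
    cE = 2.0 * eta_E / dz**2
    cW = 2.0 * eta_W / dz**2
    aE[:-1, :] -= cE[:-1, :]
    aP[:-1, :] += cE[:-1, :]
    # outlet face nz: du/dz = 0 beyond -> no E flux
    aW[:, :] -= cW
    aP[:, :] += cW
    rhs[0, :] += cW[0, :] * u_in  # inlet Dirichlet neighbour
    aW[0, :] = 0.0

    # --- convection: implicit first-order upwind + frozen MUSCL correction
    wz = u_adv[1:, :]  # (nz, nr)
    v_pad = np.concatenate([v_adv[:1], v_adv, v_adv[-1:]], axis=0)  # (nz+2, nr+1)
    v_at_u = 0.25 * (v_pad[:-1, :-1] + v_pad[:-1, 1:] + v_pad[1:, :-1] + v_pad[1:, 1:])
    wr_full = v_at_u - xi_c[None, :] * wall_vel_face[:, None]  # (nz+1, nr)
    wr = wr_full[1:, :]

    wzp = np.maximum(wz, 0.0)
    wzm = np.minimum(wz, 0.0)
    aP += rho * wzp / dz
    aW -= rho * wzp / dz
    rhs[0, :] += rho * wzp[0, :] / dz * u_in  # face 1 upstream is the inlet
    aW[0, :] = 0.0
    aP += rho * (-wzm) / dz
    aE -= rho * (-wzm) / dz
    aE[-1, :] = 0.0  # outlet: downstream ghost equals the face value
    aP[-1, :] -= rho * (-wzm[-1, :]) / dz

    wrp = np.maximum(wr, 0.0)
    wrm = np.minimum(wr, 0.0)
    aP += rho * wrp / DR
    aS -= rho * wrp / DR
    # axis (j=0): symmetric ghost equals u -> derivative contribution vanishes
    aP[:, 0] -= rho * wrp[:, 0] / DR[:, 0]
    aS[:, 0] = 0.0
    aP += rho * (-wrm) / DR
    aN -= rho * (-wrm) / DR
    # wall (j=nr-1): downwind value is u = 0 at dr/2
    aN[:, nr - 1] = 0.0
    aP[:, nr - 1] += rho * (-wrm[:, nr - 1]) / DR[:, 0]

    if hr:
        corr_z = _muscl_correction(u_adv, u_adv, dz, 0)
        h_r = np.broadcast_to(dr_f[:, None], u_adv.shape)
        corr_r = _muscl_correction(u_adv, wr_full, h_r, 1)
        rhs -= rho * (wz * corr_z[1:, :] + wr * corr_r[1:, :])

    # --- explicit cross-stress: (1/r) d/dr ( r eta dv/dz )
    g_cor = np.zeros((nz + 1, nr + 1))
    g_cor[1:nz, :] = (v_adv[1:, :] - v_adv[:-1, :]) / dz
    # inlet: v = 0 on the plane and at the first column face -> leave 0
    # outlet: dv/dz = 0
    RCfull = (np.arange(nr + 1) / nr)[None, :] * Rw_f[:, None]
    flux = RCfull * eta_corner * g_cor  # (nz+1, nr+1)
    cross = (flux[:, 1:] - flux[:, :-1]) / (r_uf * dr_f[:, None])
    rhs += cross[1:, :]

    return (aP, aN, aS, aE, aW), rhs


def _assemble_v(
    state, u_adv, v_adv, v_nm1, v_wall, mesh, rho, c0, c1, c2, dt,
    eta_cell, eta_corner, s_v, wall_vel_mesh, xi_f, hr,
):
    """Implicit radial-momentum matrix and pressure-free RHS (j = 1..nr-1)."""
    nz, nr = mesh.nz, mesh.nr
    dz = mesh.dz
    dr_c = mesh.dr_cell  # (nz,)
    DR = dr_c[:, None]
    r_f = mesh.r_rfaces  # (nz, nr+1)
    r_c = mesh.r_centers  # (nz, nr)

    J = slice(1, nr)  # unknown radial faces
    RF = r_f[:, J]  # (nz, nr-1)

    aP = np.full((nz, nr - 1), rho * c0 / dt) + s_v
    aN = np.zeros((nz, nr - 1))
    aS = np.zeros((nz, nr - 1))
    aE = np.zeros((nz, nr - 1))
    aW = np.zeros((nz, nr - 1))
    rhs = rho * (c1 * state.v[:, J] - c2 * v_nm1[:, J]) / dt

    # --- radial diffusion (1/r) d/dr (2 r eta dv/dr), fluxes at cell centres
    g_up = 2.0 * r_c[:, 1:] * eta_cell[:, 1:] / (DR * DR * RF)
    g_dn = 2.0 * r_c[:, :-1] * eta_cell[:, :-1] / (DR * DR * RF)
    aN[:, :-1] -= g_up[:, :-1]
    aP[:, :-1] += g_up[:, :-1]
    rhs[:, -1] += g_up[:, -1] * v_wall  # wall Dirichlet neighbour
    aP[:, -1] += g_up[:, -1]
    aS[:, 1:] -= g_dn[:, 1:]
    aP[:, 1:] += g_dn[:, 1:]
    aP[:, 0] += g_dn[:, 0]  # axis neighbour v = 0

    # hoop term 2 eta v / r^2 (implicit, diagonal)
    eta_v = 0.5 * (eta_cell[:, :-1] + eta_cell[:, 1:])
    aP += 2.0 * eta_v / RF**2

    # --- axial diffusion d/dz (eta dv/dz), eta at corners
    EC = eta_corner[:, J]  # (nz+1, nr-1)
    cE = EC[1:, :] / dz**2
    cW = EC[:-1, :] / dz**2
    aE[:-1, :] -= cE[:-1, :]
    aP[:-1, :] += cE[:-1, :]
    # outlet column: dv/dz = 0 -> no E flux
    aW[1:, :] -= cW[1:, :]
    aP[1:, :] += cW[1:, :]
    aP[0, :] += 2.0 * cW[0, :]  # inlet plane v = 0 at dz/2

    # --- convection (coefficients frozen at the adv state)
    wz = 0.25 * (u_adv[:-1, :-1] + u_adv[:-1, 1:] + u_adv[1:, :-1] + u_adv[1:, 1:])
    u_m = xi_f[None, J] * wall_vel_mesh[:, None]
    wr = v_adv[:, J] - u_m

    wzp = np.maximum(wz, 0.0)
    wzm = np.minimum(wz, 0.0)
    aP += rho * wzp / dz
    aW -= rho * wzp / dz
    aW[0, :] = 0.0
    aP[0, :] += rho * wzp[0, :] / dz  # inlet upstream value 0 at dz/2
    aP += rho * (-wzm) / dz
    aE -= rho * (-wzm) / dz
    aE[-1, :] = 0.0
    aP[-1, :] -= rho * (-wzm[-1, :]) / dz  # downstream ghost = v

    wrp = np.maximum(wr, 0.0)
    wrm = np.minimum(wr, 0.0)
    aP += rho * wrp / DR
    aS -= rho * wrp / DR
    aS[:, 0] = 0.0  # upstream neighbour is the axis value 0
    aP += rho * (-wrm) / DR
    aN -= rho * (-wrm) / DR
    rhs[:, -1] += rho * (-wrm[:, -1]) / DR[:, 0] * v_wall
    aN[:, -1] = 0.0

    if hr:
        # radial ghosts: v odd across the axis, linear beyond the wall
        v_ext = np.concatenate(
            [-v_adv[:, 1:2], v_adv, 2.0 * v_wall[:, None] - v_adv[:, nr - 1 : nr]], axis=1
        )  # (nz, nr+3); interior face j maps to column j+1
        w_ext = np.zeros_like(v_ext)
        w_ext[:, 2 : nr + 1] = wr
        h_r = np.broadcast_to(DR, v_ext.shape)
        corr_r = _muscl_correction(v_ext, w_ext, h_r, 1)[:, 2 : nr + 1]
        wz_full = np.zeros((nz, nr + 1))
        wz_full[:, 1:nr] = wz
        corr_z = _muscl_correction(v_adv, wz_full, dz, 0)[:, J]
        rhs -= rho * (wz * corr_z + wr * corr_r)

    # --- explicit cross-stress: d/dz (eta du/dr), corners at (i, j)
    dudr_cor = (u_adv[:, 1:] - u_adv[:, :-1]) / mesh.dr_face[:, None]  # (nz+1, nr-1)
    flux = eta_corner[:, J] * dudr_cor
    rhs += (flux[1:, :] - flux[:-1, :]) / dz

    return (aP, aN, aS, aE, aW), rhs


def _flux_areas(mesh: Mesh):
    """Axial-face and radial-face areas per radian, and cell volumes."""
    A_ax = mesh.r_ufaces * mesh.dr_face[:, None]  # (nz+1, nr)
    A_rf = mesh.r_rfaces * mesh.dz  # (nz, nr+1)
    return A_ax, A_rf


def _net_outflux(u, v, mesh, beta_c, beta_af):
    A_ax, A_rf = _flux_areas(mesh)
    fz = beta_af[:, None] * u * A_ax  # (nz+1, nr)
    fr = beta_c[:, None] * v * A_rf  # (nz, nr+1)
    return (fz[1:, :] - fz[:-1, :]) + (fr[:, 1:] - fr[:, :-1])


def _assemble_poisson(mesh, beta_c, beta_af, rho, c0, dt, s_u, s_v):
    """Pressure-correction operator with sink-aware mobility.

    The mobility m = 1 / (rho c0/dt + s) matches the momentum diagonal so
    the update converges fast in the porous zone; the corrected field is
    exactly divergence-free for any mobility.  Returns the matrix diagonals
    plus (m_u, m_v) for the velocity update.
    """
    nz, nr = mesh.nz, mesh.nr
    dz = mesh.dz
    dr_c = mesh.dr_cell
    A_ax, A_rf = _flux_areas(mesh)
    base = rho * c0 / dt

    m_u = 1.0 / (base + s_u)  # (nz, nr), axial faces 1..nz
    m_v = 1.0 / (base + s_v)  # (nz, nr-1), interior radial faces

    T_ax = beta_af[1:, None] * A_ax[1:, :] * m_u / dz  # faces 1..nz
    T_rf = beta_c[:, None] * A_rf[:, 1:nr] * m_v / dr_c[:, None]

    aE = np.zeros((nz, nr))
    aW = np.zeros((nz, nr))
    aN = np.zeros((nz, nr))
    aS = np.zeros((nz, nr))
    aE[:-1, :] = T_ax[:-1, :]
    aW[1:, :] = T_ax[:-1, :]
    aN[:, :-1] = T_rf
    aS[:, 1:] = T_rf
    aP = -(aE + aW + aN + aS)
    aP[-1, :] -= 2.0 * T_ax[-1, :]  # outlet: psi = 0 on the boundary face

    return (aP, aN, aS, aE, aW), m_u, m_v


def _divergence_residual(u, v, mesh, beta_c, beta_af, u_ref):
    """Max cell imbalance normalised by the largest face flux."""
    net = _net_outflux(u, v, mesh, beta_c, beta_af)
    A_ax, _ = _flux_areas(mesh)
    scale = max(np.max(np.abs(beta_af[:, None] * u * A_ax)), u_ref * A_ax.max(), 1e-300)
    return float(np.max(np.abs(net)) / scale)


# ---------------------------------------------------------------------------
# wall outputs


def wall_traction(state: FluidState, mesh: Mesh, rheology: RheologyParams,
                  newtonian_override: float | None = None) -> np.ndarray:
    """Radial normal traction p - 2 eta dv/dr on the wall, per cell column.

    For near-parallel flow the viscous normal stress is negligible and the
    traction reduces to the wall pressure.
    """
    nr = mesh.nr
    p = state.p
    # linear extrapolation of the two near-wall cell pressures to r = Rw
    p_w = p[:, nr - 1] + 0.5 * (p[:, nr - 1] - p[:, nr - 2])
    dvdr_w = (state.v[:, nr] - state.v[:, nr - 1]) / mesh.dr_cell
    eta_w = _eta_wall(state, mesh, rheology, newtonian_override)
    eta_w_cell = 0.5 * (eta_w[:-1] + eta_w[1:])
    return p_w - 2.0 * eta_w_cell * dvdr_w


def _wall_gradient(state: FluidState, mesh: Mesh) -> np.ndarray:
    """One-sided quadratic du/dr at the wall per axial face (nz+1,)."""
    u = state.u
    nr = mesh.nr
    return (u[:, nr - 2] - 9.0 * u[:, nr - 1]) / (3.0 * mesh.dr_face)


def _eta_wall(state, mesh, rheology, newtonian_override):
    if newtonian_override is not None:
        return np.full(mesh.nz + 1, newtonian_override)
    gd_w = np.abs(_wall_gradient(state, mesh))
    return carreau_yasuda_viscosity(gd_w, rheology)


def wall_shear_stress(state: FluidState, mesh: Mesh, rheology: RheologyParams,
                      newtonian_override: float | None = None) -> np.ndarray:
    """Signed wall shear stress tau_w = -eta(gd_w) du/dr|wall per axial face.

    Positive for forward (inlet-to-outlet) flow; evaluated on the current
    (deformed) grid with a one-sided second-order gradient.
    """
    g = _wall_gradient(state, mesh)
    eta_w = _eta_wall(state, mesh, rheology, newtonian_override)
    return -eta_w * g


def zone_interface_fluxes(state: FluidState, mesh: Mesh, porous: PorousParams) -> dict:
    """Mass-flux and pressure-continuity diagnostics at the zone interface.

    Returns volumetric flux (m^3/s) through the last fully-arterial face and
    the first fully-porous face (superficial, area_expansion-scaled), their
    relative mismatch, and the extrapolated pressure jump across the
    interface (Pa).
    """
    i_if = mesh.interface_face
    A_ax, _ = _flux_areas(mesh)

    def face_flux(i, beta):
        return 2.0 * np.pi * float(np.sum(beta * state.u[i, :] * A_ax[i, :]))

    q_artery = face_flux(i_if - 1, 1.0)
    q_porous = face_flux(i_if + 1, porous.flux_area_fraction)
    scale = max(abs(q_artery), abs(q_porous), 1e-300)
    mismatch = abs(q_artery - q_porous) / scale

    # area-averaged column pressures extrapolated to the interface
    w = mesh.r_centers * mesh.dr_cell[:, None]
    p_col = np.sum(state.p * w, axis=1) / np.sum(w, axis=1)
    pL = p_col[i_if - 1] + 0.5 * (p_col[i_if - 1] - p_col[i_if - 2])
    pR = p_col[i_if] - 0.5 * (p_col[i_if + 1] - p_col[i_if])
    return {
        "artery_flux": q_artery,
        "porous_superficial_flux": q_porous,
        "flux_mismatch": mismatch,
        "pressure_jump": float(pL - pR),
    }
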