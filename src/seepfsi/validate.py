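"""Verification experiments against closed-form solutions.

Each experiment builds a small configuration, runs the actual solver, and
returns measured-vs-analytic numbers.  They back the test suite and the
``seepfsi validate`` command:

- steady Poiseuille flow in a rigid tube (wall shear 4 eta U / R),
- the steady Darcy limit of the porous zone (dp/dz = eta q / k),
- oscillatory Womersley flow (profile + wall-shear amplitude, grid
  convergence),
- static FSI inflation (interface displacement p / kappa).

The porous zone can be made dynamically identical to the artery zone by
setting phi = 1, area_expansion = 1 and an (effectively) infinite
permeability; the rigid-tube experiments use that to run a plain tube
through the full two-zone machinery.
"""

from __future__ import annotations

import numpy as np

from .constitutive import PorousParams, RheologyParams
from .driver import CouplingConfig, SECTIONS, run_simulation, step_coupled
from .fluid import FluidState, SolverConfig, advance_fluid, wall_shear_stress, wall_traction
from .geometry import GeometryConfig, build_mesh
from .postprocess import (
    womersley_flow_rate_amplitude,
    womersley_solution,
    womersley_wall_shear_amplitude,
)
from .wall import WallParams, WallState, ring_stiffness

__all__ = [
    "neutral_porous",
    "poiseuille_experiment",
    "darcy_experiment",
    "womersley_experiment",
    "static_inflation_experiment",
    "run_validation_suite",
]


def neutral_porous() -> PorousParams:
    """Porous parameters that make the micro zone behave as plain fluid."""
    return PorousParams(porosity=1.0, area_expansion=1.0, permeability=np.inf)


def poiseuille_experiment(
    nz: int = 150,
    nr: int = 24,
    u_mean: float = 0.1,
    eta: float = 2.2e-3,
    radius: float = 0.01,
    n_steps: int = 10,
    dt: float = 5e-3,
):
    """Steady developed Newtonian tube flow through the full solver.

    The analytic parabola (parabolic inlet) is the initial condition; the
    solver marches ``n_steps`` implicit steps and the wall shear stress at
    mid-tube is compared with 4 eta u_mean / R.
    """
    geom = GeometryConfig(radius=radius, artery_length=0.15, micro_length=0.05)
    mesh = build_mesh(geom, nz, nr)
    rheo = RheologyParams()
    porous = neutral_porous()
    cfg = SolverConfig(dt=dt, newtonian_override=eta, inlet_profile="parabolic")

    state = FluidState.zeros(mesh)
    r = mesh.r_ufaces
    state.u[:, :] = 2.0 * u_mean * (1.0 - (r / radius) ** 2)
    L = geom.total_length
    grad = 8.0 * eta * u_mean / radius**2
    zc = mesh.z_centers
    state.p[:, :] = (grad * (L - zc))[:, None]

    for _ in range(n_steps):
        state = advance_fluid(state, mesh, None, u_mean, rheo, porous, cfg)

    tau = wall_shear_stress(state, mesh, rheo, eta)
    i_mid = nz // 2
    tau_exact = 4.0 * eta * u_mean / radius
    err = abs(tau[i_mid] - tau_exact) / tau_exact
    return {
        "wss": float(tau[i_mid]),
        "wss_exact": tau_exact,
        "rel_error": float(err),
        "div_residual": state.diagnostics["div_residual"],
        "state": state,
        "mesh": mesh,
        "ok": err < 0.01,
    }


def darcy_experiment(
    q: float = 0.01,
    k: float = 1e-10,
    micro_length: float = 0.1,
    eta: float = 2.2e-3,
    nz: int = 60,
    nr: int = 10,
    n_steps: int = 60,
    dt: float = 1e-2,
):
    """Steady porous-column seepage: pressure drop versus Darcy's law.

    A short artery stub feeds the porous zone at superficial flux ``q``;
    the pressure gradient measured between two interior porous stations is
    compared with eta q / k (independent of porosity for superficial flux).
    """
    geom = GeometryConfig(artery_length=0.05, micro_length=micro_length)
    mesh = build_mesh(geom, nz, nr)
    rheo = RheologyParams()
    porous = PorousParams(porosity=0.5, permeability=k, area_expansion=1.0)
    cfg = SolverConfig(dt=dt, newtonian_override=eta)

    state = FluidState.zeros(mesh)
    for _ in range(n_steps):
        state = advance_fluid(state, mesh, None, q, rheo, porous, cfg)

    zc = mesh.z_centers
    micro = mesh.zone == mesh.ZONE_MICRO
    i_lo = np.nonzero(micro & (zc > geom.artery_length + 0.15 * micro_length))[0][0]
    i_hi = np.nonzero(micro & (zc < geom.total_length - 0.1 * micro_length))[0][-1]
    p_axis = state.p[:, 0]
    dp = p_axis[i_lo] - p_axis[i_hi]
    L_meas = zc[i_hi] - zc[i_lo]
    dp_exact = eta * q * L_meas / k
    err = abs(dp - dp_exact) / dp_exact
    return {
        "dp": float(dp),
        "dp_exact": float(dp_exact),
        "rel_error": float(err),
        "state": state,
        "mesh": mesh,
        "ok": err < 0.01,
    }


def womersley_experiment(
    eta: float,
    nr: int = 48,
    nz: int = 24,
    dt: float = 1e-3,
    period: float = 0.8,
    pressure_gradient: float = 200.0,
    radius: float = 0.01,
    rho: float = 1050.0,
    periods: float = 1.0,
):
    """Oscillatory rigid-tube flow against the Bessel-series solution.

    The analytic Womersley field (driven by -dp/dz = G cos(omega t)) is the
    initial condition and the inlet profile at every step; after ``periods``
    periods the velocity field and the wall-shear time series are compared
    with the closed form.  Returns relative L2 profile error and relative
    wall-shear-amplitude error.
    """
    omega = 2.0 * np.pi / period
    geom = GeometryConfig(radius=radius, artery_length=0.15, micro_length=0.05)
    mesh = build_mesh(geom, nz, nr)
    rheo = RheologyParams(rho_fluid=rho)
    porous = neutral_porous()
    cfg = SolverConfig(dt=dt, newtonian_override=eta)

    def exact_u(r, t):
        return womersley_solution(radius, rho, eta, pressure_gradient, omega, r, t)

    state = FluidState.zeros(mesh)
    state.u[:, :] = exact_u(mesh.r_ufaces[0], 0.0)[None, :]
    L = geom.total_length
    state.p[:, :] = (pressure_gradient * np.cos(0.0) * (L - mesh.z_centers))[:, None]

    n_steps = int(round(periods * period / dt))
    xi_inlet = mesh.r_ufaces[0]
    i_mid = nz // 2
    tau_series = []
    for n in range(n_steps):
        t_new = (n + 1) * dt
        u_in = exact_u(xi_inlet, t_new)
        state = advance_fluid(state, mesh, None, u_in, rheo, porous, cfg)
        tau_series.append(wall_shear_stress(state, mesh, rheo, eta)[i_mid])

    t_end = n_steps * dt
    u_exact = exact_u(mesh.r_ufaces[i_mid], t_end)
    u_num = state.u[i_mid, :]
    w = mesh.r_ufaces[i_mid]
    scale = np.sqrt(np.sum(w * u_exact**2))
    l2 = float(np.sqrt(np.sum(w * (u_num - u_exact) ** 2)) / max(scale, 1e-300))

    # wall-shear amplitude: least-squares fit of the known-frequency
    # sinusoid over the second half of the run (start-up transient skipped)
    i0 = n_steps // 2
    tau = np.asarray(tau_series)[i0:]
    tt = dt * np.arange(i0 + 1, n_steps + 1)
    basis = np.column_stack([np.cos(omega * tt), np.sin(omega * tt), np.ones_like(tt)])
    coef, *_ = np.linalg.lstsq(basis, tau, rcond=None)
    amp = float(np.hypot(coef[0], coef[1]))
    amp_exact = womersley_wall_shear_amplitude(radius, rho, eta, pressure_gradient, omega)
    amp_err = abs(amp - amp_exact) / amp_exact
    alpha = radius * np.sqrt(omega * rho / eta)
    return {
        "alpha": float(alpha),
        "l2_profile_error": l2,
        "wss_amplitude": float(amp),
        "wss_amplitude_exact": amp_exact,
        "wss_amplitude_error": float(amp_err),
        "state": state,
        "mesh": mesh,
    }


def womersley_convergence(eta: float, resolutions=(12, 24, 48), **kwargs):
    """Profile error versus radial resolution; returns errors and the
    observed order between successive refinements."""
    errs = []
    for nr in resolutions:
        out = womersley_experiment(eta, nr=nr, **kwargs)
        errs.append(out["l2_profile_error"])
    orders = [
        float(np.log2(errs[i] / errs[i + 1])) for i in range(len(errs) - 1)
    ]
    return {"resolutions": list(resolutions), "errors": errs, "orders": orders}


def static_inflation_experiment(
    u_inlet: float = 0.2,
    eta: float = 3.5e-3,
    area_expansion: float = 4e5,
    nz: int = 60,
    nr: int = 10,
    n_steps: int = 100,
    dt: float = 4e-3,
    damping: float = 3e4,
):
    """Steady compliant inflation: interface displacement versus p / kappa.

    Constant inflow against the porous resistance pressurises the artery;
    with near-critical structural damping the rings settle to their static
    response, and each interior station's displacement is compared with
    traction / kappa.
    """
    geom = GeometryConfig()
    mesh0 = build_mesh(geom, nz, nr)
    rheo = RheologyParams()
    porous = PorousParams(area_expansion=area_expansion)
    wall_params = WallParams(damping=damping)
    solver = SolverConfig(dt=dt, newtonian_override=eta)
    coupling = CouplingConfig()

    fluid = FluidState.zeros(mesh0)
    wall = WallState.zeros(mesh0.n_artery)
    mesh = mesh0
    for _ in range(n_steps):
        fluid, wall, mesh, _ = step_coupled(
            fluid, wall, mesh, mesh0, u_inlet, rheo, porous, wall_params, solver, coupling
        )

    kappa = ring_stiffness(wall_params)
    traction = wall_traction(fluid, mesh, rheo, solver.newtonian_override)[mesh.artery_cells]
    d = wall.displacement
    interior = slice(2, -2)
    expected = traction[interior] / kappa
    err = np.max(np.abs(d[interior] - expected) / np.abs(expected))
    return {
        "max_rel_error": float(err),
        "displacement": d,
        "expected": traction / kappa,
        "ok": err < 0.01,
    }


def run_validation_suite() -> dict:
    """Fast subset used by the CLI ``validate`` command."""
    report = {}
    pois = poiseuille_experiment(nz=60, nr=16, n_steps=5)
    report["poiseuille_wss"] = {
        "value": pois["wss"], "exact": pois["wss_exact"],
        "rel_error": pois["rel_error"], "ok": bool(pois["ok"]),
    }
    dar = darcy_experiment(n_steps=40)
    report["darcy_pressure_drop"] = {
        "value": dar["dp"], "exact": dar["dp_exact"],
        "rel_error": dar["rel_error"], "ok": bool(dar["ok"]),
    }
    stat = static_inflation_experiment(nz=40, nr=8, n_steps=60)
    report["static_inflation"] = {
        "rel_error": stat["max_rel_error"], "ok": bool(stat["ok"]),
    }
    return report
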