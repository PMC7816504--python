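"""Calibration of the under-determined closure parameters.

Two quantities are not fixed by first principles in this model and are set
by calibration, both logged and echoed in run provenance:

1. The terminal resistance of the porous outlet.  Strict mass conservation
   in a uniform tube with the Kozeny–Carman permeability of an 8 um
   microvessel bed would force arterial-scale superficial velocities
   through the porous zone and astronomically large pressure drops; a real
   capillary bed carries the same flow through a total cross-section many
   orders of magnitude larger than the feeding artery.  ``area_expansion``
   scales the porous flux area so the rigid-wall cycle-maximum arterial
   pressure matches a physiological target; the Darcy law gives the first
   guess and 1–2 secant steps on full rigid runs refine it.

2. The inlet waveform peak.  The generator is a stand-in for a measured
   velocity trace known only by its near-inlet peak; ``peak_velocity`` is
   scaled so the simulated S1 peak sectional velocity matches the target.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .constitutive import PorousParams, RheologyParams
from .driver import CouplingConfig, run_simulation
from .fluid import SolverConfig
from .geometry import GeometryConfig
from .wall import WallParams
from .waveform import WaveformConfig

__all__ = ["darcy_area_expansion_guess", "calibrate_terminal_resistance", "calibrate_waveform_peak"]

log = logging.getLogger(__name__)


def _sink_viscosity(rheology: RheologyParams, solver: SolverConfig) -> float:
    """Viscosity governing the porous Darcy drop at near-zero pore shear."""
    if solver.newtonian_override is not None:
        return solver.newtonian_override
    if solver.porous_viscosity == "eta_inf":
        return rheology.eta_inf
    return rheology.eta_0  # local evaluation at ~zero shear rate


def darcy_area_expansion_guess(
    target_pressure: float,
    peak_superficial_velocity: float,
    geometry: GeometryConfig,
    porous: PorousParams,
    rheology: RheologyParams,
    solver: SolverConfig,
) -> float:
    """Closed-form Darcy estimate of the area expansion hitting a target
    peak pressure: delta_p = eta u_sup L_mic / (k A_e)."""
    eta = _sink_viscosity(rheology, solver)
    a = eta * peak_superficial_velocity * geometry.micro_length / porous.permeability
    return max(a / target_pressure, 1.0)


def _rigid_peak_pressure(porous, **kwargs) -> float:
    res = run_simulation(porous=porous, **kwargs)
    summ = res.analysis_summary()
    return float(max(summ.loc["S1", "peak_pressure"], summ.loc["S2", "peak_pressure"]))


def calibrate_terminal_resistance(
    target_pressure: float,
    geometry: GeometryConfig = GeometryConfig(),
    waveform_config: WaveformConfig = WaveformConfig(),
    rheology: RheologyParams = RheologyParams(),
    porous: PorousParams = PorousParams(),
    wall_params: WallParams = WallParams(),
    solver: SolverConfig = SolverConfig(),
    coupling: CouplingConfig = CouplingConfig(),
    nz: int = 150,
    nr: int = 24,
    rel_tol: float = 0.03,
    max_runs: int = 4,
):
    """Tune ``area_expansion`` so the rigid-wall run's cycle-maximum artery
    pressure matches ``target_pressure``.

    Returns (calibrated PorousParams, info dict).  The arterial pressure is
    nearly affine in 1/area_expansion (Darcy resistance plus a
    resistance-independent inertial part), so a secant iteration on
    x = 1/area_expansion converges in one or two refinement runs.
    """
    rigid_wall = replace(wall_params, rigid=True)
    kwargs = dict(
        geometry=geometry,
        waveform_config=waveform_config,
        rheology=rheology,
        wall_params=rigid_wall,
        solver=solver,
        coupling=coupling,
        nz=nz,
        nr=nr,
    )
    x0 = 1.0 / darcy_area_expansion_guess(
        target_pressure, waveform_config.peak_velocity, geometry, porous, rheology, solver
    )
    history = []
    p0 = _rigid_peak_pressure(replace(porous, area_expansion=1.0 / x0), **kwargs)
    history.append((1.0 / x0, p0))
    log.info("terminal-resistance calibration: A_e=%.4g -> p_max=%.4g Pa", 1.0 / x0, p0)
    # second point from the analytic Darcy slope a = p_target / x_guess
    a = target_pressure / x0
    b = p0 - a * x0
    x1 = max((target_pressure - b) / a, 1e-12) if target_pressure > b else 0.5 * x0
    p_prev, x_prev = p0, x0
    x, p = x1, None
    for _ in range(max_runs - 1):
        if abs(p_prev - target_pressure) / target_pressure < rel_tol:
            x = x_prev
            p = p_prev
            break
        p = _rigid_peak_pressure(replace(porous, area_expansion=1.0 / x), **kwargs)
        history.append((1.0 / x, p))
        log.info("terminal-resistance calibration: A_e=%.4g -> p_max=%.4g Pa", 1.0 / x, p)
        if abs(p - target_pressure) / target_pressure < rel_tol:
            break
        slope = (p - p_prev) / (x - x_prev)
        if slope <= 0:
            break
        x_prev, p_prev = x, p
        x = x + (target_pressure - p) / slope
        x = max(x, 1e-12)
    calibrated = replace(porous, area_expansion=1.0 / x)
    info = {
        "history": history,
        "area_expansion": 1.0 / x,
        "achieved_pressure": p if p is not None else p0,
        "target_pressure": target_pressure,
    }
    return calibrated, info


def calibrate_waveform_peak(
    target_s1_peak_velocity: float,
    waveform_config: WaveformConfig,
    measure,
    rel_tol: float = 0.02,
    max_runs: int = 2,
):
    """Scale the generator peak until the simulated S1 peak sectional
    velocity matches the target.

    ``measure`` is a callable WaveformConfig -> simulated S1 peak velocity.
    With a plug inlet the response is close to identity, so this usually
    accepts the first run.
    """
    cfg = waveform_config
    measured = None
    for _ in range(max_runs):
        measured = measure(cfg)
        if abs(measured - target_s1_peak_velocity) / target_s1_peak_velocity < rel_tol:
            break
        scale = target_s1_peak_velocity / measured
        cfg = replace(
            cfg,
            peak_velocity=cfg.peak_velocity * scale,
            diastolic_velocity=cfg.diastolic_velocity * scale,
        )
        log.info("waveform calibration: scaling peak by %.4f -> %.4g m/s", scale, cfg.peak_velocity)
    return cfg, measured
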