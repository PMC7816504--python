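"""Probe-series reduction and the analytic verification oracles.

Reductions: cycle extraction, per-section/per-cycle extrema (peak and
bottom pressure, amplitude, peak sectional velocity, peak wall shear
stress), and compliant-vs-rigid comparison tables.

Oracles: the classical Womersley oscillatory pipe-flow solution (Bessel
functions, Newtonian) including the analytic wall-shear amplitude, and the
Moens–Korteweg pulse-wave speed c = sqrt(E h / (2 rho R)) for a thin
elastic tube.  Both are closed forms independent of the finite-volume
solver and are used to verify it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import jv

__all__ = [
    "ProbeSeries",
    "extract_cycle",
    "cycle_summary",
    "compare_runs",
    "womersley_solution",
    "womersley_wall_shear_amplitude",
    "moens_korteweg_speed",
]


@dataclass
class ProbeSeries:
    """Uniformly sampled per-section time series.

    ``pressure``, ``velocity`` and ``wss`` have shape (n_sections, n_times);
    sections are ordered by axial position.
    """

    time: np.ndarray
    pressure: np.ndarray
    velocity: np.ndarray
    wss: np.ndarray
    sections: list
    section_positions: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.time}
        for i, s in enumerate(self.sections):
            cols[f"pressure_{s}"] = self.pressure[i]
            cols[f"velocity_{s}"] = self.velocity[i]
            cols[f"wss_{s}"] = self.wss[i]
        return pd.DataFrame(cols)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def extract_cycle(series: ProbeSeries, cycle_index: int, period: float) -> ProbeSeries:
    """Sub-series covering [(k-1) T, k T] for cycle k (1-based).

    The sample at the closing instant k*T is included, so consecutive
    extracted cycles share their boundary sample.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    dt = series.dt
    per_cycle = int(round(period / dt))
    i0 = (cycle_index - 1) * per_cycle
    i1 = cycle_index * per_cycle
    if i1 > len(series.time) - 1:
        raise ValueError(
            f"series spans {len(series.time) - 1} steps; cycle {cycle_index} "
            f"needs {i1}"
        )
    sl = slice(i0, i1 + 1)
    return replace(
        series,
        time=series.time[sl],
        pressure=series.pressure[:, sl],
        velocity=series.velocity[:, sl],
        wss=series.wss[:, sl],
    )


def cycle_summary(series: ProbeSeries) -> pd.DataFrame:
    """Per-section extrema over (one cycle of) the series.

    Columns: peak_pressure, bottom_pressure, pressure_amplitude,
    peak_velocity, peak_wss; indexed by section name.
    """
    rows = {}
    for i, s in enumerate(series.sections):
        p = series.pressure[i]
        rows[s] = {
            "peak_pressure": float(np.max(p)),
            "bottom_pressure": float(np.min(p)),
            "pressure_amplitude": float(np.max(p) - np.min(p)),
            "peak_velocity": float(np.max(series.velocity[i])),
            "peak_wss": float(np.max(series.wss[i])),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_runs(compliant: pd.DataFrame, rigid: pd.DataFrame) -> pd.DataFrame:
    """Per-section compliant-minus-rigid deltas and compliant/rigid ratios.

    Inputs are ``cycle_summary`` frames over the same sections.  The result
    is antisymmetric in the sense that swapping the arguments negates the
    deltas and inverts the ratios.
    """
    if list(compliant.index) != list(rigid.index):
        raise ValueError("section sets differ between the two summaries")
    out = {}
    for col in ("peak_pressure", "peak_velocity", "peak_wss"):
        out[f"delta_{col}"] = compliant[col] - rigid[col]
        out[f"ratio_{col}"] = compliant[col] / rigid[col]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# analytic oracles


def womersley_number(R: float, omega: float, rho: float, eta: float) -> float:
    """alpha = R sqrt(omega rho / eta)."""
    return R * np.sqrt(omega * rho / eta)


def womersley_solution(R, rho, eta, pressure_gradient_amplitude, omega, r, t):
    """Oscillatory Newtonian pipe flow driven by -dp/dz = G cos(omega t).

    Returns the axial velocity at radius r and time t:

        u(r, t) = Re[ (G / (i rho omega)) (1 - J0(zeta r/R) / J0(zeta)) e^{i omega t} ],

    with zeta = i^{3/2} alpha and alpha the Womersley number.  ``r`` and
    ``t`` may be arrays (broadcast).
    """
    G = pressure_gradient_amplitude
    alpha = womersley_number(R, omega, rho, eta)
    zeta = 1j**1.5 * alpha
    r = np.asarray(r, dtype=float)
    if np.any(r > R * (1 + 1e-12)):
        raise ValueError("r must not exceed R")
    prof = 1.0 - jv(0, zeta * r / R) / jv(0, zeta)
    phasor = (G / (1j * rho * omega)) * prof
    out = np.real(np.multiply.outer(np.exp(1j * omega * np.asarray(t, float)), phasor))
    return out if out.ndim else float(out)


def womersley_wall_shear_amplitude(R, rho, eta, pressure_gradient_amplitude, omega):
    """Amplitude of the analytic wall shear stress tau_w = -eta du/dr|_R.

    du/dr phasor at the wall: (G/(i rho omega)) * (zeta/R) J1(zeta)/J0(zeta).
    """
    G = pressure_gradient_amplitude
    alpha = womersley_number(R, omega, rho, eta)
    zeta = 1j**1.5 * alpha
    dudr = (G / (1j * rho * omega)) * (zeta / R) * jv(1, zeta) / jv(0, zeta)
    return float(np.abs(eta * dudr))


def womersley_flow_rate_amplitude(R, rho, eta, pressure_gradient_amplitude, omega):
    """Amplitude of the volumetric flow rate for the same driving gradient."""
    G = pressure_gradient_amplitude
    alpha = womersley_number(R, omega, rho, eta)
    zeta = 1j**1.5 * alpha
    q = (G / (1j * rho * omega)) * np.pi * R**2 * (1.0 - 2.0 * jv(1, zeta) / (zeta * jv(0, zeta)))
    return float(np.abs(q))


def moens_korteweg_speed(E: float, h: float, rho: float, R: float) -> float:
    """Pulse-wave speed c = sqrt(E h / (2 rho R)) in a thin elastic tube."""
    if min(E, h, rho, R) <= 0:
        raise ValueError("all arguments must be positive")
    return float(np.sqrt(E * h / (2.0 * rho * R)))
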