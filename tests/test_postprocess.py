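"""Cycle reduction, comparison tables, and the analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seepfsi.postprocess import (
    ProbeSeries,
    compare_runs,
    cycle_summary,
    extract_cycle,
    moens_korteweg_speed,
    womersley_flow_rate_amplitude,
    womersley_solution,
    womersley_wall_shear_amplitude,
)

PERIOD = 0.8
DT = 4e-3


def _series(n_cycles=3, f=None):
    n = int(round(n_cycles * PERIOD / DT))
    t = DT * np.arange(n + 1)
    if f is None:
        f = lambda tt: np.sin(2 * np.pi * tt / PERIOD)
    base = f(t)
    data = np.stack([base, 2 * base, 3 * base + 1, 0.5 * base - 2])
    return ProbeSeries(
        time=t, pressure=data, velocity=0.1 * data, wss=0.01 * data,
        sections=["S1", "S2", "S3", "S4"],
        section_positions=np.array([0.05, 0.15, 0.225, 0.275]),
    )


class TestExtractCycle:
    def test_single_cycle_identity(self):
        s = _series(1)
        out = extract_cycle(s, 1, PERIOD)
        assert np.array_equal(out.time, s.time)
        assert np.array_equal(out.pressure, s.pressure)

    def test_extracted_length(self):
        out = extract_cycle(_series(3), 3, PERIOD)
        assert out.pressure.shape[1] == int(PERIOD / DT) + 1  # 200 steps + closing sample

    def test_cycles_partition_series(self):
        s = _series(3)
        parts = [extract_cycle(s, k, PERIOD) for k in (1, 2, 3)]
        # boundary samples shared; concatenating interiors reproduces the series
        rebuilt = np.concatenate(
            [parts[0].pressure] + [p.pressure[:, 1:] for p in parts[1:]], axis=1
        )
        assert np.array_equal(rebuilt, s.pressure)

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError):
            extract_cycle(_series(2), 3, PERIOD)


class TestCycleSummary:
    def test_constant_series(self):
        s = _series(1, f=lambda t: np.ones_like(t))
        summ = cycle_summary(s)
        assert summ.loc["S1", "pressure_amplitude"] == 0.0
        assert summ.loc["S1", "peak_pressure"] == summ.loc["S1", "bottom_pressure"]

    def test_sinusoid_amplitude(self):
        A, m = 3.0, 1.0
        s = _series(1)
        s = ProbeSeries(
            time=s.time,
            pressure=np.tile(A * np.sin(2 * np.pi * s.time / PERIOD) + m, (4, 1)),
            velocity=s.velocity, wss=s.wss, sections=s.sections,
            section_positions=s.section_positions,
        )
        summ = cycle_summary(s)
        assert summ.loc["S2", "pressure_amplitude"] == pytest.approx(2 * A, rel=1e-3)
        assert summ.loc["S2", "peak_pressure"] == pytest.approx(m + A, rel=1e-3)

    def test_extrema_invariant_to_time_shift(self):
        s = _series(1)
        shift = 37
        rolled = ProbeSeries(
            time=s.time,
            pressure=np.roll(s.pressure[:, :-1], shift, axis=1),
            velocity=np.roll(s.velocity[:, :-1], shift, axis=1),
            wss=np.roll(s.wss[:, :-1], shift, axis=1),
            sections=s.sections, section_positions=s.section_positions,
        )
        a = cycle_summary(s)
        # drop the closing sample to compare like with like
        trimmed = ProbeSeries(
            time=s.time[:-1], pressure=s.pressure[:, :-1], velocity=s.velocity[:, :-1],
            wss=s.wss[:, :-1], sections=s.sections, section_positions=s.section_positions,
        )
        b = cycle_summary(rolled)
        c = cycle_summary(trimmed)
        pd.testing.assert_frame_equal(b, c)


class TestCompareRuns:
    def test_identical_runs_zero_delta(self):
        summ = cycle_summary(_series(1))
        out = compare_runs(summ, summ)
        assert np.allclose(out["delta_peak_pressure"], 0.0)
        assert np.allclose(out["ratio_peak_wss"], 1.0)

    def test_antisymmetry(self):
        a = cycle_summary(_series(1))
        b = a * 1.37 + 0.1
        fw = compare_runs(a, b)
        bw = compare_runs(b, a)
        assert np.allclose(fw["delta_peak_velocity"], -bw["delta_peak_velocity"])
        assert np.allclose(fw["ratio_peak_velocity"], 1.0 / bw["ratio_peak_velocity"])

    def test_section_mismatch_raises(self):
        a = cycle_summary(_series(1))
        b = a.iloc[:3]
        with pytest.raises(ValueError):
            compare_runs(a, b)


class TestWomersleyOracle:
    R, RHO, ETA = 0.01, 1050.0, 3.5e-3
    G = 100.0

    def test_no_slip_at_wall(self):
        t = np.linspace(0, 1, 7)
        u = womersley_solution(self.R, self.RHO, self.ETA, self.G, 2 * np.pi, self.R, t)
        assert np.allclose(u, 0.0, atol=1e-14)

    def test_quasi_steady_limit_is_poiseuille(self):
        """alpha < 0.1: profile within 0.1% of the steady parabola."""
        omega = 0.1**2 * self.ETA / (self.RHO * self.R**2)  # alpha = 0.1
        r = np.linspace(0, self.R, 30)
        u = womersley_solution(self.R, self.RHO, self.ETA, self.G, omega, r, 0.0)
        u_pois = self.G / (4 * self.ETA) * (self.R**2 - r**2)
        assert np.allclose(u, u_pois, rtol=2e-3, atol=1e-3 * np.max(u_pois))

    def test_annular_effect_at_high_alpha(self):
        """alpha = 10: centreline amplitude below the quasi-steady value and
        the peak sits off-centre (Richardson annulus)."""
        omega = 10**2 * self.ETA / (self.RHO * self.R**2)
        r = np.linspace(0, self.R, 200)
        t = np.linspace(0, 2 * np.pi / omega, 100, endpoint=False)
        u = womersley_solution(self.R, self.RHO, self.ETA, self.G, omega, r, t)
        amp = np.max(np.abs(u), axis=0)
        quasi_steady_centre = self.G * self.R**2 / (4 * self.ETA)
        assert amp[0] < quasi_steady_centre
        assert np.argmax(amp) > 0  # off-axis maximum

    def test_wall_shear_amplitude_vs_numerical_derivative(self):
        omega = 2 * np.pi / PERIOD
        amp = womersley_wall_shear_amplitude(self.R, self.RHO, self.ETA, self.G, omega)
        # numerical: differentiate the profile near the wall over a period
        r = np.array([self.R - 1e-6, self.R])
        t = np.linspace(0, PERIOD, 400, endpoint=False)
        u = womersley_solution(self.R, self.RHO, self.ETA, self.G, omega, r, t)
        tau_t = -self.ETA * (u[:, 1] - u[:, 0]) / 1e-6
        assert np.max(np.abs(tau_t)) == pytest.approx(amp, rel=1e-3)

    def test_flow_rate_amplitude_vs_quadrature(self):
        omega = 2 * np.pi / PERIOD
        amp = womersley_flow_rate_amplitude(self.R, self.RHO, self.ETA, self.G, omega)
        r = np.linspace(0, self.R, 4000)
        t = np.linspace(0, PERIOD, 200, endpoint=False)
        u = womersley_solution(self.R, self.RHO, self.ETA, self.G, omega, r, t)
        q_t = np.trapezoid(2 * np.pi * r * u, r, axis=1)
        assert np.max(np.abs(q_t)) == pytest.approx(amp, rel=1e-3)

    def test_r_beyond_wall_rejected(self):
        with pytest.raises(ValueError):
            womersley_solution(self.R, self.RHO, self.ETA, self.G, 1.0, 2 * self.R, 0.0)


class TestMoensKorteweg:
    def test_reference_value(self):
        assert moens_korteweg_speed(5e6, 0.002, 1050.0, 0.01) == pytest.approx(21.8, rel=1e-3)

    def test_quadrupling_E_doubles_speed(self):
        c1 = moens_korteweg_speed(1e6, 0.002, 1050.0, 0.01)
        c2 = moens_korteweg_speed(4e6, 0.002, 1050.0, 0.01)
        assert c2 == pytest.approx(2 * c1)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            moens_korteweg_speed(-1.0, 0.002, 1050.0, 0.01)

    def test_pulse_transit_time_matches_wave_speed(self):
        """A short inflow pulse launches a wall wave whose crest transit
        between two artery stations matches sqrt(Eh/2 rho R) within 15%.

        The crest is tracked on the wall *velocity*: incompressible FSI
        also carries an instantaneous elliptic pressure component, and the
        wall-velocity crest isolates the propagating part.  The terminal
        resistance is opened wide so the outlet is nearly reflection-free
        over the measurement window.
        """
        from seepfsi.constitutive import PorousParams, RheologyParams
        from seepfsi.driver import CouplingConfig, step_coupled
        from seepfsi.fluid import FluidState, SolverConfig
        from seepfsi.geometry import GeometryConfig, build_mesh
        from seepfsi.wall import WallParams, WallState
        from seepfsi.waveform import WaveformConfig, generate_waveform, sample

        E = 1e6
        dt = 2.5e-4
        geom = GeometryConfig(artery_length=0.4, micro_length=0.1)
        mesh0 = build_mesh(geom, 200, 10)
        rheo = RheologyParams()
        porous = PorousParams(area_expansion=1e8)
        wallp = WallParams(youngs_modulus=E)
        solver = SolverConfig(dt=dt, newtonian_override=1e-3)
        coup = CouplingConfig()
        wave = generate_waveform(
            WaveformConfig(peak_velocity=0.3, diastolic_velocity=0.0, systolic_fraction=0.0125)
        )
        fluid = FluidState.zeros(mesh0)
        wall = WallState.zeros(mesh0.n_artery)
        mesh = mesh0
        zc = mesh0.z_centers[mesh0.artery_cells]
        n_steps = 160
        V = np.zeros((n_steps, mesh0.n_artery))
        for n in range(n_steps):
            t = (n + 1) * dt
            fluid, wall, mesh, _ = step_coupled(
                fluid, wall, mesh, mesh0, sample(wave, t), rheo, porous, wallp, solver, coup
            )
            V[n] = wall.velocity

        def crest_arrival(z):
            i = int(np.argmin(np.abs(zc - z)))
            s = V[:, i]
            k = min(max(int(np.argmax(s)), 1), n_steps - 2)
            den = s[k - 1] - 2 * s[k] + s[k + 1]
            frac = 0.5 * (s[k - 1] - s[k + 1]) / den if den != 0 else 0.0
            return (k + frac) * dt

        transit = crest_arrival(0.30) - crest_arrival(0.12)
        c_meas = 0.18 / transit
        c_mk = moens_korteweg_speed(E, wallp.thickness, rheo.rho_fluid, wallp.reference_radius)
        assert c_meas == pytest.approx(c_mk, rel=0.15)
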