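"""Shared fixtures.

The expensive multi-cycle simulations are session-scoped and lazy: only
tests that request them trigger the runs, and every test sharing a fixture
reuses the same RunResult.  The "baseline" pair is the calibrated study
configuration (terminal resistance tuned so the rigid-wall cycle-maximum
artery pressure is 1200 Pa; inlet waveform tuned so the compliant S1 peak
sectional velocity is 0.75 m/s).
"""

import numpy as np
import pytest

from seepfsi.calibrate import calibrate_terminal_resistance, calibrate_waveform_peak
from seepfsi.constitutive import PorousParams, RheologyParams
from seepfsi.driver import CouplingConfig, run_simulation
from seepfsi.fluid import SolverConfig
from seepfsi.geometry import GeometryConfig
from seepfsi.wall import WallParams
from seepfsi.waveform import WaveformConfig

BASE_NZ, BASE_NR = 150, 24
RIGID_PMAX_TARGET = 1200.0  # Pa, rigid-wall cycle maximum
S1_PEAK_VELOCITY_TARGET = 0.75  # m/s


@pytest.fixture(scope="session")
def calibrated_setup():
    """Terminal resistance + waveform calibration shared by the heavy runs."""
    porous, info = calibrate_terminal_resistance(
        RIGID_PMAX_TARGET, nz=BASE_NZ, nr=BASE_NR
    )

    def measure(wcfg):
        res = run_simulation(
            waveform_config=wcfg, porous=porous, wall_params=WallParams(),
            nz=BASE_NZ, nr=BASE_NR,
        )
        measure.last_result = res
        return float(res.analysis_summary().loc["S1", "peak_velocity"])

    wcfg, measured = calibrate_waveform_peak(
        S1_PEAK_VELOCITY_TARGET, WaveformConfig(), measure
    )
    return {
        "porous": porous,
        "waveform": wcfg,
        "calibration_info": info,
        "compliant": measure.last_result,
        "s1_peak_velocity": measured,
    }


@pytest.fixture(scope="session")
def baseline_compliant(calibrated_setup):
    return calibrated_setup["compliant"]


@pytest.fixture(scope="session")
def baseline_rigid(calibrated_setup):
    return run_simulation(
        waveform_config=calibrated_setup["waveform"],
        porous=calibrated_setup["porous"],
        wall_params=WallParams(rigid=True),
        nz=BASE_NZ,
        nr=BASE_NR,
    )


@pytest.fixture(scope="session")
def sensitivity_results(calibrated_setup):
    """Peak WSS at S1/S2 for E in {5, 4, 2.5, 1} MPa (baseline conditions)."""
    from seepfsi.driver import sensitivity_sweep

    return sensitivity_sweep(
        [5e6, 4e6, 2.5e6, 1e6],
        waveform_config=calibrated_setup["waveform"],
        porous=calibrated_setup["porous"],
        nz=BASE_NZ,
        nr=BASE_NR,
    )
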