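"""Parametric inlet velocity waveform.

The inlet forcing is a periodic systolic pulse: a squared half-sine of
height ``peak_velocity`` riding on a diastolic baseline, occupying the first
``systolic_fraction`` of each cardiac period,

    u(t) = u_dia + (u_peak - u_dia) * sin^2(pi t / (sf*T))   for t in systole
    u(t) = u_dia                                             in diastole.

The generator is a calibrated stand-in for a measured aortic velocity trace:
its peak is a config value tuned so the simulated near-inlet peak sectional
velocity matches a target (0.75 m/s by default).  A digitized trace can be
substituted through the two-column CSV import.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WaveformConfig", "Waveform", "generate_waveform", "sample"]


@dataclass(frozen=True)
class WaveformConfig:
    period: float = 0.8  # s
    peak_velocity: float = 0.75  # m/s
    diastolic_velocity: float = 0.05  # m/s
    systolic_fraction: float = 0.4
    profile_shape: str = "half_sine_squared"  # or "fourier"
    n_samples: int = 800  # samples per period in the dense table

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not (self.peak_velocity > self.diastolic_velocity >= 0):
            raise ValueError("require peak_velocity > diastolic_velocity >= 0")
        if not (0 < self.systolic_fraction < 1):
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.profile_shape not in ("half_sine_squared", "fourier"):
            raise ValueError("unknown profile_shape %r" % (self.profile_shape,))
        if self.n_samples < 16:
            raise ValueError("n_samples too small")


@dataclass
class Waveform:
    """Dense one-period table of inlet mean velocity, plus its config.

    Generated waveforms carry their closed form (``analytic``) and sample
    it exactly; imported traces interpolate the table linearly.
    """

    times: np.ndarray  # (n+1,), 0 .. period inclusive
    values: np.ndarray  # (n+1,), values[0] == values[-1]
    config: WaveformConfig
    analytic: object = None  # optional callable t -> velocity

    @property
    def period(self) -> float:
        return self.config.period

    def __call__(self, t):
        return sample(self, t)

    def mean(self) -> float:
        """Cycle-mean velocity by trapezoidal quadrature."""
        return float(np.trapezoid(self.values, self.times) / self.period)

    def to_csv(self, path_or_buf):
        data = np.column_stack([self.times, self.values])
        header = "time_s,velocity_m_per_s"
        if hasattr(path_or_buf, "write"):
            np.savetxt(path_or_buf, data, delimiter=",", header=header, comments="")
        else:
            np.savetxt(str(path_or_buf), data, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path_or_buf, period: float | None = None) -> "Waveform":
        """Load a (time, velocity) table; the trace must span one period."""
        data = np.loadtxt(path_or_buf, delimiter=",", skiprows=1)
        t, u = data[:, 0], data[:, 1]
        if period is None:
            period = float(t[-1] - t[0])
        t = t - t[0]
        if not np.isclose(u[0], u[-1], rtol=1e-3, atol=1e-9 + 1e-3 * np.max(np.abs(u))):
            raise ValueError("imported waveform is not periodic (endpoints differ)")
        cfg = WaveformConfig(
            period=period,
            peak_velocity=float(np.max(u)),
            diastolic_velocity=float(max(np.min(u), 0.0)),
            n_samples=max(len(t) - 1, 16),
        )
        return cls(times=t, values=u.copy(), config=cfg)


def _analytic(cfg: WaveformConfig, t: np.ndarray) -> np.ndarray:
    tau = np.mod(t, cfg.period)
    ts = cfg.systolic_fraction * cfg.period
    u = np.full_like(tau, cfg.diastolic_velocity, dtype=float)
    sys = tau < ts
    u[sys] = cfg.diastolic_velocity + (cfg.peak_velocity - cfg.diastolic_velocity) * np.sin(
        np.pi * tau[sys] / ts
    ) ** 2
    return u


def _fourier(cfg: WaveformConfig, t: np.ndarray) -> np.ndarray:
    # Smooth strictly-periodic alternative: a von-Mises-like bump centred
    # mid-systole, rescaled to hit the configured peak and baseline exactly.
    tau = np.mod(t, cfg.period)
    x = 2 * np.pi * tau / cfg.period
    centre = np.pi * cfg.systolic_fraction
    bump = np.exp(3.0 * (np.cos(x - centre) - 1.0))
    lo = np.exp(-6.0)  # analytic extrema of the bump over one period
    bump = (bump - lo) / (1.0 - lo)
    return cfg.diastolic_velocity + (cfg.peak_velocity - cfg.diastolic_velocity) * bump


def generate_waveform(config: WaveformConfig) -> Waveform:
    """Tabulate one period of the configured waveform.

    The returned table is periodic (first and last samples equal) and dense
    enough that linear interpolation is converged beyond ~400 points/period.
    """
    t = np.linspace(0.0, config.period, config.n_samples + 1)
    if config.profile_shape == "half_sine_squared":
        fn = _analytic
    else:
        fn = _fourier
    u = fn(config, t)
    u[-1] = u[0]
    return Waveform(times=t, values=u, config=config, analytic=lambda tt: fn(config, tt))


def sample(waveform: Waveform, t):
    """Periodic evaluation of the waveform at time(s) t >= 0.

    Generated waveforms evaluate their closed form exactly; imported
    tables are linearly interpolated (C0).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    tau = np.mod(t_arr, waveform.period)
    if waveform.analytic is not None:
        out = waveform.analytic(np.atleast_1d(tau))
        out = out.reshape(tau.shape) if tau.ndim else out[0]
        return float(out) if np.ndim(out) == 0 else out
    out = np.interp(tau, waveform.times, waveform.values)
    return float(out) if out.ndim == 0 else out
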