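"""Scalar constitutive laws for blood and the porous microcirculation bed.

Blood is shear-thinning; the Carreau–Yasuda law interpolates between the
zero-shear viscosity ``eta_0`` and the infinite-shear viscosity ``eta_inf``

    eta(gd) = eta_inf + (eta_0 - eta_inf) * [1 + (lambda*gd)^a]^((n-1)/a)

with relaxation time ``lambda`` and exponents ``a`` and ``n``.  The
microcirculation zone is treated as a porous continuum whose permeability
follows the Kozeny–Carman relation

    k = d^2 phi^3 / (180 (1 - phi)^2)

for porosity ``phi`` and microvessel diameter ``d``; the momentum sink added
to the Navier–Stokes equations inside the porous zone is the Brinkman/Darcy
drag ``-(phi^2 eta / k) u`` on the intrinsic (pore-average) velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RheologyParams",
    "PorousParams",
    "carreau_yasuda_viscosity",
    "shear_rate_magnitude",
    "kozeny_carman_permeability",
    "brinkman_sink_coefficient",
]


@dataclass(frozen=True)
class RheologyParams:
    """Carreau–Yasuda constants plus the fluid density.

    Defaults are the standard blood values: eta_inf = 2.2 mPa.s,
    eta_0 = 22 mPa.s, lambda = 0.110 s, a = 0.644, n = 0.392,
    rho = 1050 kg/m^3.
    """

    eta_inf: float = 2.2e-3  # Pa.s
    eta_0: float = 22e-3  # Pa.s
    lambda_relax: float = 0.110  # s
    a_exp: float = 0.644
    n_exp: float = 0.392
    rho_fluid: float = 1050.0  # kg/m^3

    def __post_init__(self):
        if not (self.eta_0 > self.eta_inf > 0):
            raise ValueError("require eta_0 > eta_inf > 0")
        if self.lambda_relax <= 0:
            raise ValueError("lambda_relax must be positive")
        if self.a_exp <= 0:
            raise ValueError("a_exp must be positive")
        if not (0 < self.n_exp <= 1):
            raise ValueError("n_exp must lie in (0, 1]")
        if self.rho_fluid <= 0:
            raise ValueError("rho_fluid must be positive")


@dataclass(frozen=True)
class PorousParams:
    """Porous-zone parameters.

    ``permeability`` defaults to the Kozeny–Carman value for
    (``microvessel_diameter``, ``porosity``); pass an explicit value to
    override it (terminal-resistance calibration).  ``area_expansion`` is the
    effective cross-section of the microcirculation bed relative to the
    artery lumen (a capillary bed has a vastly larger total cross-section
    than the feeding artery); it scales the flux area of the porous zone so
    a physiological terminal resistance and near-zero seepage velocities can
    coexist with strict mass conservation.
    """

    porosity: float = 0.5
    microvessel_diameter: float = 8e-6  # m
    permeability: float | None = None  # m^2; None -> Kozeny-Carman
    area_expansion: float = 1.0

    def __post_init__(self):
        # phi = 1 (plain fluid) is allowed only with an explicit
        # permeability, since the Kozeny-Carman relation is singular there.
        if not (0 < self.porosity < 1) and not (
            self.porosity == 1.0 and self.permeability is not None
        ):
            raise ValueError("porosity must lie in (0, 1), or be 1 with an "
                             "explicit permeability override")
        if self.microvessel_diameter <= 0:
            raise ValueError("microvessel_diameter must be positive")
        if self.area_expansion < 1:
            raise ValueError("area_expansion must be >= 1")
        if self.permeability is None:
            object.__setattr__(
                self,
                "permeability",
                kozeny_carman_permeability(self.microvessel_diameter, self.porosity),
            )
        elif self.permeability <= 0:
            raise ValueError("permeability must be positive")

    @property
    def flux_area_fraction(self) -> float:
        """phi * area_expansion: superficial flux area per unit artery area."""
        return self.porosity * self.area_expansion


def carreau_yasuda_viscosity(gamma_dot, params: RheologyParams):
    """Carreau–Yasuda viscosity eta(gamma_dot), Pa.s.

    Accepts scalars or arrays; ``gamma_dot`` must be non-negative.
    The result lies in (eta_inf, eta_0].
    """
    gd = np.asarray(gamma_dot, dtype=float)
    if np.any(gd < 0):
        raise ValueError("gamma_dot must be non-negative")
    x = (params.lambda_relax * gd) ** params.a_exp
    eta = params.eta_inf + (params.eta_0 - params.eta_inf) * (1.0 + x) ** (
        (params.n_exp - 1.0) / params.a_exp
    )
    if np.isscalar(gamma_dot):
        return float(eta)
    return eta


def shear_rate_magnitude(dudz, dudr, dvdz, dvdr, v_over_r):
    """Scalar shear rate gd = sqrt(2 D:D) for an axisymmetric velocity field.

    Arguments are the strain components du_z/dz, du_z/dr, du_r/dz, du_r/dr
    and the hoop term u_r/r (all 1/s, scalar or array, broadcastable).
    D is the symmetric part of the velocity gradient; in axisymmetric
    coordinates D:D = Dzz^2 + Drr^2 + Dtt^2 + 2 Dzr^2 with Dtt = u_r/r.
    """
    arrs = [np.asarray(a, dtype=float) for a in (dudz, dudr, dvdz, dvdr, v_over_r)]
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("velocity-gradient components must be finite")
    dudz, dudr, dvdz, dvdr, v_over_r = arrs
    dzr = 0.5 * (dudr + dvdz)
    dd = dudz**2 + dvdr**2 + v_over_r**2 + 2.0 * dzr**2
    out = np.sqrt(2.0 * dd)
    return float(out) if out.ndim == 0 else out


def kozeny_carman_permeability(d: float, phi: float) -> float:
    """Kozeny–Carman permeability k = d^2 phi^3 / (180 (1-phi)^2), m^2."""
    if not (0 < phi < 1):
        raise ValueError("phi must lie in (0, 1)")
    if d <= 0:
        raise ValueError("d must be positive")
    return d * d * phi**3 / (180.0 * (1.0 - phi) ** 2)


def brinkman_sink_coefficient(phi: float, eta, k: float):
    """Brinkman drag coefficient phi^2 eta / k (Pa.s/m^2).

    Multiplies the intrinsic velocity in the porous-zone momentum sink.
    ``eta`` may be an array (local-viscosity evaluation).
    """
    if not (0 < phi <= 1):
        raise ValueError("phi must lie in (0, 1]")
    if k <= 0:
        raise ValueError("permeability must be positive")
    if np.any(np.asarray(eta) <= 0):
        raise ValueError("viscosity must be positive")
    return phi * phi * np.asarray(eta) / k if not np.isscalar(eta) else phi * phi * eta / k
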