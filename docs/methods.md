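# Methods

`seepfsi` simulates pulsatile flow in a straight compliant artery whose
outlet is terminated by a porous continuum standing in for the
microcirculation, and reports per-section pressure, sectional peak
velocity, wall shear stress (WSS) and their cycle extrema.  This note
records the model, its assumptions, the numerical choices, the two
calibrations, and — importantly — what the reduced model can and cannot
reproduce of the reference three-dimensional commercial-solver study it
is scaled down from.

## Geometry and fields

The domain is a straight tube of lumen radius R = 10 mm in axisymmetric
(r, z) coordinates: an elastic artery zone (default length 10 D = 0.2 m)
followed by a rigid porous microcirculation zone (default 5 D = 0.1 m).
Probe sections S1/S2 sit at 25%/75% of the artery zone and S3/S4 at
25%/75% of the porous zone.  The zone lengths and section positions are
not constrained by first principles; the defaults are configuration
values chosen once (artery long enough for entrance effects to decay
between sections, porous zone long enough to act as a distributed
resistance).

Flow is axisymmetric and swirl-free; gravity is neglected; blood density
is 1050 kg/m^3.  The hoop coordinate carries no flow, so the
three-dimensional straight-tube problem reduces exactly to (r, z) — this
is a reduction of cost, not of physics, for this geometry.

## Fluid

Artery zone: incompressible Navier–Stokes in ALE form (convection by
u − u_m, with u_m the mesh velocity) and the Carreau–Yasuda viscosity

    eta(gd) = eta_inf + (eta_0 − eta_inf) [1 + (lambda gd)^a]^((n−1)/a),

with eta_inf = 2.2 mPa·s, eta_0 = 22 mPa·s, lambda = 0.110 s, a = 0.644,
n = 0.392, and gd = sqrt(2 D:D) the second-invariant shear rate
(including the axisymmetric hoop component u_r/r; the scalar-shear-rate
convention is the one used by general-purpose CFD codes and the
rheological literature).

Microcirculation zone: volume-averaged momentum with constant porosity
phi = 0.5 and the Brinkman sink −(phi^2 eta / k) u on the intrinsic
velocity, permeability from Kozeny–Carman with microvessel diameter
d = 8 um (k ≈ 1.78e-13 m^2).  Dividing by the constant phi puts both
zones in one discretisation; zone differences enter only through the
superficial flux-area fraction beta(z) (1 in the artery,
phi·area_expansion in the porous zone) in the continuity equation
div(beta u) = 0, and the sink s(z).  The viscosity in the sink is
evaluated at the local shear rate by default (hence ~eta_0 in the
near-stagnant porous interior); a constant eta_inf option exists.

`area_expansion` is the effective cross-section of the microvascular bed
relative to the artery lumen.  It is essential: with the Kozeny–Carman
permeability of an 8-um bed, strict mass conservation in a
uniform-cross-section tube would force arterial-scale superficial
velocities through the pores and pressure drops of order 1e8–1e9 Pa.  A
real capillary bed carries the same flow through a total cross-section
several orders of magnitude larger than the feeding artery.
`area_expansion` (equivalently, a permeability override) is therefore the
terminal-resistance calibration knob; see "Calibrations".

Boundary conditions: prescribed inlet axial velocity (plug profile by
default — pulsatile arterial flow at Womersley number ~13–19 is
plug-like; a parabolic option exists and is used by the steady
verification runs), p = 0 at the porous outlet, no-slip at walls (the
structural velocity in the artery zone, zero in the rigid porous zone),
symmetry on the axis.  Initial state: rest; three cardiac cycles are run
and the third is analysed, which removes the start-up transient from the
reported quantities.

## Wall

The isotropic linear-elastic wall (rho_w = 1120 kg/m^3, E = 5 MPa,
nu = 0.499, h = 2 mm) is reduced to independent inertial rings per axial
station:

    rho_w h d'' + c d' + kappa d = p_wall − p_ext,
    kappa = E h / ((1 − nu^2) R^2) ≈ 1.33e8 Pa/m,

with both artery-zone ends clamped (d = 0).  Axial wall displacement,
bending and axial tension are neglected — defensible for radius-dominated
motion of a straight clamped tube.  The reduction error against the
plane-strain thick-tube (Lame) solution at h/R = 0.2 is ~8% when the ring
is written with the mid-surface radius and ~24% with the lumen-radius
convention used for kappa above; both are documented by a test and are
small against the study's dominant uncertainties.  Structural damping c
defaults to zero; runs that need a static limit enable it explicitly and
the parameter is logged on use.

Time integration is Newmark.  The default pair (gamma = 0.6,
beta = (gamma + 1/2)^2/4) adds slight high-frequency dissipation: the
ring natural frequency (7.7e3 rad/s) is far above the cardiac time step
(omega_n dt ≈ 31), and the energy-conserving trapezoidal pair would carry
a persistent ±Nyquist ringing into the wall-velocity boundary condition.
The trapezoidal pair (0.25, 0.5) is available and is what the
ring-resolved tests (free-oscillation frequency, energy conservation)
use.

## Discretisation

MAC staggered finite volumes in mapped coordinates (z, xi = r/R_w(z,t)):
the grid follows the wall by pure radial scaling, the ALE mesh velocity
is xi·dR_w/dt, and metric terms proportional to dR_w/dz (wall slopes
~1e-4) are neglected.  BDF2 in time (backward Euler for the first step).
Each step is linearly implicit: viscosity, convection coefficients, the
MUSCL deferred correction and the sink are frozen at the extrapolated (or
FSI warm-start) state; first-order upwind convection and the
own-component viscous terms are implicit; transposed-gradient viscous
terms are explicit at the frozen state.  Convective fluxes use van-Leer
limited MUSCL as the "high-resolution" default with plain first-order
upwind as an option.  The wall viscous flux and the WSS both use a
one-sided three-point quadratic gradient (exact for a parabola — the
steady Poiseuille solution is a discrete fixed point to round-off).

Pressure–velocity coupling is an incremental pressure correction whose
mobility includes the sink diagonal, m = 1/(rho c0/dt + s): the corrected
field is exactly divergence-free for any mobility, and the sink-aware
choice makes pressure converge as fast in the porous zone as in the open
lumen.  Inner iterations repeat momentum + correction until the relative
field change is below `residual_tol` (1e-4 by default; the FSI driver
tightens it to 1e-6 inside sub-iterations because the interface loop
differentiates tractions and amplifies solver noise through the fluid
column's inertance).  All linear systems are direct banded LU solves,
factored once per step and reused across the inner iterations.  An
advective CFL above 1 logs a warning (accuracy, not stability: the
transport operator is implicit).

## Partitioned coupling

Per time step: fluid solve → wall traction (p − 2 eta dv/dr at the wall)
→ ring update → interface-displacement update → mesh deform → repeat,
until the relative interface-displacement change is below 1e-4 (the
field-residual threshold reused for the interface, a documented
assumption).  The no-slip wall velocity handed to the fluid is the
Newmark-consistent structural velocity, and one final fluid solve with
the converged wall state makes the discrete kinematic interface condition
hold exactly on exit.

The interface update is accelerated by an Anderson/IQN-type least-squares
scheme over the step's sub-iteration history (with column normalisation
and rcond filtering; updates are capped so added-mass overshoot in the
first sub-iterations cannot leave the physical regime).  Scalar Aitken
and fixed-omega relaxation remain as options, but against the added mass
of an incompressible liquid column (interface gain ~ −20 at the baseline,
growing as dt shrinks) Aitken needs several times more sub-iterations and
plain fixed omega = 0.5 diverges outright; the least-squares default
converges in 3–6.  The fluid linearisation is frozen once per step so the
interface map the accelerator sees is a single affine operator.

Rigid mode (the comparison baseline) performs exactly one fluid solve per
step and never touches wall or mesh; a compliant run at E = 5 GPa
reproduces it to <1% over the analysis cycle, which ties the two code
paths together.

## Inlet waveform

The measured inlet trace of the reference study is available only as a
figure, so the generator is an explicit parametric stand-in: a squared
half-sine systolic pulse over the first 40% of the 0.8-s period on a
0.05 m/s diastolic baseline.  Its peak is a calibration target (below),
not a hidden constant; a digitised trace can be substituted through the
two-column CSV import.  Generated waveforms are sampled from their closed
form, so the sampling density plays no role.

## Calibrations (the only two tuned quantities)

1. Terminal resistance: `area_expansion` is set so the rigid-wall run's
   cycle-maximum artery pressure equals 1200 Pa, the rigid-wall reference
   value.  A closed-form Darcy estimate seeds a 1–2 step secant iteration
   on full rigid runs.  At the calibrated point (area_expansion ~1.3e8)
   the outlet is resistively almost open and the arterial pressure maxima
   are dominated by the fluid column's inertia (~1.1 kPa); porous
   velocities are ~1e-8 m/s, matching the near-steady seepage picture.
2. Inlet peak: the generator's `peak_velocity` is scaled so the compliant
   baseline's S1 peak sectional velocity is 0.75 m/s (one measurement
   run; with a plug inlet the map is close to identity).

Both calibrations are logged and echoed in run provenance.  Nothing else
is tuned.

## What the reduced model reproduces, and what it cannot

The analytic verification suite is the binding evidence that the solver
is right: Poiseuille WSS to round-off, Womersley profiles and wall-shear
amplitudes to <2% at Womersley numbers 6–19 with observed spatial order
~1.8–2, the Darcy limit to <1%, static FSI inflation to <1%, pulse
transit at the Moens–Korteweg speed to ~11%, stiff-limit equivalence,
and exact discrete mass conservation.

On the calibrated baseline the model reproduces the reference study's
*headline* contrast: with a seepage outlet, wall compliance raises both
the peak WSS (at S1 and S2) and the peak pressure relative to the rigid
wall, and peak WSS grows monotonically as E decreases — the opposite sign
to the classical prescribed-outlet result.  It also reproduces the
monotone pressure decay along the porous zone, near-steady porous
velocities, and the S1→S2 decrease of peak WSS.

Several of the reference study's reported magnitudes and orderings are
*not* reproduced, and the model says why:

- Effect sizes.  With E = 5 MPa and h = 2 mm, the wall stores only
  ~0.3% of the lumen area per kPa (kappa ≈ 1.33e8 Pa/m) and the
  Moens–Korteweg wavelength (c T ≈ 17 m) is two orders larger than the
  0.3-m domain: the tube is acoustically compact, so compliant-vs-rigid
  contrasts are sub-percent (ratios ~1.001–1.005), not the reported
  ~2x pressure contrast (2200 vs 1200 Pa).  A compact elastic tube with
  these printed properties cannot produce that contrast; whatever
  produced it in the 3D commercial setup (domain length, outlet closure,
  coupling details) is not recoverable from the printed parameters.
- Axial orderings driven by wave reflection.  In the compact limit the
  inertial pressure component is largest near the inlet, so peak
  pressure and pressure amplitude *decrease* from S1 to S2, and the
  porous-zone pressure amplitude scales with distance-to-outlet rather
  than staying constant; the reported opposite orderings would require a
  non-compact domain (many metres at this stiffness) or a much softer
  wall.
- Peak sectional velocity.  With a plug inlet, boundary-layer growth
  forces a core overshoot that increases downstream, so the S2 sectional
  maximum slightly exceeds S1 (0.89 vs 0.85 m/s) instead of dropping to
  0.45 m/s; a 40% drop between sections of a quasi-rigid tube is
  incompatible with mass conservation.
- Absolute WSS peaks.  The oscillatory boundary layer at these Womersley
  numbers gives peak WSS ~3.7 Pa at both sections for a 0.75 m/s peak
  velocity (the Stokes-layer estimate eta U / sqrt(nu T_sys) reproduces
  this scale), above the reported 2.1/1.0 Pa.

The acceptance script reports the calibrated-baseline values as computed;
the test suite marks the unreachable comparisons red rather than
adjusting the model toward them.

## Problem sizes and costs

Baseline runs use 150 x 24 cells and dt = 4 ms (600 steps for three
cycles): ~10 s rigid and ~40 s compliant on one CPU.  Verification runs
use 24–64 radial cells as each comparison requires (e.g. 64 across the
thin Stokes layer at Womersley number 19).  These resolutions put the
discretisation error well below the model-form uncertainties discussed
above.

## Known limitations

Axisymmetric straight tube only (no curvature, taper, branching);
independent-ring wall (no axial coupling, bending, viscoelasticity or
anisotropy); linear elasticity at physiological strains; single Fourier
outlet closure p = 0 behind the porous zone; no turbulence model (peak
Reynolds ~3600, transitional at most, treated as laminar); the inlet
waveform is a parametric stand-in.
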