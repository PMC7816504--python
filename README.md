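# seepfsi

Pulsatile blood flow in a compliant artery whose downstream
microcirculation is represented by a porous ("seepage") outlet zone,
solved by a desk-scale axisymmetric fluid–structure interaction (FSI)
code.

## The problem

Hemodynamic simulations usually truncate the arterial tree with a
prescribed outlet pressure or velocity.  Such closures misrepresent the
dominant resistance of the real circulation — the microvascular bed — and
they change the answer to a clinically loaded question: does wall
compliance raise or lower wall shear stress (WSS), the quantity whose
*low* values are associated with atherogenesis?  `seepfsi` couples

- the incompressible Navier–Stokes equations in arbitrary
  Lagrangian–Eulerian (ALE) form on a moving axisymmetric grid, with the
  shear-thinning Carreau–Yasuda viscosity
  `eta(g) = eta_inf + (eta_0 - eta_inf) [1 + (lambda g)^a]^((n-1)/a)`,
- an elastic arterial wall, reduced to an inertial thick-ring
  (generalized-string) model per axial station,
  `rho_w h d'' + c d' + kappa d = p_wall`, with hoop stiffness
  `kappa = E h / ((1 - nu^2) R^2)`,
- a volume-averaged porous zone appended at the outlet
  (Darcy–Brinkman momentum sink `-(phi^2 eta / k) u`, Kozeny–Carman
  permeability `k = d^2 phi^3 / (180 (1 - phi)^2)`),

with a partitioned staggered coupling (IQN/Anderson-accelerated interface
sub-iterations) and BDF2 time integration.  Parameters default to a
20-mm-diameter vessel with a 2-mm wall (E = 5 MPa, nu = 0.499), blood
rheology, a 0.8-s cardiac period and a 4-ms time step; simulations run
three cycles from rest and analyse the third.

It is a research/teaching tool for people who want a transparent,
fully-scriptable reference implementation of the seepage-outlet FSI
configuration — not a clinical solver.

## Worked example

```python
from seepfsi import PorousParams, WallParams, run_simulation, compare_runs

porous = PorousParams(area_expansion=1.3e8)   # calibrated terminal resistance
compliant = run_simulation(porous=porous, nz=150, nr=24)
rigid = run_simulation(porous=porous, wall_params=WallParams(rigid=True),
                       nz=150, nr=24)
print(compliant.analysis_summary().round(3))
print(compare_runs(compliant.analysis_summary(), rigid.analysis_summary())
      [["ratio_peak_wss", "ratio_peak_pressure"]].round(4))
```

prints (third analysed cycle, sections S1/S2 in the artery, S3/S4 in the
porous zone):

```
    peak_pressure  bottom_pressure  pressure_amplitude  peak_velocity  peak_wss
S1       1273.267        -1106.572            2379.840          0.849     4.191
S2        460.397         -349.983             810.381          0.891     4.176
S3         53.803            3.261              50.542          0.000     0.000
S4         17.934            1.087              16.847          0.000     0.000

    ratio_peak_wss  ratio_peak_pressure
S1          1.0015               1.0316
S2          1.0051               1.0468
S3          1.0048               1.0048
S4          1.0048               1.0048
```

Reading the numbers: peak pressure and its amplitude fall toward the
porous outlet (the seepage zone carries a near-steady trickle — peak
porous velocities are ~1e-8 m/s, eight orders below the arterial
0.85 m/s); peak WSS is a few Pa and decreases slightly from S1 to S2;
and with the seepage outlet the compliant wall shows *higher* peak WSS
and pressure than the rigid wall (ratios > 1) — opposite to the classical
prescribed-pressure-outlet result that compliance lowers WSS.

A CLI wraps the same library (`seepfsi run | sweep | compare | validate`,
YAML config, CSV/VTK output); `seepfsi validate` replays quick
closed-form checks (Poiseuille WSS, Darcy seepage, static inflation).

## Verification

The solver is tested against closed forms end to end: steady Poiseuille
WSS (`4 eta U / R`, exact to round-off on the staggered grid), the
oscillatory Womersley solution at Womersley numbers ~6–19 (velocity
profile and wall-shear amplitude to <2%, observed spatial order ~1.8–2),
the Darcy limit of the porous zone (<1%), static FSI inflation against
`p/kappa` (<1%), ring natural frequency and energy conservation,
Moens–Korteweg pulse transit, stiff-limit equivalence with the rigid
solver, and discrete mass conservation.  See `docs/methods.md` for the
model's assumptions and known limitations.

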