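# Methods

## Model and assumptions

The package implements a deterministic, well-mixed, four-compartment
model of the interaction between a criminal organization and the
judiciary. The state (G, J, C, P) collects the densities of gang
members, non-corrupt judges, corrupt judges and prisoners, in persons
per area unit:

```
dG/dt = αG(σ − G) − δGJ + βP
dJ/dt = γ − ηJ − ρGJ
dC/dt = ρGJ − φCJ
dP/dt = δGJ + φCJ − κP
```

Assumptions built into this structure: gang recruitment is logistic
(self-limited at the carrying capacity σ); incarceration of gang
members (δ) and of corrupt judges (φ), and co-optation of judges (ρ),
are mass-action contact processes; the judiciary has a constant intake
γ and exponential attrition η with no crowding term (judges act
individually); corrupt judges convict no one; prisoners leave prison at
rate κ and a fraction rejoins the gang at rate β, constrained by
β ≤ κ. All nine constants are positive except ρ and β, which may be
exactly zero — those zeros are structural switches, not small numbers,
and select one of four analysis cases (1: ρ=β=0, 2: ρ=0<β,
3: β=0<ρ, 4: both positive). Near-zero values deliberately do *not*
round to a different case.

## Equilibria and thresholds

The crime-free state E0 = (0, γ/η, 0, 0) exists always. The endemic
states are closed-form:

* cases 1–2 (no corruption): G* is linear in R0 = αησ/(γδ), with the
  recidivism shift β/κ in case 2; at β = κ the endemic gang density
  equals σ exactly, so total recidivism defeats even an honest
  judiciary.
* cases 3–4 (corruption): G* solves AG² + BG + const = 0 with
  A = αρ/(γδ) > 0, B = α(η − ρσ)/(γδ), and constant term D = 1 − R0
  (case 3) or H = 1 − R0 − (β/κ)(1 + ρ/δ) (case 4). The companion
  coordinates follow as J* = γ/(η + ρG*), C* = ρG*/φ,
  P* = (δ+ρ)γG*/(κ(η+ρG*)).

The thresholds r = 4ηρσ/(η+ρσ)² (≤ 1 by AM–GM), r2 = 1 − (β/κ)(1+ρ/δ)
and r1 = r·r2 delimit the backward-bifurcation window r1 ≤ R0 < r2 in
which the upper endemic root (E3/E5) is stable, the lower one (E4/E6)
unstable, and E0 also stable — bistability. Because R0 is linear in α
while r, r1, r2 are α-independent, every critical α inverts in closed
form (α = target·γδ/(ησ)); bifurcation branches are therefore drawn
from the closed-form equilibria on an α grid rather than by numerical
continuation.

Equilibria with negative or complex coordinates are returned flagged
(`exists_physically=False`) rather than dropped, so diagrams can show
the unphysical branch segments. A quadratic discriminant within
±1e−12 of zero is treated as an exact double root, stabilising the
saddle-node point itself. When r2 ≤ 0 (strong recidivism,
(β/κ)(1+ρ/δ) ≥ 1) the package reports "no bistability window" instead
of a negative threshold: R0 > 0 ≥ r2 always holds, so the window is
meaningless there and the crime-free state is never stabilised by
reducing α alone — that design choice keeps the threshold set
interpretable.

## Stability classification

Numeric eigenvalues of the full 4×4 Jacobian are the authoritative
verdict in every case, with a marginality band of 1e−9 on real parts
(at a bifurcation point the verdict is "marginal", never forced).
The closed-form spectra are exposed alongside:

* Cases 1–3 they are exact — the Jacobian is block-triangular at the
  relevant equilibria, and the reduced quadratics (u, v, p, q
  coefficients) follow from equilibrium identities such as
  δJ* = α(σ − G*) (case 3). The test suite checks analytic-vs-numeric
  agreement to 1e−8 over random parameter draws.
* Case 4 factorisations (one eigenvalue −φJ*, plus a cubic with
  coefficients y1, y2, y3 and Routh–Hurwitz determinant
  Δ = y1y2 − y3) hold only in the small-rate regime ρ ≪ 1, φ ≪ 1.
  Reports carry an `analytic_regime_ok` flag with configurable bounds,
  defaulting to ρ ≤ 1e−3 and φ ≤ 1e−2 — chosen to cover realistic
  co-optation/incarceration rates such as the shipped real-world
  scenario (ρ = 2.5e−5, φ = 1e−2) while excluding the didactic
  β=30/ρ=0.1 set, whose analytic case-4 spectrum is visibly off. In
  strict mode an out-of-regime request raises instead.

Two exact results that the approximate case-4 algebra only suggests are
confirmed numerically throughout: the crime-free state exchanges
stability exactly at R0 = r2 (the determinant of the reduced 3×3 block
at E0 changes sign precisely there, which is also where the endemic
branch crosses G* = 0), and Δ > 0 whenever the upper endemic state is
physical and β ≤ κ, so no Hopf bifurcation and no limit cycles arise
on that branch.

## Numerical integration

Trajectories use the classic fixed-step 4-stage Runge–Kutta scheme,
default step 0.01 time units, recording every step. The integrator
does not clamp: a component falling below −1e−6 (or going non-finite)
aborts the run with advice to reduce the step, because silent
projection would mask instability. This honesty matters here: the
didactic parameter set with γδ/η = 800 is stiff wherever the judiciary
sits near its crime-free level — the Jacobian at E0 has an eigenvalue
≈ −716, and the α=20 endemic state one of ≈ −412 — so a step of 0.01
lies outside the RK4 linear stability interval (≈ (−2.785, 0) on dtλ)
and roundoff noise grows by a factor ~60 per step. The affected
shipped scenarios (fig3a, fig3b, fig3d) therefore use dt = 0.002,
comfortably inside the stability region; fig1a/fig1b, fig3c and fig5
never enter a stiff regime and keep dt = 0.01. Step-halving changes
the endpoints of these runs by less than 1e−6 relative, consistent
with fourth-order convergence.

Horizons are scenario-dependent and chosen so the trailing window is
quasi-stationary: 10 time units for the fast case-1 runs, 100 for the
case-4 set (the judge pool relaxes at rate η = 0.1, so reaching the
1e−4 convergence tolerance near E0 needs t ≈ 100), and 300 years for
the real-world scenario. All are overridable.

Attractor detection requires the trailing 10% of the trajectory to be
quasi-stationary (peak-to-peak variation below the relative tolerance
1e−4) and then matches the window mean against the closed-form
equilibria component-wise, with an absolute floor of 1e−6 for zero
coordinates. The basin probe simply maps a list of initial conditions
through integration and detection, reporting per-start labels (or
errors) without claiming anything about the geometry of the separatrix
between basins.

## Scenario fixtures

Seven fixtures encode the published simulation experiments exactly
(parameters, printed initial conditions, expected limits at the
two-decimal display convention; comparisons use an absolute tolerance
of 0.005 on rounded values plus the convergence tolerance). The case-1
figures do not print their initial conditions; those fixtures start at
(1, γ/η, 0, 0) — a single gang member invading a crime-free
equilibrium — which is immaterial because the case-1 regimes are
monostable and the asymptotic state is initial-condition independent.
The bistable fixtures (fig3b/fig3c) differ only in their printed
initial conditions and land on different attractors, which is the
point of the backward bifurcation.

## What the fixtures do and do not show

The parameter sets are didactic (except fig5, a plausibly scaled
real-world configuration with judge careers of 30 years, 5-year
sentences, 5/6 recidivism and ~1% judicial corruption); passing tests
show that the implementation reproduces the model's analytical
structure and its published simulations, not that the model fits any
empirical crime series. The model itself omits spatial structure, age
structure, police compartments, time-varying policy and stochasticity;
parameter estimation from data is out of scope.

## Numerical conventions

Full double precision everywhere internally; two-decimal rounding is a
display convention only. Case dispatch is by exact zero comparison on
ρ and β. Eigenvalue ties and orderings are handled by sorting on
(real, imaginary) parts. Boundary behaviour at B = 0 with R0 < 1
(case 3) is reported as the algebraic roots with the physical-existence
flags, without asserting a sign taxonomy at the boundary itself.
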