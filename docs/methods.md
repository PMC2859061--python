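# Methods

## Scope and assumptions

Three deterministic models, each a closed form or a small ODE system,
share a package because they cover the three rate processes that decide
whether a liposome formulation is worth making: payload retention,
vascular residence, and production throughput.

**MLV leakage.** The multilamellar vesicle is treated as a homogeneous
sphere — drug evenly mixed with lipid, one effective diffusivity — with
no drug–lipid binding kinetics, no concentration dependence, and no
resolved lamellae. The exterior is a perfect sink: the surface flux is
−D ∂C/∂r = k_C C(R, t) with zero outside concentration. A finite,
configurable exterior concentration was deliberately not added; the
mass-transfer coefficient k_C is the single surface parameter.

**Vascular transport.** Blood is Newtonian at constant viscosity
(non-Newtonian inputs are rejected at validation), flow is steady,
fully developed, unidirectional and axisymmetric, and the axial Peclet
number is large so axial diffusion is dropped. Radial concentration
structure is collapsed into the blood-side film coefficient k_c; the
three coefficients k_c, k_m, k_t are user inputs (no Graetz/Leveque
entrance correlation is built in). The tissue boundary concentration
C_t is a constant parameter, default 0; tissue-side accumulation is not
modeled. Reverse flow is refused unless explicitly allowed
(`allow_reverse`), in which case the mean velocity and profile change
sign together.

**CTR production.** Plug flow at constant diameter and volumetric feed
rate; no axial dispersion; isothermal k. The solid lipid deposit is in
large excess, so kinetics are pseudo-second order, r = k[TR][DRG], with
the stoichiometric multipliers applied in the balance equations and
*not* inside k — k stays a single fit parameter, and the choice is
pinned by the conserved combinations [DRG]−100[TR], [TR]+100[DEL],
[DRG]+10000[DEL], which only hold with the multipliers outside. Lipid
is bookkept (80000 per liposome formed), not integrated. Concentrations
stay in the feed's arbitrary units end to end.

## Key derived quantities

| symbol | meaning | default / range |
| --- | --- | --- |
| Bi = k_C R / D | surface transfer vs internal diffusion | test battery spans 1e-3..1e3 |
| τ = D t / R² | dimensionless time | — |
| K, 1/K = Σ 1/k_i | overall wall transfer coefficient (m/s) | — |
| 2KL/(R_v U) | axial decay extent of C_b | fixtures span 1e-2..10 |
| c = (πd²/4)/u | reactor residence per unit length (s/m per volume) | reference scenario fixes c·k = 1 |

The reactor profile depends on position only through c·k·L, so the
reference production scenario — whose k, d, u have no independently
meaningful values — fixes c·k = 1 in arbitrary units (unit
cross-section, unit flow, unit rate coefficient). Its feed is TR = 500,
DRG = 50000, DEL = 0 a.u.; because 500/100 = 50000/10000 both reagents
exhaust simultaneously and the product ceiling is exactly 5 a.u.

## Numerical choices

**Eigenvalues.** λ cot λ = 1 − Bi has exactly one root per interval
((n−1)π, nπ); after multiplying by the sign of sin λ the condition
λ cos λ + (Bi−1) sin λ is sign-definite at the bracket ends, so Brent's
method inside the bracket cannot escape, and a few Newton steps polish
the root. For extreme Bi the root approaches an endpoint closer than
the default bracket inset; the inset is then shrunk toward machine
spacing. The residual is asserted on the *normalized* condition,
|λ cos λ + (Bi−1) sin λ| / max(λ, |Bi−1|, 1) < 1e-12: the unnormalized
residual scales with max(λ, Bi) near the root, so an absolute bound is
not representable in double precision for large n or Bi.

**Series evaluation.** Default truncation N = 200 with an early exit
once a term falls below 1e-14 of the running sum (the exponential
factors decrease in n, so the tail is bounded by the first dropped
term). For τ < 1e-6 the initial condition is returned exactly: the
series converges slowly there, the physical state is unchanged, and
this avoids Gibbs oscillation near the surface. At η = 0 the basis
value is the analytic limit λₙ of sin(λₙη)/η. The volume average is
done term by term in closed form (3aₙ(sin λₙ − λₙcos λₙ)/λₙ²), not by
quadrature. With N = 200 the reconstructed initial mean carries an
O(1e-3) truncation error only in the absorbing-surface limit (the
Dirichlet series tail is 6/(π²N)); at finite Bi the coefficients decay
like λ⁻⁴ and the error is far smaller. `time_to_fraction` inverts the
strictly decreasing mean by bracketed root finding to 1e-12 relative in
τ.

**Reactor integration.** Adaptive DOP853 at rtol 1e-10 / atol 1e-12
with output on the requested grid (dense output for
`conversion_length`). These tolerances keep conservation drift around
1e-15 relative — comfortably inside the 1e-9 budget — at negligible
cost for a 3-state system. States are clamped non-negative inside the
rate evaluation so roundoff-negative excursions cannot feed back.

**Oracles.** Each production solver is checked by an oracle that shares
none of its machinery. The sphere oracle is a second-order
finite-difference scheme (ghost node for the Robin condition, symmetry
at the center) stepped by Crank–Nicolson with eight initial
backward-Euler steps: the uniform start is incompatible with the
leaking surface, and without the damping steps Crank–Nicolson rings at
large Bi. Grid doubling confirms the error ratio ≈ 4. The ODE oracle is
classical fixed-step RK4 with the substep count doubled until
successive trajectories agree pointwise to 1e-10 relative (with a small
absolute floor so exact zeros don't stall). The projection oracle is
composite-Simpson quadrature of the coefficient integrals.

## Synthetic scenario generation

`lipokin.fixtures` draws seeded random parameter sets used by the
property suites and the acceptance script. Vesicles: radius log-uniform
50 nm–10 µm, diffusivity 1e-14–1e-10 m²/s, and the *Biot number*
sampled log-uniformly over [1e-3, 1e3] with k_C derived — sampling the
controlling dimensionless group directly guarantees both asymptotic
regimes are exercised. Vessels: capillary-to-small-artery radii
(5 µm–5 mm), blood viscosity 2–5 mPa·s, mean velocities 0.1–100 mm/s,
film coefficients 1e-8–1e-4 m/s, and the axial decay extent 2KL/(R_vU)
sampled log-uniformly over [1e-2, 10] with the length derived: outside
that window the outcome is numerically indistinguishable from
all-or-nothing delivery and a relative comparison against the oracle is
meaningless (the exponential underflows). Reactors: millimeter tubes,
µL/s–mL/s flows, with k scaled so the dimensionless conversion extent
is O(1–100).

What the generator does *not* emulate: real vesicle polydispersity,
pulsatile or branching flow, margination and size-dependent wall
interaction, lipid-deposit depletion, or any noise — these are
deterministic models and the tests establish their mathematical
correctness and internal consistency, not agreement with in-vivo or
plant data. Passing the batteries means the implemented solutions solve
the stated equations; calibrating k_C, k_c/k_m/k_t or k to a real system
remains the user's experiment.

## Problem sizes

The validation batteries use 20 seeded vesicles × 5 dimensionless times
against a 2000-node finite-difference grid, 20 seeded vessel scenarios,
and 201-point reactor profiles; these sizes put every oracle comparison
well past its convergence plateau while keeping the full suite around
half a minute.

## Known limitations

- The leakage mean carries the ~6/(π²N) truncation error at τ → 0 in
  the strict Dirichlet limit; callers needing the exact surface flux at
  very early dimensionless times should raise `n_terms`.
- `delivered_fraction` is defined only for a perfect tissue sink
  (C_t = 0); with finite C_t the "delivered" amount is ambiguous and
  the call is rejected rather than guessed.
- The sweep utility evaluates the full Cartesian product serially; it
  is intended for screening grids of up to ~10⁴ combinations, not
  optimization.
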