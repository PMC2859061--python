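# lipokin

First-principles models for the design of drug-encapsulating liposomes:
how fast an encapsulated drug leaks out of a multilamellar vesicle, how
far liposomes travel down a blood vessel before crossing into tissue,
and how much product a continuous tubular reactor makes from a given
feed. The package is aimed at formulation scientists and process
engineers who want a rapid, low-cost *in-silico* filter over candidate
compositions and production conditions before committing any of them to
the bench.

## The models

**Drug leakage from a multilamellar vesicle (MLV).** The vesicle is a
homogeneous sphere (drug evenly mixed with lipid) of radius *R*, drug
diffusivity *D*, losing drug through its surface into a perfect sink
via a convective flux with mass-transfer coefficient *k<sub>C</sub>*. In
dimensionless variables (η = r/R, τ = Dt/R², θ = C/C₀) the solution is
the eigenfunction series

&nbsp;&nbsp;θ(η, τ) = Σₙ aₙ sin(λₙη)/η · exp(−λₙ²τ),
&nbsp;&nbsp;λ cot λ = 1 − Bi,
&nbsp;&nbsp;aₙ = 4(sin λₙ − λₙ cos λₙ) / (λₙ(2λₙ − sin 2λₙ)),

controlled entirely by the Biot number Bi = k<sub>C</sub>R/D. The
volume-averaged remaining fraction, the local concentration, and the
time to reach any remaining fraction (e.g. the leakage half-time) are
all exposed. The limits are classical: Bi → ∞ recovers the absorbing
sphere (λₙ = nπ), Bi → 0 the lumped decay exp(−3 Bi τ).

**Vascular mass transfer.** Steady laminar (Hagen–Poiseuille) flow in a
vessel of radius R<sub>v</sub>: v(r) = 2U(1 − (r/R<sub>v</sub>)²) with
U = R<sub>v</sub>²(−d℘/dz)/8μ. Liposomes cross the wall against three
film resistances in series — blood side k<sub>c</sub>, wall
k<sub>m</sub>, tissue k<sub>t</sub> — giving 1/K = 1/k<sub>c</sub> +
1/k<sub>m</sub> + 1/k<sub>t</sub> and the axial depletion

&nbsp;&nbsp;C<sub>b</sub>(z) = C<sub>t</sub> + (C<sub>o</sub> − C<sub>t</sub>) exp(−2Kz/(R<sub>v</sub>U)).

**Continuous tubular reactor (CTR) production.** Liposome synthesis with
targeting receptors follows the fixed stoichiometry
100 TR + 10000 DRG + 80000 LIP(s) → DEL, with pseudo-second-order
kinetics r = k[TR][DRG] (the excess solid lipid absorbed into k). The
plug-flow mole balance per unit length, with c = (πd²/4)/u,

&nbsp;&nbsp;d[TR]/dL = −100·c·r, d[DRG]/dL = −10000·c·r, d[DEL]/dL = +c·r,

is integrated at tight tolerance; the combinations [DRG] − 100[TR],
[TR] + 100[DEL] and [DRG] + 10000[DEL] are conserved to machine
precision along the profile.

## Worked example

```python
from lipokin import MLVSpec, time_to_fraction, fraction_remaining

spec = MLVSpec(radius=1e-6, diffusivity=1e-13, surface_coeff=5e-8)
print(spec.biot)                      # 0.5
print(time_to_fraction(spec, 0.5))    # 5.073 -> half the drug gone in ~5.1 s
print(fraction_remaining(spec, 10.1)) # 0.251 -> ~25% left after two half-times
```

A 1 µm vesicle with hindered internal diffusion (10⁻¹³ m²/s) and a slow
outer bilayer (5·10⁻⁸ m/s) sits between the surface-limited and
diffusion-limited regimes (Bi = 0.5) and protects half its payload for
about 5 s per the series solution. The `examples/` directory carries one
narrative script per capability (`leakage_half_time.py`,
`vascular_delivery.py`, `reactor_production.py`, `screening_sweep.py`);
each builds a small scenario, runs the model, and explains the numbers
it prints.

The same models are available from the shell:

```
lipokin leakage --radius 1e-6 --diffusivity 1e-13 --surface-coeff 5e-8 \
    --t-max 20 --out leak.csv
lipokin reactor --diameter 1.1284e-3 --flow 1e-6 --k 1 --reference-feed --length 10 \
    --out reactor.csv
lipokin sweep --grid mlv.radius_m=0.5e-6,1e-6,2e-6 \
    --fixed mlv.diffusivity_m2s=1e-13 --fixed mlv.kc_ms=1e-7 \
    --metric leakage_half_time --out ranked.csv
```

Outputs are deterministic CSV (12 significant digits, embedded config
echo) or JSON with a metadata block; exit codes are 2 for validation
errors and 3 for numerical failures.

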