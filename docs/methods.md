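# Methods

## Model

A short artery segment is idealized as a thin circular ring of reference
radius R (thickness-averaged), thickness H, density ρ₀, held at a constant
axial pre-stretch λz0 = l/L and loaded by a uniform internal pressure p(t).
The wall is a single homogeneous incompressible layer; the ring deforms
radially only (plane strain), so the kinematics reduce to one degree of
freedom, the circumferential stretch λθ(t) = r/R = 1 + ur/R, with the
radial stretch slaved by incompressibility, λr = h/H = 1/(λθ λz0).
Viscosity, anisotropy, multi-layer structure and axial wave propagation are
outside this model: the ring is a cross-section of the artery, not the
artery as a whole.

Radial momentum balance of a wall element gives

    r p − N = ρ₀ h r ür,    N = Tθ = σθθ h,

with the inertia coefficient ρ₀ h r = ρ₀ H R / λz0 constant in time by mass
conservation (this is the only reading consistent with the characteristic
times below). Normalizing displacement by R and time by the
law-specific characteristic time t_c reduces every model to

    x'' = (1 + x) p̂(τ) − g(x).

### Constitutive laws and restoring forces

With λ = 1 + x:

* **Skalak (membrane, healthy)** — W/C = (B/4C)(I²/2 + I − II) + II²/8 with
  I = λθ² + λz0² − 2, II = λθ²λz0² − 1; tensions
  Tθ/C = (λθ/λz0)[(B/2C)(λθ²−1) + (λz0²/2)(λθ²λz0²−1)] (and θ↔z swapped for
  Tz); g(x) = Tθ/C. g is an exact cubic polynomial in x with coefficients
  c0 = (λz0³−λz0)/2, c1 = B/(Cλz0) + (3/2)λz0³ − λz0/2,
  c2 = (3/2)(B/(Cλz0)+λz0³), c3 = (1/2)(B/(Cλz0)+λz0³). Characteristic time
  t_Sk = √(ρ₀R²H/(Cλz0)); pressure scale C/R.
* **Hariton exponential (atherosclerotic)** — W/a =
  (1/b)[exp((b/2)(I₁−3)²) − 1] with I₁ = λθ² + λz0² + 1/(λθ²λz0²); Cauchy
  stresses from σᵢ − σ_rr with σ_rr ≈ 0 (thin wall, free outer surface):
  σθθ/a = 2(λθ² − 1/(λθ²λz0²))(I₁−3)exp((b/2)(I₁−3)²). t_H = √(ρ₀R²/(aλz0));
  pressure scale aH/R.
* **Mooney–Rivlin (aneurysmatic)** — W/μ = ½[(½+β)(I₁−3) + (½−β)(I₂−3)],
  I₂ = λθ²λz0² + 1/λz0² + 1/λθ²; σθθ/μ = (½+β)(λθ² − 1/(λθ²λz0²)) +
  (½−β)(λθ²λz0² − 1/λθ²). β drops out entirely when λz0 = 1.
  t_MR = √(ρ₀R²/(μλz0)); pressure scale μH/R.
* **Linear reference** — ρ₀H ür = p − (EθH/R²) ur with the initial tangent
  modulus Eθ of the law being compared, initial displacement
  u0 = R(λz0 − 1); solved exactly piecewise-harmonically.

The zero-order (linearized-about-reference) natural frequency is
ω₀ = √(g'(0))/t_c: for Skalak √(B/(Cλz0) + (3/2)λz0³ − λz0/2)/t_Sk, for
Mooney–Rivlin the Knowles limit ω₀ t_MR = 2 at λz0 = 1, and zero for the
exponential law at λz0 = 1 (its stress-strain curve starts with zero
slope, which is also why its linear-model comparison is poor at low
pre-stretch). A negative linearized stiffness (Skalak with λz0 < 1/√3 and
B ≈ 0) is reported as a flagged non-oscillatory result — possible material
instability — rather than an error.

The Skalak truncation hierarchy: order 3 is the full cubic; orders 2 and 1
truncate g at x² and x¹; order 0 additionally drops the parametric p̂·x
load term, leaving the constant-coefficient oscillator that defines ω₀.

## Loading

The cardiac cycle is an ideal rectangular wave: p = ps on [0, ts] of each
cycle, p = pd on (ts, tcp), repeated. Defaults: ps = 16 kPa (120 mmHg),
pd = 10.66 kPa (80 mmHg), ts = 0.35 s, tcp = 1 s. The instantaneous rise is
the most conservative loading: it produces the factor-two dynamic
overshoot over the quasi-steady response that dominates the peak tables.
The wave is *not* smoothed; instead the integrator is restarted at every
switch time (known a priori), so no stiff step ever straddles a jump.

## Numerics

Each constant-pressure segment is integrated with `scipy.integrate.solve_ivp`
(default LSODA, rtol 1e-8, atol 1e-10) in dimensionless time. The problems
are stiff in the engineering sense that the forcing period is thousands of
characteristic times (tcp/t_c up to ~3300 here) while the ring oscillates
on the scale of one; within a segment the dynamics are smooth, undamped
and conservative. RHS closures use scalar math (no array overhead) since
the integrator evaluates them millions of times per run.

Peak extraction: turning points of the displacement (v = 0) are located
exactly by the integrator's event machinery. Every response quantity is a
smooth function of the attained stretch, so its extremum over the trace
occurs at a turning point, a segment boundary, or t = 0; all are in the
sample set, which also includes an equispaced grid (5000 samples/cycle by
default) for output. Because the motion on each segment is exactly
periodic, the global extremum recurs every ring oscillation; summaries
report its *first* attainment, taken as the first sample within a 1e-4
relative band of the global extremum (the band absorbs the integrator's
small amplitude drift over thousands of oscillations). The t = 0 sample is
always included: for strong pre-stretch the reference state λθ = 1 itself
carries the peak strain energy and the tables quote time 0.

Degenerate regimes: integration terminates with a diagnostic flag when the
stretch reaches 20 (the Mooney–Rivlin ring is unbounded for p̂s ≥ 1 at
λz0 = 1 — the aneurysm limit p_sR/μH → 1) or when the ring collapses
(1 + x ≤ 10⁻³). The Hariton exponent (b/2)(I₁−3)² is capped at 700 and
raises a diagnostic beyond, since it grows quartically in stretch and
would otherwise overflow silently.

Energy audit: on each constant-pressure segment the total
v²/2 + V(x) − p̂(x + x²/2), with V' = g, is conserved; the default
tolerances hold the relative drift below 1e-6 per cycle, and halving the
tolerances moves reported peaks by well under 0.1%.

## Dimensionalization

The Skalak law is two-dimensional (tensions in N/m): Cauchy stress and
volumetric energy density divide by the *current* thickness,
σθθ = Tθ λθ λz0 / H and W₃D = W₂D λθ λz0 / H (per current volume — this
reproduces the benchmark energy entries, whereas dividing by the reference
thickness does not). The 3-D laws only need their stress scale (a or μ).
Since the conversion factor λθλz0/H varies along the trace, physical peaks
are extracted from the converted series, not from normalized summaries.

## Benchmarks and their decoding

Two literature cases are built in. The `demiray` case (dog abdominal
aorta, λz0 = 1.53) runs one cycle; the `humphrey` case (small artery,
λz0 = 1.832) runs two cycles and models residual circumferential stress as
a constant 50 mmHg compressive pressure offset subtracted from both
systolic and diastolic pressures (no opening-angle mechanics), leaving
55/41 mmHg. The printed dimensionless groups of each case are the
simulation inputs; material constants are backed out of them only to
dimensionalize. For the `humphrey` case the printed time-scale ratios are
consistent with normalization at tcp = 1 s although the example states
tcp = 0.8 s; the printed groups are taken as authoritative.

The distension exponent α = ln(ps/pd)/[(λθs/λθd)² − 1] links the ring
response to pressure-area measurements. The systolic stretch entering it
is quasi-steady: it is taken as half the peak systolic-phase dynamic
displacement (the mean of the undamped overshoot oscillation), and the
diastolic one scales with pd/ps — this decoding reproduces the tabulated
stretch pairs exactly, whereas the exact static equilibria at ps and pd
differ from them by 3–5%.

## Parameter sweeps

Response spectra run every grid point independently from identical initial
conditions (x = v = 0 for the nonlinear laws), so rows are
order-independent and parallelizable by contract. The built-in fixtures
encode the figure/table parameter sets; where a source range is given
without a resolution, grids default to 7–11 evenly spaced points. Table
output keeps 5 significant digits.

## Known limitations

* The diastolic rebound amplitude depends on the oscillation phase at the
  systole→diastole switch, reached after O(10²–10³) undamped ring periods;
  near the pre-stretch value where outward and inward peaks balance
  (λz0 ≈ 1.1 for the Skalak ring at p̂s = 0.16), the *sign* of the
  largest-magnitude displacement is sensitive to that phase, and
  low-accuracy integrators (whose numerical damping shrinks the rebound)
  can report the opposite sign from a high-accuracy run.
* The rectangular pulse is a worst case; smooth physiological profiles
  produce smaller overshoots.
* No viscoelasticity: the undamped model rings indefinitely and its peaks
  never decay; real arteries damp a few percent of the energy per cycle.
* Single-layer isotropic laws; fiber-reinforced anisotropy and residual
  stress beyond the constant-offset proxy are out of scope.
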