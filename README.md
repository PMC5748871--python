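# arteryring

Radial dynamics of short human-artery segments modeled as incompressible
hyperelastic rings under pulsatile blood pressure.

## The problem

A short artery segment held at a fixed axial pre-stretch λ<sub>z</sub><sup>0</sup>
and loaded by the cardiac pressure pulse deforms essentially radially. Its
cross-section behaves as a thin vibrating ring: with x = u<sub>r</sub>/R the
normalized radial displacement and τ = t/t<sub>c</sub> time in units of the
ring's characteristic time, every model here takes the form

    x'' = (1 + x) p̂(τ) − g(x)

where p̂ is the normalized pressure (a rectangular systole/diastole wave,
p<sub>s</sub> = 120 mmHg for 0.35 s of a 1 s cycle, p<sub>d</sub> = 80 mmHg
otherwise) and g is the restoring force of one of three incompressible
constitutive laws, each associated with a wall condition:

| law | wall condition | parameters | characteristic time |
|---|---|---|---|
| Skalak (membrane) | healthy, hardening | B, C [N/m], C ≥ B ≥ 0 | t<sub>Sk</sub> = √(ρ₀R²H/(Cλ<sub>z</sub><sup>0</sup>)) |
| Hariton / Delfino exponential | atherosclerotic, strongly hardening | a [Pa], b | t<sub>H</sub> = √(ρ₀R²/(aλ<sub>z</sub><sup>0</sup>)) |
| Mooney–Rivlin | aneurysmatic, softening | μ [Pa], β ∈ [−½, ½] | t<sub>MR</sub> = √(ρ₀R²/(μλ<sub>z</sub><sup>0</sup>)) |

plus an equivalent linear model built on the initial tangent modulus
E<sub>θ</sub> = dσ<sub>θθ</sub>/dλ<sub>θ</sub> |<sub>λθ=1</sub>, which has an
exact piecewise-harmonic solution.

The package integrates these stiff nonlinear oscillators, extracts peak
responses — displacement, circumferential stretch, wall thinning, Cauchy
stresses, and the strain-energy density W (a trustworthy arterial-strength
criterion, unlike the hoop stress whose curves intersect across stiffness
grades) — sweeps response spectra over the dimensionless parameter groups
(B/C or b or β, λ<sub>z</sub><sup>0</sup>, p<sub>s</sub>R/C,
t<sub>cp</sub>/t<sub>c</sub>), computes the zero-order radial resonance
frequency ω₀ = √(g'(0))/t<sub>c</sub>, and evaluates the pulse-wave helper
relations (exponential distension exponent α, axial/radial wall displacement
ratio).

## Worked example

The built-in `demiray` benchmark (a dog abdominal aorta: R = 3.46 mm,
H = 0.68 mm, λ<sub>z</sub><sup>0</sup> = 1.53, systolic/diastolic pressures
9.892/3.466 kPa) run with the exponential-hardening law:

```python
from arteryring import run_example
report = run_example("demiray", "hariton")
print(report["peaks"])
```

prints

```
{'ur_over_R': 0.4241949585224647, 'ur_mm': 1.4677145564877279,
 'sigma_theta_kPa': 448.5117589345006, 'sigma_z_kPa': 525.6361896161497,
 'W_kPa': 44.052515839765945}
```

i.e. the ring overshoots to a 42% radial strain when systole starts
abruptly, with a peak circumferential Cauchy stress of ≈ 449 kPa and a peak
strain-energy density of ≈ 44 kPa — the hardening exponential wall carries
the pulse at finite stretch, where a softening wall (Mooney–Rivlin at this
pre-stretch) would not be meaningful.

The same machinery is available from the shell:

```sh
arteryring example --case demiray --law hariton
arteryring sweep --fixture table1 --out table1.csv
arteryring freq --law skalak --ratio 0 --lamz0 1 --tchar 5e-4
arteryring simulate --config run.toml --summary-json out.json
```

A dimensionless run configuration is a small TOML file:

```toml
mode = "dimensionless"
law  = "skalak"

[groups]
material_ratio = 0.5   # B/C
p_hat_s        = 0.16  # ps*R/C
lam_z0         = 1.2
time_ratio     = 2000  # tcp/tSk
```

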