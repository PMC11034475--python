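# poremech

Mechanics of pore-spanning (free-standing) lipid bilayers from AFM
force spectroscopy.

A bilayer suspended over a micrometre-scale hole in a solid support can
be indented in its centre by an AFM tip. The approach curve contains
three mechanical observables:

* the **breakthrough force** BF — the largest force the membrane bears
  before the tip punches through, read at the first abrupt force drop;
* the **pre-stress** σ [mN m⁻¹] — the in-plane tension set by the
  preparation, which controls the quasi-linear small-indentation
  response;
* the **Young's modulus** E [MPa] (equivalently the area-stretching
  modulus E²ᴰ = E·h) — the material stiffness that dominates once the
  membrane is stretched, producing the cubic large-indentation response.

`poremech` implements the full analysis chain: baseline correction,
contact-point detection, construction of the indentation axis δ from the
piezo axis, first-rupture extraction, and a per-curve fit of the
point-loaded pre-stressed circular membrane model for (E, σ). Ensemble
results are summarised the way this field reports them: Gaussian peaks
fitted to BF and E histograms, mean ± SE for σ, and the derived bending
rigidity κ = E·h³/12(1−ν²) and E²ᴰ = E·h. A separate module covers the
microfluidic route to bilayer tension: Young's equation Γ = 2γ·cos θ and
the leaflet adhesion energy ΔW = 2γ(1−cos θ) from the monolayer
interfacial tension γ and the bilayer contact angle θ.

## The forward model

For a clamped circular membrane of radius R, thickness h, Poisson ratio
ν under central point load F at indentation δ, two laws are provided:

* `approx_superposition` — the common interpolation
  `F = π σ δ + E²ᴰ q³ δ³ / R²` with `q = 1/(1.049 − 0.146ν − 0.158ν²)`;
* `exact_fvk` — the numerical solution of the axisymmetric
  Föppl–von-Kármán membrane boundary-value problem (no bending term),
  valid at any pre-stress. The dimensionless problem collapses exactly
  onto a single master curve `F/(E²ᴰR) = s^{3/2} Φ(δ/(R√s); ν)` with
  `s = σ/E²ᴰ`, which the package builds once by parameter continuation
  (≈1 s) and caches; at σ = 0 it reduces to the classical Schwerin-type
  cubic law.

Because no public force-curve data exist for this system, the package
ships a first-class synthetic-data generator: seeded, ground-truth
annotated approach curves with baseline drift, snap-in, spring-in-series
membrane deformation, a stochastic rupture and Gaussian force noise, for
two membrane compositions (`PMC`, a plasma-membrane-like lipid mixture
with cholesterol and sphingomyelin, and `PMC-`, the same mixture without
them) whose generating parameters are the fitted ensemble values for
those membranes.

## Worked example

```python
import poremech as pm

curve, meta, truth = pm.generate_curve(pm.make_preset("PMC"), [42, 0])
ana = pm.analyze_curve(curve, meta)
print("BF =", round(ana.event.bf / 1e-12, 1), "pN")
print(ana.fit.summary())
```

prints

```
BF = 408.1 pN
Membrane indentation fit
==============================================
model kind        exact_fvk
converged         True
n points          201
E      [MPa]             566.4 +/- 26.2
sigma  [mN/m]            3.553 +/- 0.44
contact offset        -0.00467 nm
delta_max [nm]           27.08
delta_max / R          0.04514
rss    [pN^2]        1.968e+04
E identifiable    True
passed filter     True
```

This curve ruptured at 408 pN after 27 nm of indentation (δ/R = 0.045,
deep enough for E to be identifiable — curves with δ/R ≤ 0.03 are
excluded from modulus statistics); the fit estimates a 566 ± 26 MPa
modulus and 3.6 ± 0.4 mN m⁻¹ pre-stress for this membrane (generating
values: 536 MPa, 4.12 mN m⁻¹ — single-curve estimates scatter, the
ensemble statistics are the quantity of interest).

The same pipeline runs from the shell:

```bash
poremech simulate --preset PMC --n 200 --seed 42 --out data/pmc
poremech run --manifest data/pmc/manifest.csv --out results/pmc
poremech tension --gamma 7.65 --theta 31.81 --label PMC
```

`run` writes `results.csv` (one row per curve), `summary.json` (per
condition: BF peak ± SE, E peak ± SE, σ mean ± SE, κ, E²ᴰ), a config
snapshot and a log.

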