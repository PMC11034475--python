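# Methods

## Physical model

The object is a lipid bilayer of thickness h clamped over a circular
hole of radius R, carrying an isotropic in-plane pre-tension σ, indented
at its centre by a point force F to depth δ. Bending stiffness is
neglected (membrane limit): for bilayers κ/σR² ≈ 10⁻⁵–10⁻³, so tension
and stretching dominate at all probed indentations. The material is
treated as isotropic with Young's modulus E and Poisson ratio ν; only
the area-stretching combination E²ᴰ = E·h is mechanically probed, E is
reported for comparability. ν is fixed at 0.485 (nearly
area-incompressible).

### Exact Föppl–von-Kármán solution

The axisymmetric FvK membrane equations couple vertical equilibrium
`2π r N_r w' = −F`, in-plane equilibrium `(r N_r)' = N_t`, and linear
constitutive relations with modulus E²ᴰ. With x = r/R, t = ln x,
G = r·N_r/(E²ᴰR), f = F/(E²ᴰR) and s = σ/E²ᴰ this reduces to

    G_tt − G = −(f²/8π²) eᵗ / G²  on  t ∈ [ln x₀, 0]

with a pre-stressed clamped edge, `G_t − νG = s(1−ν)` at t = 0, and a
Schwerin-core asymptote `3G_t = G` (G ∝ x^{1/3}) at an inner cutoff
x₀ = 10⁻⁴ regularising the point load; the deflection is
δ/R = (f/2π)∫eᵗ/G dt plus the analytic core contribution below x₀.
The boundary-value problem is solved with a damped-Newton collocation
solver (relative tolerance 10⁻⁸).

Because the inner boundary condition is homogeneous in G, the solution
family has an exact scaling symmetry: `f(d, s) = s^{3/2} Φ(d/√s; ν)`
with d = δ/R. The entire exact law is therefore one scalar profile Φ,
built once per (ν, x₀) by continuation over ~70 loads at s = 1 and
interpolated monotonically in log–log (PCHIP); interpolation error is
~10⁻⁴ relative, far below the measurement noise. At s = 0 the same
symmetry makes the law exactly cubic, `f = C(ν)d³`, with C obtained
from a single solve; C(0.485) agrees with the conventional prefactor
q³ = 1/(1.049 − 0.146ν − 0.158ν²)³ to 0.4%.

Two numerical conventions matter and are deliberate:

* The small-δ response of a point-loaded pre-tensioned membrane is
  logarithmically sensitive to the load regularisation. With the
  Schwerin-core condition at x₀ = 10⁻⁴ the observed small-δ stiffness is
  ≈ 0.54·σ·(per unit δ), i.e. about six times softer than the πσδ of
  the superposition formula. Within this package the same law generates
  and fits the synthetic data, so the convention cancels; when fitting
  real data the fitted σ is convention-dependent at the tens-of-percent
  level, as it is for any implementation of this model.
* The approximate law `F = πσδ + E²ᴰq³δ³/R²` is kept as an independent
  closed form (used for cross-checks and initialisation), not as a
  small-δ limit of the exact law.

## Synthetic data generator

Each curve draws a membrane (E, σ, R) and a rupture force from the
preset's population distributions, maps the exact force law through the
cantilever spring (k = 0.03 N m⁻¹) in series onto a uniform piezo axis,
truncates at the drawn rupture force with an abrupt drop to zero (the
substrate lies 70–100 nm below the membrane, so the tip falls free),
and adds a linear baseline, an optional snap-in dip just before contact
and white Gaussian force noise.

Preset central values are the reported ensemble parameters of the two
compositions (PMC: E 513 MPa, σ 5.2 mN m⁻¹, BF 366 pN, h 6.7 nm;
PMC⁻: 21.4 MPa, 2.0 mN m⁻¹, 146 pN, 6.0 nm; hole radii 400/600 nm with
equal weight). Population spreads are not published (the printed ± are
peak standard errors); the defaults — E sd 15% of the mean, σ sd 20%,
BF sd 60/40 pN, 10 pN RMS noise — give realistic histogram widths.
Ramp (180 nm) and sampling (720 points, 0.25 nm) are typical quasistatic
force-ramp settings. Rupture forces are truncated at five noise scales
so every drawn rupture is detectable; presets verify at construction
that ≥95% of draws rupture within the ramp.

What the generator does **not** emulate: coloured/1-f instrument noise,
piezo creep and hysteresis, finite tip radius, multi-step rupture
ladders, lateral offset from the hole centre, and any loading-rate
dependence of rupture. Passing tests therefore demonstrate estimator
correctness under the stated statistical model, not robustness to every
instrumental artefact of real data.

## Per-curve estimation

* **Baseline**: straight line over the first 40% of the ramp; noise
  scale = 1.4826·MAD of the residuals (robust to snap-in outliers).
* **Contact**: onset = force above 3×noise for 10 consecutive samples;
  backtrack to the last zero-crossing; refine by extrapolating a
  quadratic fitted from the crossing until the force clears 20×noise
  down to zero force. The raw backtrack is systematically late by about
  noise/slope; a straight-line extrapolation under-corrects because the
  early response is convex; the quadratic root leaves a residual bias
  of a few ångström to ~1 nm (95th percentile < 2 nm at 10 pN noise for
  the stiff preset).
* **Rupture**: first sample lying ≥ max(5×noise, 30 pN) below the
  maximum of the preceding 15-sample window, confirmed by the mean of
  the next 5 samples staying half a threshold below that maximum
  (rejects single-sample noise excursions). BF is read at the last
  pre-drop sample — reading the window maximum instead would take the
  max of several noisy samples and bias BF upward by about the noise
  scale.
* **Indentation axis**: δ = (z − z_c) − (F − F_c)/k (tip–sample
  separation); curves already on an indentation axis pass through.
* **Fit**: nonlinear least squares of the chosen force law over the
  post-contact region ending 3 samples before the rupture. Two details
  keep the estimates unbiased at 10 pN noise:
  1. the fit abscissa is the piezo coordinate ζ = δ + (F−F₀)/k
     reconstructed from the data — the reconstruction exactly undoes the
     separation construction, so ζ is noise-free; fitting F(δ) directly
     couples the same noise realisation into both axes and biases E by
     ≈ −6% at study conditions;
  2. the contact position enters as a bounded nuisance parameter z₀
     (±10 nm) anchored by a 40-sample pre-contact window (baseline-level
     force, snap-in dip masked); every detection-only contact algorithm
     tried leaves a 1–3 nm late bias that distorts σ by tens of percent
     for soft membranes.
  Multi-start initialisation (σ from the early slope over π, E from a
  linear+cubic polynomial fit, plus ×0.2/×5 perturbed restarts) guards
  against the near-degenerate linear/cubic trade-off. Standard errors
  come from the Gauss–Newton covariance at the optimum.
* **Identifiability**: shallow, tension-dominated curves constrain σ
  but not E; the optimiser then returns E on a bound or with a Wald
  coefficient of variation above 100%. Such fits are flagged
  `e_identifiable = False`: they are excluded from the ensemble E
  histogram (where their E, often collapsed toward zero, is
  meaningless) but their σ still enters the pre-stress summary when
  they are genuinely tension-only. The threshold is the standard
  "uncertainty exceeds the estimate" rule; the stricter 95%-CI rule was
  rejected because it induces an upward selection bias of the ensemble
  E peak, the looser 200% rule because it lets collapsed fits drag the
  peak down.

## Ensemble statistics

* **BF and E**: histogram with Freedman–Diaconis bins (floor 8 bins),
  least-squares Gaussian (amplitude, peak, width) on the bin counts;
  peak uncertainty from the fit covariance. A reduced Poisson
  chi-square above 3 flags shapes a Gaussian cannot match (e.g.
  bimodal), in which case the peak is not a distribution summary. The
  E histogram uses only δ/R > 0.03, identifiable fits (strict
  inequality at the boundary); the δ/R rule reflects that modulus
  accuracy grows with indentation depth.
* **σ**: arithmetic mean ± standard error over all converged fits
  (the δ/R filter does not apply — tension is constrained at any
  indentation depth).
* **Derived**: κ = E·h³/12(1−ν²) and E²ᴰ = E·h from the E peak with the
  condition's nominal h, ν. κ is exposed as an explicit function of E
  because the appropriate E (peak vs deep-indentation asymptote) depends
  on the question asked.
* Radii are pooled without weighting (no radius dependence is modelled).

## Tension module

Γ = 2γ·cos θ and ΔW = 2γ(1 − cos θ) with γ in mN m⁻¹ and θ in degrees;
the identity 2γ = Γ + ΔW holds to machine precision. First-order error
propagation on (γ, θ). θ ≥ 90° is a domain error (the monolayers would
not adhere). The AFM pre-stress σ and the microfluidic bilayer tension Γ
are both in-plane tensions but arise from different preparations
(substrate adhesion vs leaflet zipping) and are never equated. The
reference (γ, θ) pairs shipped with the package are back-derived from
the reported (Γ, ΔW) pairs via 2γ = Γ + ΔW, cos θ = Γ/(Γ + ΔW), because
γ and θ themselves are only published graphically.

## Problem sizes and determinism

End-to-end validation uses 200 curves per condition (base seed 42,
per-curve seeds `[base, i]` so any curve regenerates in isolation); a
full 200-curve pipeline takes ~10 s on one core after the one-off
profile build. Recovered ensemble statistics are compared to their
generating values with the two-sample criterion
|ours − ref| ≤ 3·√(SE²ours + SE²ref), the reference SEs being the
published peak uncertainties the generator is parameterised with.

## Known limitations

* The per-curve (E, σ) likelihood is banana-shaped; at 10 pN noise the
  nonlinear-least-squares point estimates carry a small (≈1–2%)
  median bias that no amount of ensemble averaging removes.
* For the soft composition ~15% of curves do not constrain E at all;
  the identifiability screen handles them, but the ensemble E peak for
  soft membranes is accordingly noisier.
* The exact-model σ is tied to the point-load regularisation convention
  (see above); comparisons across implementations should match the
  cutoff convention before comparing σ.
* Retract curves, adhesion analysis, force-volume maps and vendor
  binary formats are out of scope; the documented TSV/JSON dialect is
  the interchange format.
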