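# Methods

## The model

A macromolecule in solution samples an ensemble of conformations, and the
measured SAXS intensity is the population-weighted average of the
per-conformation intensities.  Resolving that ensemble in full is hopelessly
under-determined, so `saxsflex` reduces each conformation to a single
coordinate — its radius of gyration Rg — and represents the conformational
distribution by a probability density P(Rg).

Two further reductions make the problem tractable:

1. **Single-conformation model.**  A conformation with radius of gyration Rg
   scatters like a uniform solid sphere with the same Rg, i.e. radius
   R = √(5/3)·Rg.  Its normalized intensity is the sphere form factor

       I_S(q, Rg) = [3 (sin x − x cos x) / x³]²,   x = qR,

   with I_S(0, Rg) = 1.  This is defensible only at low q, where the
   intensity is dominated by overall particle size; the package therefore
   fits in the low-q decade by default (below).

2. **Parametric Rg density.**  P(Rg) is log-normal with log-scale location μ
   and log-scale width σ (median Rg = e^μ, both parameters dimensionless with
   Rg in Å).  The log-normal has strictly positive support and vanishes at
   Rg → 0; the density at exactly Rg = 0 is set to 0.

The model intensity is the convolution

    I_{μ,σ}(q) = ∫₀^∞ P_{μ,σ}(Rg) · I_S(q, Rg) dRg,

fitted to the measured curve with a free overall scale.  The flexibility
measure is the **differential entropy** of the fitted density,

    S = μ̂ + 1/2 + ln(σ̂·√(2π))   [nats],

which quantifies the diversity of sizes the molecule samples.  Unlike a
discrete Shannon entropy, S is unbounded below: σ → 0 (a single rigid size)
drives S → −∞.  The closed form is the standard log-normal differential
entropy; `entropy_quadrature` evaluates −∫P ln P numerically and the test
suite (and `scripts/acceptance.py`) verify agreement to better than 1e-8
across a (μ, σ) grid, with `scipy.stats.lognorm.entropy` as a second
independent check.

## Numerical choices

**Quadrature (forward model).**  The Rg integral uses trapezoid quadrature on
400 log-spaced nodes spanning the [1e-6, 1−1e-6] quantiles of the current
log-normal.  The computed grid mass (≈ 1 − 2e-6) divides the integral, so
I_{μ,σ}(0) = 1 at machine level rather than to quadrature bias.  A grid
capturing < 99.99% of the pdf mass raises an error instead of silently
truncating.  The quadrature is validated against seeded Monte-Carlo ensemble
averages of the sphere model (10⁶ draws, agreement within 3 MC standard
errors at every q point).

**Sphere kernel.**  The amplitude 3(sin x − x cos x)/x³ loses ~12 significant
digits to cancellation near x = 0; below x = 0.01 the 4th-order Taylor series
1 − x²/10 + x⁴/280 is used instead, whose truncation error (x⁶/15120) is
below machine epsilon there.  The branches join to ~1e-13.

**Guinier analysis.**  Rg and I(0) come from linear regression of ln I on q²
over the largest low-q window satisfying q·Rg ≤ 1.3 (configurable), found by
fixed-point iteration on Rg (seeded from the whole curve, max 50 iterations,
tolerance 1e-6 Å).  Rows with q = 0 in input files are dropped: measured
zero-angle points are unphysical in SAXS.

**Fit window.**  The sphere reduction is meaningful where the intensity is
dominated by overall size — the region in which I(q) falls by about one order
of magnitude.  The default window is [q_min, q_10], where q_10 is the first q
at which the lightly smoothed intensity drops below I(0)/10 (I(0) from
Guinier), capped at 0.3 Å⁻¹; it is fully overridable (`FitConfig.q_window`,
`--q-max`).

**Objective.**  Default is least squares on log-intensities (equalizes the
fitted decade of dynamic range); a σ-weighted χ² is available when the
profile carries reported errors.  In both schemes the overall scale has a
closed-form optimum for fixed (μ, σ) and is profiled out of the search, so
whether a profile is pre-normalized by I(0) or raw is immaterial — fitted
(μ̂, σ̂, S) are invariant under intensity rescaling to ≤ 1e-6.

**Optimization.**  The objective is multimodal in σ (form-factor
oscillations), so the search runs L-BFGS-B from a deterministic 3×4 lattice
of starts — μ ∈ {ln Rg_G − 1, ln Rg_G, ln Rg_G + 1} with Rg_G the Guinier
estimate, σ ∈ {0.05, 0.2, 0.5, 1.0} — within bounds μ ∈ [ln 2, ln 500]
(median Rg between 2 and 500 Å, the physical macromolecule range) and
σ ∈ [1e-3, 2] (the upper bound keeps the quadrature grid compact).  The best
minimum is polished with a Nelder-Mead simplex; on noiseless synthetic
profiles the truth is recovered to ~1e-8 in (μ, σ).  Everything is
deterministic; the only randomness in the package (noise generation and
resampling) takes explicit seeds.

**Error propagation.**  `entropy_error` perturbs the intensities with
independent additive Gaussian noise of the per-point reported sd, refits each
resample from a single warm start at (μ̂, σ̂), and reports the standard
deviation of the resulting entropies.  Correlated noise models are out of
scope.  Points driven non-positive by a noise draw are dropped before the
log-space refit.  On the synthetic reference profile with 1% multiplicative
noise the propagated sd is ≈ 0.3% of S; the documented bound asserted by the
test suite is 2%.

## Diagnostics

The classical transforms are pointwise and never smooth the data: Kratky
(q²I vs q), dimensionless Kratky ((qRg)²I/I(0) vs qRg — for an ideal compact
particle this peaks at x = √3 with height 3e⁻¹ ≈ 1.104), Porod (q⁴I/I(0) vs
q), Porod-Debye (q⁴I/I(0) vs q⁴) and the q³-Debye variant.

**Plateau detection** on Porod-Debye curves locates the first local maximum
of the Porod plot and tests the flatness of the curve over a window covering
25% of the x-range beyond it.  Flatness is measured as the quadratic
curvature of the cumulative integral ∫y dx — the relative drift of the trend
of y across the window — which is robust both to point noise and to
form-factor oscillation about a constant level; the plateau is present when
the drift is ≤ 0.1.  Both thresholds are exposed; the underlying judgement
is visual in practice and the defaults are heuristics.  Note a genuine
limitation: an exactly monodisperse (or very narrow) sphere ensemble has
deep form-factor minima, its Porod-Debye curve is truly not flat at
moderate q, and the detector reports "absent" — real globular-protein data,
whose minima are smeared by internal structure and instrument resolution,
plateau much more cleanly than the idealized sphere model does.

**Entropy quartile classification** uses fixed cut-points 3.37 / 3.86 / 4.26
nats (quartile boundaries observed across a broad survey of deposited
biomolecular SAXS datasets), boundaries inclusive on the lower class:
Q1_compact (S ≤ 3.37), Q2_intermediate, Q3_flexible, Q4_disordered
(S > 4.26).

## The synthetic generator

`saxsflex.synthetic` produces profiles under the same sphere forward model
from weighted mixtures of delta (single-size) and log-normal components, on a
default grid of 400 linear points over 0.005–0.35 Å⁻¹ (past the 0.3 Å⁻¹
coverage conventionally required for Kratky/Porod analysis).  Noise is
multiplicative Gaussian — per-point sd equal to `level`·I, recorded in the
sigma column — the crude counting-statistics structure of deposited data.
The bundled triple (`generate_suite`) emulates a folded protein
(μ = ln 16, σ = 0.10), a partially disordered one (μ = 3.0, σ = 0.30) and an
IDP (μ = 3.6, σ = 0.60) with 1% noise: true entropies ≈ 1.92 / 3.22 / 4.51,
chosen once to span the compact-to-disordered range with unambiguous
ordering.

What passing tests on these fixtures show — and what they do not: generation
and fitting share the sphere forward model, so recovery tests certify the
estimator (quadrature, optimizer, entropy arithmetic), not the physical
adequacy of the sphere reduction for real molecules.  Real profiles carry
inter-point correlations, buffer-subtraction artefacts, aggregation upturns
and instrument smearing that the generator deliberately omits; on such data
the fitted S is a model-dependent summary whose value lies in comparisons
across systems and states, not in its absolute magnitude.

## Known limitations

- The sphere form factor ignores shape anisotropy and internal contrast;
  systems far from globular (rods, flat particles) map onto effective Rg
  distributions whose entropy is not directly comparable.
- The fitted (μ, σ) are point estimates; `entropy_error` propagates reported
  intensity errors only, not model misspecification.
- Plateau detection is a heuristic stand-in for expert visual judgement.
- Problem sizes in the test suite and acceptance script (3×3 or 5×5 truth
  grids, 60 noise resamples, 10⁶ Monte-Carlo draws) were chosen as the
  smallest runs that make the corresponding checks statistically meaningful.
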