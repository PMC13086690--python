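# Methods

`dimeye` packages three computational analyses of a nocturnal insect visual
system — superposition compound-eye optics, hanging-drop ocellar lens
optics, and visual-pigment spectral template fitting — together with a
seeded synthetic-data generator that makes every stage testable without any
raw measurement files.

## Compound-eye optics (`dimeye.eye_optics`)

The model is the classical geometric optics of a refracting superposition
eye. Three scalar metrics are computed from measured anatomy:

* interommatidial angle Δφ = D/R (radians, reported in degrees), with D
  the facet centre-to-centre spacing and R the eye's radius of curvature;
* F-number F = f/A, with f the focal length (half the corneal radius of
  curvature in a classical superposition eye) and A the superposition
  aperture, measured in practice as the eye-glow diameter;
* optical sensitivity S = (π/4)² A² (d/f)² · kl/(2.3 + kl) in μm²·sr, with
  d, l the rhabdom diameter and effective length and k its absorption
  coefficient (default 0.0067 μm⁻¹, the lobster-rhabdom value that is the
  conventional stand-in for lepidopteran photoreceptors). k is a required
  explicit field in saved reports so its provenance stays visible.

Angles are held in radians internally and converted only for reporting;
report precision is 3 significant figures throughout, matching the
precision at which such metrics are customarily quoted. The physical
rhabdom length is a separate input from the effective length: doubling for
a reflective tapetum (light traverses the rhabdom twice) is an explicit
operation, never an implicit default. A superposition aperture smaller
than one facet triggers a warning rather than an error, so apposition-eye
comparisons (honeybee: A = facet diameter) remain expressible.

Assumptions: spherical eye geometry, aberration-free superposition optics,
broad-spectrum extended scenes. No ray tracing, point-spread modelling or
pigment-migration (adaptation-state) simulation is attempted.

## Ocellar lens optics (`dimeye.ocellar_optics`)

The hanging-drop measurements are reduced with four estimators:

* **Back focal distance.** BFD = |best-focus frame − reference frame| ×
  z-step × n, with n the refractive index of the medium (water, 1.33).
  The best-focus frame is the argmax of any unimodal per-frame sharpness
  score (optionally moving-average smoothed); the package deliberately
  accepts a scalar score per frame rather than raw images, so any focus
  metric — variance of intensity is the conventional choice — can feed it.
  A flat score series is an estimation error; an argmax on the stack
  boundary warns that the true focus may lie outside the scanned range.
* **Focal length.** f = s0 × (image period / object period): object
  distance times magnification. The object must be at effective infinity
  (≥ 100 mm); closer distances warn. The period ratio is taken as
  image-over-object, i.e. the magnification reading of the lens equation.
* **Michelson contrast.** M = (Imax − Imin)/(Imax + Imin) of a line
  profile perpendicular to the grating stripes, after optional
  moving-average smoothing (default window 1 = none) and trimming 10% of
  samples at each end; at least two full periods must remain. Raw min/max
  are used rather than a sinusoid fit — adequate for the high
  signal-to-noise profiles this instrumentally simple assay produces.
* **Cutoff frequency.** Unweighted ordinary least squares of contrast
  against spatial frequency; f_c is the x-intercept −b₀/b₁ and requires a
  negative slope. Contrasts at or below a floor (default 0.02) are kept in
  the record but excluded from the fit, so the flat noise tail near cutoff
  cannot lever the line; a floor of 0 disables the exclusion entirely.

Chromatic aberration and astigmatism are summarised descriptively
(per-colour / per-orientation group mean, sample sd, n). Mixed-model
inference over ocellus random effects is intentionally out of scope; the
synthetic lens generator nevertheless includes per-ocellus random
intercepts so the group summaries face realistically correlated data.

## Pigment spectra (`dimeye.pigment_spectra`)

The A1 (11-*cis*-retinal) visual-pigment template is used with its
published constants: α band S_α = 1/[exp(A(a−x)) + exp(B(b−x)) +
exp(C(c−x)) + D] with x = λmax/λ, A = 69.7, B = 28, C = −14.9, D = 0.674,
b = 0.922, c = 1.104, a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940); β band
a Gaussian of amplitude 0.26 centred at 189 + 0.315·λmax with width
−40.5 + 0.195·λmax. The β band is included by default and can be switched
off (`include_beta=False`). An A2 template is not implemented.

**Fitting.** The spectrum is normalised to unit maximum inside the fit
window (default 300–700 nm). For fixed λmax the model is linear in the
amplitude (and in the optional additive baseline), so both are solved in
closed form and the search is one-dimensional in λmax: a 1-nm grid scan
over the bounds followed by bounded scalar minimisation to 0.01 nm. This
deterministic nested scheme was chosen over generic black-box minimisers
for exact reproducibility; a test asserts equivalence with an exhaustive
0.01-nm grid search to ≤ 0.05 nm. No additive baseline is fitted by
default — a free baseline can absorb the free-retinal shoulder — and λmax
is reported to 0.1 nm.

**Bootstrap.** Confidence intervals are 2.5/97.5 percentiles of λmax over
n_boot = 1000 case resamples of the (λ, absorbance) pairs, with a
mandatory explicit seed. Resampling is implemented as multinomial count
weights, which is distributionally identical to index resampling but lets
all replicates be refit in one vectorised weighted-least-squares pass over
the λmax grid. Replicate refits refine the grid minimum by three-point
parabolic interpolation of the RSS (the RSS is locally quadratic, so this
agrees with the scalar minimiser to well under the 1-nm grid step at a
thousandth of the cost); the public point estimator keeps the bounded
scalar refinement. Replicates whose optimum pins to a grid bound count as
failures; more than 10% failures attach an unreliable-CI warning. A
200-simulation experiment in the test suite checks ≈95% coverage at noise
sd 0.02.

**UV pigments and contamination.** Free (non-covalently bound) retinal
absorbs near 380 nm and biases direct fits of UV-pigment spectra toward
it. The recommended workflow is the difference spectrum dark −
acid-denatured, which cancels the contamination exactly (it is unchanged
by acid treatment) while the denatured pigment's own band moves to
~436 nm; fitting the difference below ~400 nm then recovers the UV peak.
The subtraction direction defaults to dark − acid; the reverse is
available via the `direction` option of the CLI. Thresholds (e.g. the 5%
long-wavelength sensitivity shoulder that bounds the wavelengths an
animal can still perceive) are solved on the template by bracketed
bisection to better than 0.1 nm.

## Synthetic data (`dimeye.synthetic_data`)

Every generator is deterministic given its seed, and writes its ground
truth into the output's metadata; recovery tests read truth only from
metadata. Noise is Gaussian throughout — the assays give no reason to
prefer a heavier-tailed model — with amplitudes documented per generator:

* **Spectra**: amplitude-1 A1 template on a 300–700 nm, 1-nm grid, plus
  optional constant baseline, free-retinal contamination (Gaussian at
  380 nm, sd 30 nm — a value inside the 350–450 nm free-retinal band) and
  i.i.d. noise (typical sd 0.01–0.02 of peak absorbance).
* **Gratings**: mean-128, amplitude-127 greyscale sine or square waves,
  ≥16 samples/period, ≥3 periods, blurred by a Gaussian of angular width σ
  with circular boundary handling; for sinusoids the exact post-blur
  contrast exp(−2π²σ²f²) is recorded.
* **Z-stacks**: unit-height Gaussian focus-score bump (width default 6 μm)
  centred at the frame corresponding to the requested BFD, default 2-μm
  steps in water.
* **Lens datasets**: per-colour BFD means default 40/35/30 μm
  (red/green/blue — the longitudinal chromatic-aberration ordering), total
  sd 10 μm decomposed into a per-ocellus intercept (0.6·sd) and residual
  (0.8·sd) so that ocellus identity induces realistic correlation; focal
  length N(190, 24²) μm per ocellus.

What the generators do **not** emulate: instrument baselines that drift in
wavelength, detector saturation, scattering tails in protein eluates, 2-D
image formation (profiles are 1-D), or lens astigmatism beyond
orientation-independent means. Passing recovery tests therefore shows the
estimators are correct and calibrated under the stated noise model, not
that they are robust to every artefact of real spectrophotometry or
microscopy.

## Problem sizes and numerical choices

The recovery experiments use 50 spectra per condition (noise sd 0.01) and
the coverage experiment 200 simulations × 1000 bootstrap replicates —
sizes at which the binomial uncertainty of a coverage estimate (±1.5% at
95%) is small compared to the 5% nominal miss rate, while a full run of
the suite stays interactive. Ties in grid argmins resolve to the lowest
index (numpy convention); degenerate inputs (flat spectra, flat focus
series, all-zero intensity fields, non-decreasing contrast) raise typed
errors rather than returning sentinel values. Parse errors from the CSV
readers name file and line.

## Known limitations

* The template fitter assumes a single pigment; mixtures (e.g. co-expressed
  long-wavelength opsins a few nm apart) fit to an intermediate λmax.
* The percentile bootstrap can undercover slightly for very low noise
  where the discretisation of the 1-nm data grid dominates.
* The cutoff regression is linear by construction; a contrast curve with
  strong curvature near cutoff will bias f_c, as it would in the manual
  procedure it reproduces.
* Group summaries ignore the ocellus-level correlation their inputs may
  contain; they are descriptive, not inferential.
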