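# Methods

This note records the models the package implements, the parameter choices
that matter, and what the synthetic-data validation does and does not show.

## Chamber geometry

The chamber is modelled as four disks in a rectangle: one central well and
three outer wells on the vertices of an equilateral triangle centered on the
chamber center. The spacing parameter is the **edge-to-edge** gap between
the central well rim and each outer well rim (the fabricated chambers are
described by the gap between well rims, not between centers), so the
center-to-center distance is `spacing + diameter`. Two diameter presets are
provided — the 1.2 mm design value and the 1.63 mm as-fabricated value —
because imaging may reflect either; which one underlies a given dataset is a
registration question, so both are config presets rather than hard-coded.

Raster conventions: row-major, origin top-left, y down; pixel `(r, c)` has
its center at `((c+0.5)·ps, (r+0.5)·ps)` for pixel size `ps`. Mask
membership is a pixel-center test, chosen over area-weighted coverage for
determinism. Quadrants are assigned by half-open intervals against the crop
midline, so the four quadrant masks plus the central exclusion disk tile a
square crop exactly (asserted per-pixel in the tests).

## Diffusion model and fitting

The fitted model is the 1D instantaneous point-source solution
`I(x,t) = A₀/√(4πDt)·exp(−x²/(4Dt))`, the unique closed form consistent
with interpreting `A₀` as the total amount of diffusing substance and `x` as
radial distance from the release point. Its known idealizations, accepted
deliberately:

* the well is a finite disk, not a point. Profiles are anchored at the rim
  (the first gel pixel outside the disk) and `x` measured outward from it.
  The approximation degrades when the diffusion length `√(4Dt)` is not small
  against the well radius; with an 815 µm radius and the coefficients at
  play here (≤ ~6.4 µm²/s, t ≤ 40 min → `√(4Dt)` ≤ ~250 µm) the regime is
  acceptable, and the same approximation is baked into the fitting model, so
  self-consistency tests close exactly.
* `t = 0` frames are excluded from fits (the model is singular there); they
  are rendered as the initial condition for visual completeness only.

Fitting is a joint nonlinear least squares over every `(x, t)` sample with
`t > 0`. On normalized profiles (each time column divided by its rim value,
the default) the model reduces to `exp(−x²/(4Dt))` and only `D` is free; an
un-normalized mode fits `A₀` as well, for sensitivity analysis. The
optimizer works in log-parameters with bounds `D ∈ [1e-4, 1e4]` µm²/s, a
method-of-moments initializer (`D₀ = m₂/(2t)` from the second spatial moment
of the latest time point), and no randomness — fits are bit-reproducible.

The forward simulator is an explicit 5-point finite-difference scheme with
zero-flux (reflecting) chamber walls and time step 0.9× the stability limit
`h²/(4D)`. It conserves mass to float round-off on the closed domain and,
away from walls, agrees with the exact free-space evolution (Gaussian
convolution of the initial condition) to better than 2% along transects
where the field is above 10⁻³ of its maximum; below that the comparison is
dominated by discretization noise in both operands.

### Synthetic tracer stacks

`generate_tracer_stack` defaults to **analytic** rendering: the point-source
solution drawn radially around the well, with `x = 0` anchored at the same
rim-adjacent pixel the profile extractor uses. This choice is deliberate: a
finite-disk initial condition (the FD mode) produces erfc-like rim profiles
whose refit under the point-source model is biased at early times, while
the analytic mode makes the noiseless generate → extract → normalize → fit
loop close to within optimizer precision — the property the self-consistency
checks rely on. The FD mode remains available and is validated against its
own analytic oracle. Synthetic layouts are pixel-aligned (well centers on
pixel centers, radius a whole number of pixels) so the rendering anchor and
the extraction anchor coincide on all four profile arms; without alignment a
sub-pixel offset δ enters the exponent as `2xδ/(4Dt)` and biases the slow
tracer's recovery by tens of percent.

## Rheology summaries

Replicate frequency sweeps are reduced at 1 Hz (log-log interpolation
between grid points, since moduli of collagen gels are near power-law in
frequency; linear interpolation is an option and extrapolation is refused).
Summaries: mean ± sd (ddof = 1) of G′ and G″ across replicates;
tan δ computed from the mean moduli (the ratio of means — per-replicate
ratios are also exposed); `E′ = 2·mean(G′)·(1+ν)` with
`sd(E′) = 2(1+ν)·sd(G′)` by linear propagation; ν defaults to 0.5
(near-incompressibility of the hydrated network at 1 Hz), giving `E′ = 3G′`.
Replicate variability is interpreted as a standard deviation across
independent gels. LVER selection uses the median of the first three
strain-sweep points as the low-strain plateau and a default ±5% tolerance
band (configurable; no universal criterion exists), returning the maximal
leading run inside the band and its log-midpoint as the recommended working
strain.

## Segmentation primitives

* **Rolling ball** is realized as grayscale closing (light background) or
  opening (dark background) with a non-flat sphere-cap structuring element;
  a paraboloid element is available as the legacy variant. The output is the
  non-negative deviation from the estimated background with foreground
  positive regardless of input polarity — downstream steps only need
  "foreground bright on a flat field".
* **Contrast enhancement** clips `saturation/2` percent of pixels at each
  end and rescales to full 8-bit range, preserving rank order in between.
  It is content-adaptive by construction, which is why the confluency chain
  carries an empty-field guard (below).
* **Yen thresholding** maximizes `2·ln(P₁(1−P₁)) − ln(S₁S₂)` over histogram
  splits (`P₁` the lower-class mass, `S₁`, `S₂` the class sums of squared
  bin probabilities), ties broken toward the lowest level; integer images
  get one bin per gray level. The implementation is verified in the tests
  against exhaustive criterion maximization and against an independent
  library implementation.
* **Pixel classifier.** Interactive pixel-classification tools cannot be
  replicated bit-exactly from a written description, so the package ships an
  openly specified stand-in: per scale (1 and 2 px), Gaussian smoothing,
  gradient magnitude, |LoG| and smoothed local texture energy, plus the raw
  image, feeding a logistic model trained on labelled synthetic fixtures
  (balanced pixel sampling, weak L2 regularization `C = 100`). Scales are
  kept small and regularization weak on purpose: they set how far foreground
  evidence bleeds past object borders, and a wide intermediate-probability
  halo inflates areas whenever an automatic threshold lands near one end of
  a strongly bimodal probability histogram — which is exactly where the Yen
  criterion's tie-break puts it on near-binary maps. Weights, feature
  scales, standardization and seed serialize to JSON; prediction uses only
  the serialized numbers. A rule-based classifier (logistic squash between
  explicitly calibrated background/foreground levels) is provided for
  rendered frames with stable, known backgrounds.

## Confluency

The chain is: 8-bit conversion (identity on already-8-bit input; wider
dtypes are min-max scaled) → rolling ball (radius 6 px, light background) →
contrast enhancement (0.35%, normalized) → probability map → threshold →
area fraction over the whole image. The threshold is Yen on the probability
histogram by default, or the fixed manual 0.5 (`threshold_method="fixed"`),
which on these probability maps recovers area nearly exactly.

**Empty-field guard.** The normalized contrast stretch amplifies whatever
dynamic range a field has; on a field with no cells that is pure sensor
noise, and any threshold on amplified noise is meaningless. Fields whose
background-subtracted upper contrast percentile is below 15% of full scale
are therefore reported as empty. The floor sits between the noise plus
morphology bias of an empty field (< ~8% of scale) and the deviation a
genuine dark cell produces (> ~30%), so it is insensitive to its exact
value over a wide band.

## Synthetic migration model

The generator's motion model is a biased persistent random walk, disclosed
here as the package's own construction (a testbed for the quantification,
not a calibrated cell model). Per step of 30 min (matching the imaging
interval, so trajectory steps and frames align 1:1): the target heading is
the weighted vector mean of the previous heading (weight = persistence,
default 0.6) and the attractant gradient direction (weight = κ·g, with κ the
chemotactic bias and g the gradient magnitude normalized by its global
maximum); the realized heading is a von Mises draw around the target
(concentration 4); displacement is `speed` µm (default 10 µm per 30 min ≈
20 µm/h, a mid-range mesenchymal speed). Chamber walls reflect. Agents
start uniformly on their well's rim; non-motile types never move.

The attractant field is **quasi-static**: one snapshot of the 2D
point-source solution at a reference time (default 24 h, D = 100 µm²/s),
evaluated analytically; an FD-field option exists. At the outer-well
distance this snapshot puts the normalized gradient near its maximum, which
is the regime the chamber is designed for. Self-generated (cell-consumed)
gradients are out of scope.

Rendering draws each agent as an anti-aliased dark disk (default 30 µm
radius) on a light background (200 vs 60 gray levels) and returns exact
per-frame truth masks; rendering is deterministic given trajectories.

### Confluency image generator

Random ellipses with semi-axes 10–25 px — spread cells of ~20–50 µm at the
~1 µm/px scale of full-well brightfield frames — are unioned until the
target covered fraction is reached (each ellipse adds ≤ ~0.1 points, so the
truth fraction lands within ±0.5 points; targets above 0.99 are refused as
unreachable by random packing). Cells are darker than the background and
carry strong pixel-scale texture; the background has smooth shading (±12
levels) and mild noise (σ = 3). What this emulates: contrast and texture
segregation of cells vs. substrate under uneven illumination. What it does
not: out-of-focus halos, mitotic brightness changes, debris, or confluent
sheets with invisible cell-cell borders — so segmentation accuracy on these
fixtures bounds performance on clean data only.

## Directional statistics

Per-frame quadrant area fractions use the analyzable area (crop minus the
excluded central disk, default radius 1.05× the well radius) as the shared
denominator, so the exclusion choice rescales nothing across wells. The
bias index compares the share `s` of migrated area in the quadrants facing
the chamber center (the two whose bisectors are nearest the well→center
bearing — computed, not hard-coded, so any chamber orientation works)
against the uniform expectation `q` (the facing quadrants' share of
analyzable area): `(s−q)/(1−q)` above expectation, `(s−q)/q` below, giving
0 under uniform spread and ±1 at the extremes; wells with no migrated area
return NaN, treated as zero bias (with a warning) in group comparisons.

Group comparisons use a label-permutation test on replicate wells' terminal
bias (statistic: difference of group means; exact enumeration up to 10⁴
arrangements, seeded Monte Carlo beyond). The validation experiment
compares 5 wells with κ = 2 against 5 unbiased wells, 20 seeded runs for
power and 200 runs with both arms unbiased for type-I calibration (the
calibration path quantifies ground-truth masks directly — it is a property
of the test, not of the segmentation). With 252 exact arrangements the
smallest one-sided p is ~0.004 and the null rejection rate at α = 0.05 is
~4.8% by construction; the observed rates (100% power, 7% type-I) match.
Classical ANOVA-style inference is deliberately delegated to standard
statistical packages; the permutation test is the package's own inferential
machinery.

## Problem sizes

Validation runs use the sizes at which the properties they check are
already stable: 512²–1496×1495 px confluency fixtures, 32² histograms for
threshold oracles, 300 px migration crops with 40–80 agents per well, and a
2 mm² FD domain at 5 µm resolution for the analytic-kernel comparison.

## Known limitations

* The point-source fit ignores the finite well reservoir; absolute `A₀`
  from un-normalized fits is interpretable only up to the rim-anchoring
  approximation.
* The stand-in pixel classifier is trained on this generator's appearance
  model; applying it to real micrographs requires retraining on labelled
  real pixels (the API accepts any images/masks).
* Yen thresholding of near-binary probability maps is intrinsically
  tie-dominated; where exact areas matter, the fixed 0.5 threshold on the
  same maps is the better-behaved choice and is exposed as
  `threshold_method="fixed"`.
* The agent model has no cell-cell interactions, division, death, or
  matrix remodeling; detection-power results transfer to real assays only
  as qualitative evidence that the quantification pipeline resolves the
  designed effect size.
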