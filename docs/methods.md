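# Methods

This note records the package's modelling choices: what is computed, what
the synthetic data do and do not emulate, and where open design decisions
were settled.

## Depth map and indices

The transmittance depth map assigns every ROI pixel
`R_ij = [ln((A_i − B_ij)² + 1) · sin(π/2 · B_ij/A_i)]²`, with `A_i` the
row maximum **within the ROI** (not the full radiograph row — the ROI is
the analysis unit, and using the ROI-local maximum keeps the map invariant
to what lies outside the cropped region). Natural log is used; the base is
configurable and only rescales the map by `1/ln(base)²`. Rows with
`A_i = 0` are defined as identically zero (nothing transmitted, no depth
signal), which also makes every all-zero input legal. `R_ij = 0` exactly
when `B_ij = A_i`, `B_ij = 0` or `A_i = 0`, and
`R_ij ≤ ln(A_i² + 1)²` with strict inequality whenever the log factor is
positive. The map is computed in floating point from the 8-bit integers
with no intermediate quantization.

**Xpar** is the arithmetic mean of the map. The source formulation reports
a single per-image value without stating the reduction; the mean was
chosen because it is interpretable (average depth variation per pixel),
robust, and makes the zoom-invariance results exact: nearest-neighbour
zoom by an integer factor duplicates each pixel into an f×f block,
preserving row maxima and every row's value multiset, so Xpar and Power
Xpar are exactly invariant while Pixel Count scales by f².

**Power Xpar** is `scale · (mean(R^p))^(1/p)`, a scaled generalized power
mean, defaults `p = 2`, `scale = 10`. The construction is described
upstream only as an "exponential computation from the distribution and
magnitude" of the depth values; a power mean with `p > 1` is the simplest
monotone functional that weights the large-value tail more heavily than
the mean, which is exactly the sensitivity to concentrated heterogeneity
the index is meant to provide. Whether the clinical implementation uses a
true exponential (`e^x`) instead is unknowable from the description; both
`p` and `scale` are configurable, and no numerical acceptance is tied to
this choice. The defaults place synthetic cohort values inside the
descriptive range reported for clinical dentin–pulp ROIs (roughly 91–175).

## Imaging conventions

* 0-based, row-major indexing; half-open ROI rectangles.
* 8-bit working depth. Deeper stored data are min–max rescaled on read
  with round-half-to-even: deterministic and window-free. Whether the
  clinical pipeline analyses 8-bit exports or deeper DICOM data is not
  stated; 8-bit is assumed throughout.
* Digital zoom maps output pixel centres by
  `x_in = (x_out + 0.5)/f − 0.5` (align-corners-false), edge-clamped, with
  nearest/bilinear/bicubic kernels; the output is clipped to [0, 255] and
  re-quantized. Downsampling (f < 1) is rejected as out of scope.
* Sobel magnitude uses the standard 3×3 kernels with reflect padding,
  avoiding spurious responses at the ROI frame; it is invariant under
  adding a constant to the image.

## The phantom generator

Each phantom emulates a rectangular dentin–pulp ROI: a bright dentin field
(default mean 190, vertical gradient 0.25/px), a darker canal region,
Gaussian blur (σ = 1.1 px, detector/projection unsharpness), additive
white Gaussian noise (σ = 2.0), then 8-bit quantization. White noise after
blurring is the simplest stationary model producing realistic grain; a
Poisson option was considered and deferred.

Canal geometry: the simple canal is a straight vertical ribbon of
thickness `canal_width` (a capsule — constant width with rounded caps);
the C-shaped canal is an annular arc ribbon of the same thickness spanning
`c_arc_span` radians. The two shapes share the same **discrete** area
budget: the capsule length is matched numerically to the pixelized arc
area, because the continuous `span·r₀·width` budget drifts by a few
percent after pixelization and would otherwise leak the class label into
total darkened area. A constant-width band (rather than a tapering
ellipse) was chosen for the simple canal for the same reason: a tapered
shape dilutes differently under blur than a constant-thickness ribbon,
which would make morphology alone — rather than the intended
heterogeneity knob — a confounded discriminator. An optional
`lateral_falloff` darkens the ROI's lateral edges; its default is 0
because a shaded base interacts with canal shape (the wide arc reaches
darker columns than the straight band) and biases the shape comparison.

A known residual: even with matched areas and thickness, the row-max
normalization interacts with how the arc distributes canal pixels across
rows under noise (rows the arc crosses contain fewer dentin pixels, hence
slightly lower row maxima). At a null heterogeneity setting this leaves a
shape effect of roughly 0.25 SD on Power Xpar; oriented null-cohort AUCs
stay within [0.35, 0.65].

## The cohort generator

The default `CohortSpec` encodes the emulated study frame: 22 C-shaped vs
21 control teeth in two native-resolution groups (split 10+16 and 12+5),
sex ~ Bernoulli(0.674 male), age group ~ Bernoulli(0.558 younger), side
uniform — all generated with **no** true effect on the texture metrics,
mirroring the reported absence of sex/age differences. The higher-native-
resolution group gets a 0.8× noise multiplier, which narrows its index
spread (as seen in the reported group descriptives) and makes the
resolution indicator an informative covariate for the logistic layer.

The **heterogeneity knob** is the single label-linked dial: C-shaped teeth
draw the knob from N(1 + δ, 0.15) (controls from N(1, 0.15)), and it
multiplies both canal contrast (base 12 gray levels) and canal width
(base 6 px) — a more prominent ribbon. Default δ = 0.6 yields strong but
imperfect discrimination for Power Xpar at the 43-tooth scale. δ = 0 gives
a null cohort.

The **volume covariate** is normal with common SD 76.25 mm³, control mean
383.86 mm³ and a standardized group difference `volume_effect_d`
(default 0.90), anchored to the printed group means; pulp length is
N(21.7, 1.4) mm with no group effect. ROI geometry: area ~ N(1950, 330)
px² clipped to [1300, 2650], aspect ratio (height/width) ~ U(1.6, 2.1) —
tall rectangles whose pixel counts match clinical dentin–pulp ROIs. The
source material gives no ROI pixel dimensions beyond count ranges, so the
aspect ratio is a free choice.

The **zoomed condition** magnifies each phantom by a factor drawn from
U(1.25, 1.40) (bilinear by default), then re-selects the ROI with up to
10% per-axis shrink and a random offset — a reader re-drawing the region
on the magnified image. Zoomed pixel counts therefore always exceed the
native counts without being exact multiples of them, and the area ratios
(~1.3–1.85, mean ≈ 1.57) match the magnitude of the reported
zoomed/non-zoomed stratum ratios. Everything is driven by a
`SeedSequence`, so identical specs produce bit-identical cohorts.

What the generator does **not** emulate: anatomically faithful tooth
rendering, panoramic projection geometry, detector-specific noise spectra,
inter-observer ROI variability beyond the jitter model, or any correlation
between the volume covariate and the texture metrics. Passing tests
therefore demonstrate the correctness and internal consistency of the
measurement and statistical machinery on data with the study's assumed
structure — not clinical diagnostic performance.

## Statistical layer

* Mann–Whitney U with rank-biserial effect size `r = 1 − 2U/(n₁n₂)` (U of
  the first group; r = +1 at complete separation of A below B). Exact p
  when min(n₁, n₂) ≤ 8 without ties, tie-corrected normal approximation
  otherwise.
* Wilcoxon signed-rank: zero differences dropped; standardized
  `Z = (W⁺ − n(n+1)/4)/σ` with tie-corrected σ, positive Z when the first
  sample tends larger. Exact p by exhaustive sign-flip enumeration on
  midranks for n ≤ 12 non-zero pairs; all-zero differences return a
  flagged degenerate result with p = 1.
* ROC: rank (Mann–Whitney) AUC with midranks. Direction is chosen so the
  positive class has the higher mean score (ties → higher-is-positive);
  candidate thresholds are midpoints between adjacent distinct scores plus
  sentinels; ties in Youden J break toward higher specificity (mirroring
  the specificity-1.00 optima typical of small strata); the reported rule
  is `>=` or `<=` per direction, and `J = sens + spec − 1` holds exactly.
* Logistic models: maximum likelihood (statsmodels Logit); continuous
  predictors standardized per 1 SD; Wald ORs/CIs on the log-odds scale; LR
  test against the intercept-only model; in-sample AUC of fitted
  probabilities (the upstream report does not state cross-validation, so
  in-sample is implemented). Separation is detected (divergence,
  non-finite SEs, |log-odds| > 15) and flagged, with a lightly
  ridge-penalized IRLS fit (λ = 0.01, intercept unpenalized) keeping the
  flagged output finite — never silent.
* No multiple-testing adjustment anywhere, and no normality gating: the
  pipeline defaults to nonparametric tests for the texture metrics, with
  the t test available explicitly. Both mirror the source analysis.
* Power design: exact power of the two-sided two-sample t test via the
  noncentral t (df = 2n − 2, ncp = d·√(n/2)); the minimum n search starts
  at the closed-form normal-approximation bound and is therefore never
  below it. The Monte-Carlo check vectorizes all replicates in one pass.

## Report pipeline

`run_study` executes generate → measure → describe → paired-compare →
model → ROC deterministically under a fixed seed, logging per-stage
counts. The ROC table is stratified exactly as resolution group ×
condition × metric; strata where either class has fewer than 3 teeth are
reported as not-estimable rather than dropped (the unbalanced 12-vs-5
split makes this path reachable). Matching of cases to controls is treated
as a property of the generated cohort, not re-implemented as a matching
algorithm. All tables serialize to CSV and a JSON summary carrying the
config fingerprint and seed.

## Problem sizes used in validation

The validation suite runs null cohorts at 100 teeth per class, effect
cohorts at 50 per class, depth-map oracle checks on 16×16 ROIs, and the
Monte-Carlo power check at 10,000 replicates — sizes at which the
Monte-Carlo tolerances quoted in the tests are comfortably resolved on a
single CPU in seconds.

## Known limitations

* The residual null-cohort shape effect described above (~0.25 SD on
  Power Xpar at δ = 0).
* The Power Xpar construction is one defensible reading of an
  under-specified description; absolute Power Xpar values are therefore
  not comparable to other implementations, though ordering and
  invariance properties are.
* Default generator settings produce stronger class separation than the
  clinical report's stratified AUCs at equal n; reproducing clinical
  numbers is explicitly out of scope (the radiographs are not public).
* Single-frame grayscale I/O only; no multi-frame DICOM, color, or
  monitor-calibration modelling.
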