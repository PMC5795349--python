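# Methods

This note documents the models, numerical choices and limitations behind
phenomap, in the order the pipeline runs them.

## Experimental design

The bundled design is a 10-row × 16-column greenhouse grid: 156 plants of 32
maize inbreds plus 4 empty control pots. Each sequential pair of rows is one
complete replicate; within a replicate, genotypes are grouped into half-row
blocks of 8, and only the order within a block is randomized between
replicates. One genotype (ZL22) is present in a single replicate; the other
four replicates carry an empty pot in its place. `design.generate_design(seed)`
keeps the genotype-to-block composition fixed and permutes within blocks, so
every seed yields a valid instance of the same design family;
`design.paper_design()` returns the canonical layout unmodified. Invariants
(156/4 occupancy, 32 genotypes, no within-replicate repeats, ZL22 singleton)
are validated on construction.

## Segmentation rules

All thresholds are strict inequalities, as the rules are conventionally
stated: green index 2G/(R+B) > 1.15 (RGB), NDVI > 0.25 and stem ratio
R₁₀₅₆/R₁₁₅₁ > 1.2 (hyperspectral), red > 70 (fluorescence). Degenerate
pixels are defined explicitly: a black RGB pixel has green index 0, a pure
green one +∞; an all-zero NDVI denominator gives 0 (background); a zero stem
denominator with a positive numerator counts as stem. Band lookup for the
R-symbols is nearest-neighbor on the cube's wavelength grid, ties toward the
lower band. Leaf = plant ∧ ¬stem by definition, so stem and leaf partition
the plant mask exactly on any input — this is tested as a property, not an
example.

Exclusion rectangles (for reflective frame columns in real imagery) and
fluorescence ROIs are configuration, defaulting to none/full-frame for
synthetic data: the originals' pixel coordinates are instrument-specific and
unpublished.

## Geometry and zoom calibration

Height and width are inclusive bounding-box extents of the mask (a plant in
rows 10–109 is 100 px tall); area is the pixel count. Calibration constants
are 0.746 mm/px (zoom 1) and 1.507 mm/px (zoom 2) for side views; a day →
zoom schedule selects the factor. `area_adj = area_px · (mm/px ÷ 0.746)²`
puts all areas on the zoom-1 pixel footprint. The top view has no published
calibration and is reported in pixels only. An empty mask propagates NA to
every field; NA is encoded as an empty CSV field.

## Hyperspectral processing

Cubes are stacks of single-band grayscale images on a strictly increasing
wavelength grid, by default 243 uniformly spaced bands over 546–1700 nm (the
real instrument's exact spacing is unpublished; uniform is the neutral
choice, and any grid can be supplied). On disk a cube is one folder per
wavelength (integer nm) holding the band image; plane data round-trips
bit-exactly, while non-integer band centers must be re-supplied at read time
because the folder names are rounded. Three-channel grayscale band images
are accepted and collapsed.

Normalization divides each plant pixel's band intensity by the mean of the
non-plant pixels of the same band and image (median available by
configuration). The background acts as an internal illumination reference:
any global lamp factor multiplies plant and background alike and cancels,
which is the purpose of the step; a zero-background band is an error naming
the band. PCA false-coloring fits a pixels × bands PCA on the pooled plant
pixels of all supplied cubes (pooling makes colors comparable between
plants; per-cube fitting is available), min-max rescales each component's
scores to [0, 1] over the pooled pixels, quantizes with round-half-up to
8 bits, and writes PC1/PC2/PC3 to R/G/B with non-plant pixels black. A
zero-spread component renders as 0. PCA runs on normalized intensities by
default (a flag allows raw), since normalization is what makes pixels from
different images commensurable.

## Heritability

Per trait and day, `y_ij = μ + α_i + γ_g(i,j) + ε_ij` with row (or
replicate) and genotype as categorical fixed effects, fitted by least
squares with sequential (type-I) sums of squares, environment entered before
genotype. The design is near-balanced so ordering effects are small, and the
environment-first order matches the model statement. The statistics are SS
ratios, not REML variance-component ratios:

- adjusted: HR = SS_γ / (SS_ε + SS_γ) from the row+genotype fit;
- classical: H̃R = SS̃_γ / SS̃_total from the genotype-only fit.

Because the classical denominator retains row-driven variation, positive row
variance depresses the classical statistic relative to the adjusted one —
the package reproduces this ordering in simulation. NA values are dropped
per day; genotypes left with fewer than two plants (ZL22) are excluded
because they cannot separate genotype from error; aliased terms raise a
named error. Residual sums of squares within 1e-10 of the response's scale
are snapped to exact zero so that noise-free fixtures decompose exactly; an
all-zero decomposition yields NaN with a warning.

A caution for interpretation: the SS ratio is not an unbiased estimate of
σ²γ/(σ²γ+σ²ε). For k genotypes with n replicates, E[SS_γ] ≈ (k−1)(nσ²γ+σ²ε)
and E[SS_ε] ≈ k(n−1)σ²ε, so with σ²γ = σ²ε and the 32×5 design the statistic
concentrates near 0.59, not 0.50; the simulation tests assert this
finite-sample value, not the asymptotic variance ratio.

Smoothing is a Gaussian-kernel local mean over the day grid (default
bandwidth 2 days; truncated kernels at the endpoints). The smoother choice
is ours — no specific method is prescribed — and any kernel local mean keeps
the output inside the range of the input, which is the tested invariant.

## Biomass error decomposition

The univariate model regresses fresh biomass on zoom-adjusted side-view
pixels; multivariate models add the other five features. Fits are in-sample,
matching how fit correlations are conventionally reported for this analysis;
there is no cross-validation by default. Random Forest and SVR are thin
seeded scikit-learn adapters; MARS requires the optional py-earth package
and raises a clear error when absent.

Residuals (measured − predicted) are decomposed with the replicate+genotype
model; the genotype share SS_γ/(SS_ε+SS_γ) is the genotype error fraction. A
permutation null (residuals shuffled across plants) calibrates what "no
systematic error" looks like: its mean is close to the df ratio
(k−1)/((k−1)+k(n−1)−(r−1)) rather than 0. With genotype-dependent density in
the generator, the density-blind univariate model exceeds the null's 95th
percentile by a wide margin. The fraction equals exactly 1.0 only when
residuals are constant within genotype, which requires the predictor to
carry no within-genotype information (e.g., identical plant sizes with
density differences) — with within-genotype size variation the fraction is
necessarily below 1 even without noise, since the residual `(d_g − b)x − a`
varies with size x.

## Synthetic generator

The generator is the study's in-silico twin and the source of all oracles.

- **Growth.** μ_t is logistic (asymptote 220 px on the 400×300 default
  canvas, rate 0.35/day, midpoint at 55% of the run), matching the
  sigmoid growth of greenhouse maize; no functional form is prescribed, so
  the logistic is our choice. Days before emergence (default day 3) have
  height 0 and segment to NA downstream.
- **Variance components.** Height: genotype 150, row 25, error 50 px²
  (γ drawn once per genotype, α once per row, ε per plant-day) — a
  mid-experiment heritability around 0.75, typical for height on such
  platforms. Width uses the same model scaled by 0.45.
- **Monotone envelope.** The raw additive-model draws are not monotone in
  time (ε is i.i.d. per day), so renderers consume the running maximum per
  plant — a real plant does not shrink — while the heritability pipeline
  uses the raw values, whose covariance structure is exactly the stated
  model. The `panel` carries both columns.
- **Phantom geometry.** Stem = axis-aligned rectangle spanning exactly the
  planted height; leaves = horizontal ellipses whose widest spans exactly
  the planted (odd) width, kept inside the stem's row range. Ellipse radii
  are padded by 0.5 px because the rasterizer excludes the exact boundary.
  This makes truth bounding boxes analytic, which is what the closure tests
  exploit. Top views are crossed ellipses; their truth is measured from the
  mask.
- **Colors and spectra.** Plant RGB colors have green index 2.9–4.5 against
  a gray background at exactly 1.0, so thresholding is unambiguous by
  construction. Hyperspectral tissue templates are piecewise-linear
  reflectance curves: both tissues carry a red edge (NDVI ≈ 0.43–0.59 at
  the 705/750 bands), the stem adds a 1056-nm bump against 1151 nm (ratio
  ≈ 1.48 vs ≈ 1.06 for leaf), and the background is spectrally flat
  (NDVI 0). Cubes are quantized to 8 bits at digital-number scale 160.
- **Illumination drift.** One multiplicative lognormal factor per image
  (log-sd 0.05 by default); drift exists in the real chamber but its form
  is unpublished, and a global scalar is the form the normalization step is
  designed to cancel. Zero drift renders bit-identically.
- **Biomass.** fresh g = density(genotype) × adjusted side area + N(0, 5 g),
  with densities lognormal around 0.04 g per adjusted pixel (log-sd 0.25)
  drawn once per genotype from the seed, or supplied explicitly. The
  genotype-dependent density is the mechanism that makes density-blind
  predictors systematically wrong per genotype.
- **Determinism.** Every output is a pure function of (design, config,
  seed); string-keyed streams are seeded through CRC32, so runs reproduce
  across processes.

What the generator does **not** emulate: leaf occlusion and curvature,
specular pot reflections, shadows, camera noise and blur, non-global
illumination gradients, stem lodging, and the thermal-IR channel. Passing
closure tests therefore shows the algorithms implement their definitions
exactly, not that the thresholds are robust on real imagery — threshold
robustness is exactly what the real dataset's reflective-column exclusions
and NA conventions deal with.

## Problem sizes in the test and acceptance runs

Tests run the generator at a 200×150 canvas, 40 bands and 8 days; closure
and oracle checks use 100 scenes/images at 100×100; heritability recovery
uses 200 simulated experiments of the full 10×16 design at one day;
permutation nulls use 100 permutations. These sizes make the suite complete
in about a minute while keeping every check exact or tightly concentrated.

## Known limitations

- Fixed-effect SS ratios, not REML: no standard errors on HR, and the
  finite-sample inflation described above.
- In-sample biomass fit statistics; predictive accuracy on held-out plants
  is not the target quantity of the error decomposition.
- The real deposit's exact file naming is not fully specified by its
  description; the dataset walker's per-file parsing is pluggable for this
  reason.
- Top-view traits are pixel-only (no calibration); thermal IR is indexed
  but not processed.
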