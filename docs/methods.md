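# Methods

## The scientific model

The package operationalizes "retinal configuration" as the rate at which
retinal ganglion cell (RGC) density rises from the retinal periphery to
the fovea, and relates it across species to saccadic head/eye movement
behavior while controlling for phylogeny. Three models are chained:

1. a **spatial model** of the wholemount: a density surface with a single
   off-center foveal peak, measured through stereological counting frames;
2. a **measurement model**: topographic-map interpolation, fovea
   localization, and linear transect slopes as the configuration proxy;
3. a **comparative model**: generalized least squares with a
   Brownian-motion covariance scaled by Pagel's λ.

## Synthetic retinas

The generator's density surface over a circular wholemount of radius R is

    density(p) = base + (peak − base) · (1 − d(p))^s(p)

where d(p) ∈ [0, 1] is the normalized distance from the fovea to the
margin along the ray through p (0 at the fovea, 1 at the margin) and s(p)
is the fall-off exponent of the quadrant containing p. Quadrants (nasal,
temporal, dorsal, ventral) are delimited by the two diagonal meridians
through the fovea. The form is monotone along every ray, attains both
endpoints exactly, and brackets all values in [base, peak]. s = 1 is a
linear ("smooth") profile; larger s concentrates density near the fovea
("steep"). Optional multiplicative lognormal noise with coefficient of
variation `noise_cv` (unit mean) perturbs the surface before counting.

Counting frames follow the stereological sampling model: a site's count is
Poisson with mean density × counted area, where the counted area is
`frames_per_site` square frames of side `frame_side` µm (default 50 µm,
0.0025 mm²). Densities of a few thousand cells/mm² put only ~10 cells in
a single 50 µm frame, which is far too noisy a per-site estimate for
exact (non-smoothing) interpolation; pooling several frames per site
(pipeline default 25, ≈ 60–250 cells per site across the density range)
is the standard stereological remedy and brings the per-site coefficient
of variation to ~6–13%. Sites are uniform-random or on a lattice,
configurable, since real site layouts vary by laboratory.

Default study conditions: 29 species; radius 6 mm; base 500 and peak
4000 cells/mm² (chosen so that, with density expressed in 10³ cells/mm²,
transect slopes fall in the ~2.5–3.6 range the field reports for
single-foveate birds); per-species fall-off exponents uniform on
[0.4, 1.3]; mean fovea position (−0.145, 0.057) normalized units with
per-retina jitter SD 0.05; 2–5 retinas per species; field noise CV 0.05.

Traits evolve as y = β0 + β1·x + ε with ε ~ MVN(0, σ²V(λ)), x the
species' analytic ground-truth overall slope (see below) — never the
measured one, so trait generation is independent of the measurement
pipeline. Head movement rate is generated on the log scale (it is modeled
on the log scale downstream); degree of eye movement on the natural
scale; eye axial length is lognormal around 12 mm and independent of
slope, matching its role as a negative control.

## Topographic maps and fovea geometry

Site densities (count / counted area) are interpolated linearly on a
Delaunay triangulation of the sites (exact at sites), with
nearest-neighbor fill between the convex hull and the outline; negative
interpolants are clipped to zero; cells outside the outline are masked.
Nearest-only interpolation is available. Isodensity contours use
marching squares on the masked grid; a level below the field minimum
returns the outline itself (the whole retina lies above it), a level
above the maximum returns nothing.

The fovea is the global density maximum; plateau ties resolve to the
centroid of the largest maximal connected region. On maps interpolated
from noisy counts the raw argmax rides on single-site noise, so
`locate_fovea(field, smooth_mm=...)` can first smooth with a disk mean;
the pipeline uses the mean site spacing √(area/n_sites) as the radius.
Localization accuracy is then limited by the site spacing, not the grid:
with 200 sites on a 6 mm retina, typical error is ~0.3–0.5 mm, and the
recovered across-species mean fovea position is slightly attenuated
toward the retinal center (density falls more gently on the side of the
retina farther from the off-center fovea, so noise perturbs the peak
preferentially in that direction). On noiseless fields with a shared
fall-off exponent the peak is recovered within one grid step.

Fovea position is normalized by the outline: center = centroid, radius =
equal-area circle radius, coordinates = offset / radius. For left eyes
the horizontal axis is mirrored so that temporal is negative for both
sides. The stored sign convention is **negative x = temporal, positive
x = nasal, positive y = dorsal** — chosen so that the dorso-temporal
average fovea of single-foveate birds has x < 0, y > 0. Across-species
summaries use the t interval mean ± t(1−α/2, n−1)·SD/√n.

## Transect slopes

Four transects run from the outline intersection of each axis ray to the
fovea. Density is recorded at n equally spaced points (default 10) as the
disk mean of the field within one grid step of the point (emulating an
averaged local reading; the disk test carries a 1e−9 relative tolerance
so cells exactly one step away are included at every scale). Distances
are normalized to [0, 1] margin→fovea and densities to 10³ cells/mm²;
the OLS slope of density on distance is the configuration proxy, the
overall proxy the arithmetic mean of the four axis slopes. Because both
axes of the regression are normalized, the slope is exactly invariant to
retina size — the structural counterpart of the empirical check that
slope is unrelated to eye axial length.

For the planted profile the population OLS slope over t ∈ [0, 1] of
base + (peak − base)·t^s is

    slope(s) = (peak − base) · 6s / ((s + 1)(s + 2)),

which the pipeline uses as the analytic ground-truth predictor in trait
simulation. Note slope(s) increases with s only for s < √2 and saturates
beyond: once density concentrates very near the fovea, a straight trend
line stops getting steeper. Steepness-recovery checks therefore work in
the sub-linear-to-linear regime (exponents ≈ 0.3–1.3), which is also
where the generator's defaults live.

## Regional comparison

The four within-species axis slopes are treated as independent
observations in a one-way fixed-effects model — replicating the standard
design, and a documented caveat, since it ignores the species pairing; no
mixed-effects alternative is provided. Unbalanced tables are accepted and
degrees of freedom follow observed counts. Pairwise comparisons use Tukey
HSD: q = |mᵢ − mⱼ| / √((s²ₚ/2)(1/nᵢ + 1/nⱼ)) referred to the studentized
range with (k, N − k) parameters; with two groups this is exactly the
pooled t test. Reported per-region mean ± dispersion summaries in the
comparative literature are not always consistent with the accompanying F
statistic; when emulating such data the within-group SD should be
calibrated to the F and its degrees of freedom rather than to the printed
dispersions (the test suite does exactly that).

## PGLS

The Brownian covariance V has V[i,j] = root-to-MRCA shared path length
(a root edge, if present, is shared by all tips); Pagel's λ multiplies
the off-diagonals. λ = 0 is OLS structure, λ = 1 full Brownian. The fit
whitens through a Cholesky factor of V(λ) (no explicit inverse);
λ̂ maximizes the profile log-likelihood (ML default, REML selectable)
over a 101-point grid followed by bounded refinement to 1e−6, with
boundary optima returned exactly as 0 or 1 — matching how comparative
analyses report "λ = 0" and "λ = 1". σ̂² = RSS_gls/(n − p), so rescaling
all branch lengths by k leaves λ̂ unchanged and divides σ̂² by k.

The F test compares the fitted model to the intercept-only model under
the same λ̂, with conventional (q, n − p) degrees of freedom; a label in
the (parameters, residual-df) style some packages print (e.g. "F_2,27"
for one predictor and n = 29) is provided alongside. R² is the GLS
coefficient of determination; the headline value is adjusted R² (which
can be negative). Standardized whitened residuals are reported, and
values beyond ±3 flagged — not removed. Head movement rate enters models
as its natural log.

Estimated-λ inference is approximate: the F test's empirical size at
α = 0.05 under a 29-tip Brownian null measures ≈ 0.045–0.055 (computed,
not assumed, by the acceptance script and test suite).

## Numerical and design choices

- Interpolation method, transect point count (10), grid step, site
  layout, frame pooling, λ mode, and α are all configurable; defaults are
  logged in the run manifest.
- Flat fields: contour below-minimum → outline; fovea on a flat field →
  rejected ("no unique fovea"); flat transect profile → slope 0 with
  r² = 0 and a flag.
- Degenerate inputs rejected with explicit messages: collinear counting
  sites, fovea outside the outline, singular designs, non-PSD transformed
  covariances, tip mismatches (listing the offending species), malformed
  newick, negative or missing branch lengths.
- Determinism: every stochastic operation takes a seed; a fixed study
  seed yields byte-identical artifacts.

## What the tests do and do not show

Synthetic retinas are ideal circles with a single smooth peak, isotropic
within quadrants; real wholemounts have relaxation cuts, irregular
outlines, staining artifacts, and secondary specializations, none of
which are modeled. Passing tests show the estimators are correct and
calibrated under the stated generative model — unbiased density
estimates, nominal CI coverage and F-test size, recovery of planted
foveas, slopes, regression coefficients and λ — not that any biological
conclusion holds for real retinas. Heavy simulation properties run at
reduced replicate counts and grid resolutions in the default suite
(e.g. power checks at the trait level with dozens of replicates, null
p-uniformity at 400 replicates); the acceptance script reports the
problem sizes it used alongside each quantity.
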