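# foveate

Tools for asking whether **retinal configuration moves the head and eyes of
foveate birds**: how steeply retinal ganglion cell (RGC) density rises from
the retinal periphery to the fovea, and whether species with steeper
gradients — hence a smaller retinal region of high visual acuity — show
more head and eye movement, once shared evolutionary history is accounted
for.

The package is aimed at visual ecologists and comparative biologists. It
covers the full chain from stereology-style cell counts to comparative
inference:

1. **Synthetic wholemounts** — circular retinas with a single off-center
   foveal density peak, per-quadrant fall-off exponents, multiplicative
   lognormal field noise, and Poisson counting-frame sampling; plus trait
   evolution on a phylogeny under Brownian motion with Pagel's λ. Every
   downstream stage can be tested against planted ground truth.
2. **Topographic maps** — counting frames (count / frame area) interpolated
   onto a masked grid, isodensity contours by marching squares, fovea
   localization at the density peak, and fovea position normalized to the
   retinal center: x < 0 temporal, x > 0 nasal, y > 0 dorsal, with
   left-eye mirroring so both eyes are comparable.
3. **Gradient slopes** — transects along the nasal, temporal, dorsal and
   ventral axes from the margin to the fovea; density (10³ cells/mm²) is
   regressed on normalized distance (0 = margin, 1 = fovea) and the OLS
   slope is the retinal-configuration proxy. Normalization makes the slope
   independent of retina size.
4. **Inference** — a one-way GLM comparing slopes among the four retinal
   regions with Tukey HSD pairwise tests, and from-scratch **phylogenetic
   generalized least squares**: for tip covariance V with
   V[i,j] = shared root-to-MRCA path length,

   y = Xβ + ε,  ε ~ N(0, σ² V(λ)),  V(λ) = λ·V_offdiag + diag(V),

   with λ̂ maximized over [0, 1] by profile ML (or REML), boundary optima
   returned exactly, and an F test of the predictors against the
   intercept-only model under the same λ̂.

## Worked example

Build a steep dorso-temporal retina, count it, map it, and measure it:

```python
import foveate as fv

spec = fv.RetinaSpec(
    radius=6.0, fovea_xy=(-0.145, 0.057),
    base_density=500.0, peak_density=4000.0,
    quadrant_steepness={"nasal": 0.7, "temporal": 1.1,
                        "dorsal": 1.2, "ventral": 0.9},
)
field = fv.generate_density_field(spec, grid_step=0.05)
frames = fv.sample_counting_frames(field, n_sites=400, frame_side=50.0,
                                   frames_per_site=50, seed=0)
rec = fv.build_topographic_map(frames, field.outline, grid_step=0.05)
fovea_mm = fv.locate_fovea(rec, smooth_mm=0.5)
pos = fv.normalize_fovea_position(fovea_mm, rec.outline, eye_side="right")
print(f"fovea (mm): ({fovea_mm[0]:.2f}, {fovea_mm[1]:.2f})")
print(f"fovea (normalized): x = {pos.x:.3f}, y = {pos.y:.3f}")
slopes = fv.slopes_for_field(rec, fovea_mm)
for axis in (*fv.AXES, "overall"):
    print(f"{axis:9s} slope = {slopes[axis].slope:5.2f}")
```

prints

```
fovea (mm): (-0.60, 0.35)
fovea (normalized): x = -0.100, y = 0.058
nasal     slope =  3.04
temporal  slope =  3.56
dorsal    slope =  3.50
ventral   slope =  3.20
overall   slope =  3.33
```

The fovea planted at (−0.87, 0.34) mm is recovered to within the counting
site spacing, its normalized position lands in the dorso-temporal quadrant
(x negative, y positive), and the per-axis slopes recover the planted
steepness ordering: the steep dorsal/temporal quadrants fit higher slopes
than the shallow ventral/nasal ones. Slope units are 10³ cells/mm² per
unit of normalized margin-to-fovea distance.

The comparative layer is a scikit-learn style estimator:

```python
model = fv.PGLSRegression(tree=tree, lam="ml").fit(X, y)   # X, y indexed by species
model.coef_, model.lambda_, model.fstat_, model.pvalue_, model.r2_adj_
```

`fv.run_study(fv.StudyConfig(...))` (or the `foveate` CLI: `simulate`,
`maps`, `slopes`, `fovea`, `regions`, `pgls`, `run-all`) orchestrates the
whole study: per-species slope table, fovea position summary with t-based
confidence intervals, the four-region GLM + Tukey comparison, and the
twelve-model PGLS battery ({log head movement rate, degree of eye
movement} × {overall + four axis slopes}, eye movement ~ log head rate,
and the overall-slope ~ log axial length size check), with a manifest
capturing config and seed.

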