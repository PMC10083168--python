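# Methods

## Measurement model

A macular OCT raster volume is indexed `(b, z, x)`: B-scan (slow axis),
axial row (depth, vitreous at the top) and A-scan column (fast axis). The
default `ScanGeometry` is a 20° raster of 25 lines at 221 µm spacing, each
B-scan 512×496 px covering 5.3 mm laterally and 1.9 mm in depth, giving an
anisotropic voxel of 10.35 × 221 × 3.83 µm (8.763·10⁻⁶ mm³). En-face
coordinates place an A-scan column's centre at `x = (x_index + 0.5)·L/n_x`
and a B-scan line at `y = b_index·Δy`.

All regional measurement is anchored on the **nulla**, the deepest point of
the inner limiting membrane (ILM) inside the foveolar depression. Anchoring
on an image landmark rather than on scan placement removes the operator-
dependent localisation error that anaesthetised, non-fixating animals
otherwise introduce.

Pipeline per eye: semantic label volume → ILM depth map (first retina row
per column; columns without retina are invalid) → nulla → nulla-centred
region masks → voxel counting. "Deepest" is the **largest axial row index**
(posterior direction increases with row). The measurement is pure: the same
labels and configuration always give the same volumes.

### Nulla detection

The integer ILM depth map is median-filtered (odd window, default 5; 1
disables) first along each B-scan profile, then across B-scans, and the
argmax is taken over valid columns within a search disc (default radius
1.5 mm) about the scan centre. Because the depth map is quantised at
3.83 µm while a foveal pit is locally flat, the maximum is typically a
*plateau* tens of µm wide, not a single column. Ties are therefore broken
by distance to the **centroid of the tied deepest plateau** — an unbiased
estimate of the pit centre — computed over the full valid map so that the
search-window boundary cannot clip the plateau asymmetrically; remaining
ties fall back to distance-to-scan-centre, then smallest B-scan, then
smallest A-scan index. On a perfectly flat surface the plateau is the whole
window and the rule degrades to "nearest the scan centre". No sub-pixel
refinement is attempted; the slow-axis quantisation of 221 µm is accepted
and shows up as a ≤1 B-scan recovery error on phantoms.

### Region masks and volumes

A column belongs to the region containing its en-face centre (half-open
intervals, no partial-area weighting): `r < 0.5 mm` → S1; `0.5 ≤ r < 1` →
inner ring; `1 ≤ r < 1.5` → outer ring; else outside. Sectors use the
ETDRS-style diagonal (±45°) boundaries, superior toward smaller B-scan
indices; for right eyes nasal is the +x side by default and left eyes
mirror it (configurable, as is the sector↔slice naming). Quadrants are
defined by composition, `Q_k = S1/4 + inner + outer slice of the sector`,
which makes ΣS = ΣQ = ΣZ exact by construction. Masks whose 3-mm footprint
crosses the scan edge are computed on the available columns and the clipped
share of the ideal footprint lattice is reported (`clipped_fraction`); no
extrapolation. Volumes count retina voxels over the full scan depth of each
assigned column ("cylinder" interpretation) times the voxel volume; no
interpolation between the 25 B-scans.

**Known discretisation bias.** Counting whole 221 µm slabs by their column
centres overestimates the area of the 0.5 mm-radius central disc centred on
a raster line by +4.9% (closed-form), with ±~0.5% lateral/axial
quantisation on top; at default geometry the measured central-disc volume
of a flat phantom is ~5.3% above the analytic disc volume. The bias falls
to 1.3% / 0.2% at 2× / 4× lateral sampling. Outer annuli are less affected
(−2% for the 1–1.5 mm ring). Tests bound the central disc at 6–6.5% and
other regions at 5% against the analytic oracle; this is a property of
25-line raster volumetry itself, not of the implementation.

### Segmentation stand-in

The package does not ship a learned segmenter (trained weights are not the
contribution; real label maps can be ingested directly). Its deterministic
segmenter classifies pixels by nearest configured class intensity
(equivalent to midpoint thresholding; defaults 20/160/100/200 for vitreous/
retina/choroid/sclera) and then, per A-scan, solves for the boundary rows
`b1 ≤ b2 ≤ b3` that maximise agreement with the raw labels — an exact
O(rows) dynamic program via prefix running maxima, vectorised over columns.
Output columns always satisfy the anatomical ordering; columns whose retina
run is empty are flagged. This replaces a largest-run-plus-gap-fill
heuristic: the DP is as cheap, strictly order-preserving, and optimal for
the same objective. On phantoms at the default noise (σ=8 grey levels) it
recovers >99.99% of voxel labels; noiseless renders are recovered exactly.

Label-map validation (usable on any source of labels) reports out-of-order
columns, zero-retina columns and retina-thickness outliers by global
z-score. The default threshold is 8 because a *healthy* foveal depression
already reaches z ≈ −6 against the volume-wide thickness distribution;
the detector is meant to catch gross segmentation blunders, not anatomy.

## Synthetic data

### Geometric phantom

ILM depth is a single Gaussian bump `z_base + pit_depth·exp(−r²/2σ²)`
(unique, controllable deepest point) over a radially symmetric thickness
profile linear in radius between anchors at 0 / 1.0 / 2.5 mm. The
retina/choroid boundary at the pit centre sits at `outer_boundary_depth_px`
(anchor for `z_base`); choroid and sclera bands follow, and parameters
that would push layers outside the axial extent are rejected by name.
Voxel labels discretise the continuous boundaries by voxel-centre
membership (rounding to nearest row). Defaults: pit 120 µm deep, σ=300 µm,
thicknesses 212/359/311 µm — calibrated so the analytic zone volumes are
0.205 / 0.768 / 1.375 mm³, the reference means for Z1/Z2/Z3. The analytic
oracle integrates `2π∫t(r)·r dr` per annulus on a radial grid 20× finer
than the fast-axis pitch (sector slices are quarter-annuli by symmetry)
and shares no code with voxel counting. Renders draw each class at its
mean intensity plus Gaussian noise, seeded and reproducible.

The phantom deliberately omits OCT speckle physics, vascular shadows,
curvature and pathology; passing tests demonstrate the correctness of the
measurement chain, not robustness to real-scan artefacts.

### Cohort simulator

Cohorts are simulated at volume level (the statistics need distributional
structure, not pixels): per eye a 9-slice vector from a multivariate normal
plus additive female-vs-male and Mauritius-vs-Asia offsets; zones/quadrants
follow by composition. Defaults emulate the reference cohort: 187 animals ×
2 eyes (374 eyes), female probability 147/374, Mauritius probability
199/358, marginal slice means (0.205, 0.191, 0.199, 0.188, 0.191, 0.351,
0.347, 0.352, 0.325) mm³ and CVs (8.1, 6.1, 4.8, 6.3, 4.5, 5.4, 3.9, 5.5,
3.8)%, uniform 0.5 between-slice correlation (the reference mean
between-slice correlation is 0.49; the full empirical correlation matrix is
not published, so emergent quantities such as among-quadrant correlations
or PCA explained-variance shares differ from the real data), and effect
vectors derived from the published right-eye subgroup means — sex offsets
concentrated on S2/S4/S7/S9 (−10.5, −12, −8.5, −9 µm³·10⁻³ there), origin
offsets on S1/S4/S5 (−10.5, −5, −3.5). Means and CVs are *marginal*
targets: the intercept and the within-group variance are back-computed
from the configured proportions and effects. Fellow eyes share an
animal-level random intercept (intraclass correlation 0.8, configurable; a
modelling stand-in, not an estimate) — which is precisely why downstream
MANOVA/ANOVA default to analysing one eye side at a time, where each animal
contributes at most one eye and observations are independent. Unknown-origin
eyes are not simulated by default.

## Statistics

Summaries use the n−1 standard deviation; CV = SD/mean. Correlation blocks
summarise all pairwise Pearson coefficients within and between the Z/Q/S
families (3, 6, 36, 12, 27, 36 pairs), pooling both eyes by default;
coefficients involving (numerically) zero-variance variables are excluded
and counted. PCA eigendecomposes the sample covariance of S1–S9 without
standardisation (shared mm³ units), orders eigenvalues descending and signs
each unit eigenvector so its largest-magnitude loading is positive.

MANOVA (statsmodels) fits S1–S9 on sex and origin after excluding
unknown-origin eyes, per eye side; the sex×origin interaction is removed
when its Wilks p ≥ 0.01 and the additive model refitted. The per-slice
ANOVAs use Type II sums of squares — the natural choice for the
additive-after-interaction-removal workflow on an unbalanced design — with
the interaction dropped at 0.01/9, and Bonferroni stars dividing the usual
levels by the nine slice tests (strict inequalities). Because all nine
responses share one design matrix, the ANOVA engine computes every Type II
test in one batched QR pass; it is numerically identical to statsmodels
`anova_lm(typ=2)` (asserted in the test suite) and ~30× faster, which the
replicated power/calibration simulations rely on. Multiplicity note: the
/9 correction guarantees ≤5% family-wise error per factor; across the two
factor families (18 cells, slice correlation 0.5) the simulated any-star
rate under the null is ≈7–8%.

Covariates (age, weight) are carried but not modelled. An animal-level
cluster bootstrap is deliberately out of scope; eyes are treated as
independent within a side, as the reference analysis does.

## Problem sizes and numerical choices

Replicated simulations use 200 cohorts for power and 300–500 for null
calibration at n = 374 independent eyes; phantom checks run at the native
geometry plus 2× and 4× lateral refinement (refinement keeps the outermost
raster lines fixed and subdivides). Cohort CSVs store volumes at 10 decimal
places so a write/read round-trip preserves every region to 1e−9 mm³ and
reconstructed zone sums stay within the same tolerance; readers always
rebuild zones/quadrants from the slices and cross-check any provided
values to 1e−6 mm³, rejecting inconsistent rows with row-level diagnostics.
All generators accept seeds and are bit-reproducible.

## Limitations

- The 221 µm slow-axis discretisation bounds both nulla localisation (one
  B-scan) and regional-area accuracy (the ~5% central-disc bias above).
- The rule-based segmenter models intensity contrast only; it makes no
  attempt to reproduce the error characteristics of a learned segmenter on
  real scans.
- The uniform default correlation cannot reproduce covariance-shaped
  results of real data (PCA loading patterns, among-family correlation
  gaps); tests of those patterns use explicitly factor-structured
  covariances instead.
- Device-dependent differences between OCT instruments are out of scope;
  volumes measured on other devices are not comparable without bridging
  data.
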