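# retvol

Nulla-centred retinal volumetry for macular OCT raster scans of cynomolgus
monkeys (*Macaca fascicularis*), plus the statistics of a normative
reference database.

Cynomolgus monkeys are the standard non-human primate in preclinical ocular
studies because, like humans, they have a fovea. Interpreting their OCT
readouts needs two things this package provides: a *localization-free*
measurement procedure (monkeys cannot fixate, so the measurement grid must
be anchored on an automatically detected landmark rather than on scan
placement) and *normative statistics* (how much healthy retinal volume
varies, and how much of that variation is explained by sex, geographic
origin and eye side).

## What it computes

Starting from pixel-wise semantic label maps of a 25-line macular raster
(labels: vitreous / retina / choroid / sclera per B-scan pixel):

1. **ILM surface & nulla.** The inner limiting membrane is the first
   retina-labelled pixel per A-scan; the *nulla* is its deepest point
   within the foveolar depression, found as the argmax of the
   median-smoothed depth map.
2. **Nulla-centred grid.** A cylinder of diameter 3000 µm around the nulla
   is partitioned ETDRS-style into concentric zones Z1–Z3 (1 / 2 / 3 mm
   ring diameters), four diagonal-boundary quadrants Q1–Q4, and nine
   slices: the central disc S1 (≡ Z1), inner-ring sectors S2–S5 and
   outer-ring sectors S6–S9. Nasal/temporal naming mirrors between OD and
   OS.
3. **Voxel volumetry.** Regional volume = (retina-labelled voxels in the
   region's A-scan columns) × voxel volume, with

   V_voxel = (L/n_x) · Δy · (D/n_z)

   for scan length L = 5.3 mm over n_x = 512 A-scans, B-scan spacing
   Δy = 221 µm and depth D = 1.9 mm over n_z = 496 rows
   (= 8.763·10⁻⁶ mm³). Composition holds exactly: Z2 = S2+S3+S4+S5,
   Z3 = S6+…+S9, Q_k = S1/4 + inner + outer sector slice, ΣS = ΣQ = ΣZ.
4. **Reference statistics** over a per-eye cohort table: grouped summaries
   (count, mean, SD, min, median, max, CV) by eye × sex × origin; Pearson
   correlation block summaries among and between Z/Q/S; PCA of S1–S9 on
   the covariance matrix; two-factor MANOVA (Wilks' Λ, Rao's F); and nine
   per-slice two-factor ANOVAs (Type II SS) with Bonferroni-corrected
   stars (*p* < 0.05/9, 0.01/9, 0.001/9).

A deterministic intensity-based segmenter (nearest class mean + an exact
ordered-boundary dynamic program per A-scan) converts rendered or real
B-scan images into label maps with the same contract as a learned
segmenter, and a synthetic **phantom/cohort generator** provides label
volumes with a parametric foveal pit (known centre, analytic regional
volumes) and simulated cohorts with configurable means, CVs, between-slice
correlation and sex/origin effects — so the entire pipeline is testable
without scanner data.

## Worked example

```python
import retvol as rv
from retvol import phantom as ph
from retvol import refstats as rs

geom = rv.ScanGeometry()                      # 25 B-scans, 512x496 px, 221 um spacing
params = ph.PhantomParams(pit_center_offset_mm=(0.4, 0.221), seed=7)
volume, truth = ph.synthesize_label_volume(geom, params)
stack = ph.render_bscan_images(volume, params)

labels, flags = rv.segment_stack(stack.images, geom)
eye = rv.process_eye(labels, eye="OD")
print(f"nulla at B-scan {eye.nulla.b_index}, A-scan {eye.nulla.x_index}")
print(f"Z1={eye.volumes.Z1:.3f}  Z2={eye.volumes.Z2:.3f}  Z3={eye.volumes.Z3:.3f} mm^3")

cohort = ph.simulate_cohort(ph.EffectDesign(seed=1))
z1 = rs.summarize(cohort, region="Z1")
print(f"cohort: n={z1.count}  Z1 mean={z1.mean:.3f} mm^3  CV={100*z1.cv:.1f}%")
table = rs.anova_per_slice(cohort, eye_side="OD")
print("sex-significant slices:", table.significant_slices("sex"))
print("origin-significant slices:", table.significant_slices("origin"))
```

prints

```
nulla at B-scan 13, A-scan 295
Z1=0.216  Z2=0.769  Z3=1.349 mm^3
cohort: n=374  Z1 mean=0.205 mm^3  CV=7.7%
sex-significant slices: ['S2', 'S4', 'S9']
origin-significant slices: ['S1', 'S2', 'S4', 'S5']
```

The pit was planted 0.4 mm laterally and one B-scan step off-centre and is
recovered at (13, 295), within one A-scan of the true centre. Zone volumes
carry the documented voxel-counting discretisation of the 221 µm slow axis
(see `docs/methods.md`); the simulated 374-eye cohort reproduces its
calibrated central-zone mean of 0.205 mm³ with a CV near 7.9%, and the
per-slice ANOVA screening flags the slices that carry the injected sex
(paracentral S2/S4/…) and origin (central S1, …) offsets.

A `retvol` CLI wraps the same stages (`retvol phantom`, `simulate-cohort`,
`ingest`, `segment`, `nulla`, `volumes`, `report`, `run-all`); run
`retvol --help`.

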