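# Methods

This note records the models, conventions and design choices behind
`conntarget`, in the spirit of the methods documentation that accompanies
simulation and statistics packages: what is computed, under which
assumptions, with which defaults, and what the synthetic data do and do not
establish.

## Volumetric model

All volumes live on a `VoxelGrid`: a shape triple plus an invertible 4×4
affine mapping 0-based voxel indices to MNI millimetres. Voxel sizes are the
column norms of the affine's rotation block. Masks and scalar maps are only
combinable on identical grids (same shape, affines equal to within floating
tolerance); violating this raises `GridMismatchError` rather than silently
resampling — resampling and registration are out of scope.

The default working grid is a 4-mm isotropic lattice covering the MNI
bounding box x ∈ [−90, 90], y ∈ [−126, 90], z ∈ [−72, 108] (46 × 55 × 46
voxels). This is a desk-scale coarsening of the 2-mm space used for real
acquisitions; `mni_grid(2.0)` gives the full-resolution lattice and every
operation is resolution-agnostic.

**Sphere ROIs.** A voxel belongs to a sphere iff the Euclidean distance from
its centre to the sphere centre is ≤ the radius (inclusive boundary,
voxel-centre dialect). The DLPFC search mask is the union of four 20-mm
spheres at the standard left-prefrontal stimulation sites: BA9 (−36, 39, 43),
BA46 (−44, 40, 29), the 5-cm-rule site (−41, 16, 54) and the Beam F3 site
(−37, 26, 49). The merged mask is used as-is; whether to further intersect
it with a gray-matter mask is left to the caller (the phantom pipeline does
intersect, since correlations are only defined where there is signal).

**PGC seed.** The pregenual-cingulate mask normally comes from an external
file supplied by the user. When none is given, a synthetic stand-in — a 6-mm
sphere at (0, 40, 4), a pregenual ACC location — is used and flagged as
`synthetic-standin` in reports.

## Signal processing

Processing order for targeting inputs is: high-pass filter, then spatial
smoothing, then series extraction.

**High-pass (> 0.01 Hz).** Implemented as regression on a discrete-cosine
basis: unit-norm DCT-II regressors with frequencies k/(2·T·tr) for
k = 1 … ⌊2·T·tr·f_c⌋, plus the constant. This filter is deterministic, has
no edge transients for runs as short as 100 frames, and its frequency
response is analytic, which makes the pass/stop-band tests exact. It is a
projection, hence idempotent up to floating error.

**Smoothing (4 mm FWHM).** Isotropic Gaussian with σ = FWHM/(2√(2 ln 2)) mm,
converted to voxel units per axis; zero-padded boundary, kernel truncated at
6σ. Because the discrete kernel is normalised, image mass is conserved
exactly for any input whose kernel support stays inside the volume; the
impulse response at FWHM/2 from the peak is one half of the peak by
construction. FWHM 0 returns the input unchanged.

**Seed series.** The DLPFC series is the unweighted mask mean. The PGC
series uses the seedmap estimator: a weighted average over all gray-matter
voxels excluding the DLPFC, weights taken from a group-average PGC
connectivity map, normalised by Σ|w| so the output scale is stable even if
the weight map carries negative lobes; weights are used with their sign.
The estimator is linear in the data.

**Connectivity metric.** Pearson product-moment correlation. Fisher z is
applied only where correlations are differenced across sessions (ΔFC), not
for within-map ranking — the transform is monotone, so selection and
clustering are unaffected. Zero-variance voxels inside a search mask are
assigned r = 0 with a logged warning rather than an error, so a dead voxel
cannot abort a whole-map computation.

## Target selection

Within the search mask, the top fraction (default 0.5 %) of voxels by
*signed* r is selected, with k = ⌈fraction × N⌉ (ceiling guarantees at least
one voxel on small masks). Ties at the cut go to larger r, then to lower
linear voxel index, making the selection deterministic. Selected voxels are
partitioned into connected components under the 26-neighbourhood (the common
neuroimaging convention; 6 and 18 are available), components sorted by size,
size ties by higher mean r, then by lowest member index. The stimulation
target is the unweighted centroid of the largest component, reported in MNI
mm, together with a "snapped" voxel (the member nearest the centroid, ties
toward higher r — useful because a centroid can fall between voxels or
outside a non-convex cluster) and the peak-r voxel.

**ΔFC.** The trial-level connectivity-change score is
z(r_post) − z(r_pre), where each r is the correlation between the mean
series of a 10-mm sphere centred on the (pre-session) target centroid and
the seedmap PGC series, both sessions processed identically. The 10-mm
radius approximates the cortical extent effectively engaged by a
figure-of-eight coil; the definition of the scalar (sphere radius, Fisher z,
seedmap reference) is this package's choice of a reproducible convention.

**E-field indices.** Given an externally computed field-magnitude map (V/m)
and an ROI, the summary is mean, max, and the percentage of ROI voxels
*strictly* above the threshold (default 150 V/m). Field simulation itself
(finite-element modelling) is out of scope.

## Synthetic phantom

`make_phantom` emulates the minimal structure the targeting chain needs:

* a gray-matter ellipsoid (semi-axes 72/90/78 mm, centred near (0, −18, 18))
  filled with i.i.d. Gaussian noise (SD 1.0);
* a latent band-limited time course (white noise smoothed over ~2 frames,
  standardised);
* the PGC stand-in voxels carry latent + noise; a planted hotspot — an 8-mm
  sphere at (−38, 36, 40), inside the DLPFC mask — carries
  `coupling_gain × latent + noise` (default gain 1.0, giving voxel–seed
  correlations ≈ 0.7 at 200 frames);
* a spatially smooth confound: a random loading map smoothed at 12 mm FWHM,
  multiplied by its own band-limited time course at amplitude 0.3 — a
  stand-in for global/physiological structured noise;
* the group weight map is the 12-mm-smoothed PGC indicator restricted to
  gray matter, peaked at the seed;
* the post session is regenerated with fresh noise and the gain multiplied
  by `post_gain_factor`.

Defaults are a desk-scale surrogate for a 600-frame, TR 1 s, 2-mm
acquisition: 200 frames, TR 1 s, 4-mm grid. One integer seed drives a
`SeedSequence` with one child stream per component (latent, pre-noise,
post-noise, confound), so outputs are bit-reproducible. Noise is generated
only inside gray matter (other voxels stay zero); search masks are always
intersected with gray matter so zero-variance voxels never enter targeting.

At these settings the targeting chain recovers the planted centroid within
two voxels in ≥ 18 of 20 seeded phantoms. The occasional miss is informative
rather than a defect: the smooth confound can, by chance, produce a genuine
competing cluster whose coupling to the (confound-contaminated) seedmap
series rivals the hotspot — the same failure mode a real physiological
artefact would produce. What the phantom does *not* model: hemodynamic
response shape, motion, multi-compartment noise spectra, anatomical
variability. Passing recovery tests therefore demonstrates correctness of
the selection machinery at a representative SNR, not field performance on
patient data.

## Synthetic cohort

`make_cohort` draws, per patient: baseline headache days from a truncated
normal (mean 10.2, SD 7.1, bounds 3–30 days/month); a latent responder flag
Bernoulli(11/21); a class-specific proportional reduction (responders
0.55 ± 0.15, non-responders 0.05 ± 0.15, clipped to [0, 1]) applied at Post
and Follow-up with a small per-timepoint jitter (SD 0.05), so the effect is
sustained; headache intensity (0–10 integer scale, baseline 5.7 ± 1.5)
reduced proportionally to the realised day reduction; PSQI (0–21, baseline
7.7 ± 3) with only ±1 random drift — no treatment effect, by design; a
3-category PGIC derived from the realised reduction (> 15 % improvement,
< −5 % worsening, else no change); and ΔFC with responder/non-responder
means separated by `dfc_effect` standard deviations (default 1.1, SD 0.15).
Days are rounded to integers by default (headache diaries count days), which
makes the realised ≥ 30 %-rule responder status occasionally differ from the
latent flag — as it would in a real trial.

With the default separation of 1.1 SD, the expected AUC of a
normal–normal two-class problem is Φ(1.1/√2) ≈ 0.78, and the median AUC
across seeded 21-patient cohorts falls in the low 0.8s — the regime of a
strong but imperfect biomarker. With `dfc_effect = 0` the AUC is calibrated
at 0.5.

## Statistical conventions

* **Protocol totals**: pulses = frequency × train length × trains; session
  time counts n trains and n−1 intertrain gaps, reported raw and rounded up
  to whole minutes (10 Hz, 5 s, 25 s, 36 trains → 1800 pulses, 17.58 → 18 min).
* **Responder**: (baseline − later)/baseline ≥ 0.30, boundary inclusive.
* **RM-ANOVA**: univariate, sphericity assumed, df (k−1, (k−1)(n−1)); the
  error SS is declared degenerate when it is ≤ 10⁻¹⁰ of the larger of the
  condition and subject SS (double-precision guard), in which case F is
  reported as 0 or ∞ with a warning.
* **Paired comparisons**: differences d = a − b; t = mean/(SD/√n) on df n−1;
  Bonferroni-adjusted p = min(1, m·p); CI = mean ± t(df, 1−α/(2m))·SD/√n
  (Dunn critical value). Cohen's d for paired change = mean(Δ)/SD(Δ) — this
  variant reproduces the emulated trial's printed effect sizes (0.81, 0.58)
  and CI bounds (1.30–7.54, 0.07–6.29) from its printed summaries. A
  pooled-error CI variant (RM-ANOVA error mean square, the convention of
  some stats packages) is provided as `pooled_error_ci`.
* **Kruskal–Wallis**: scipy's tie-corrected H across the three timepoints
  treated as independent groups (a known simplification for repeated
  measures, kept for comparability), so N counts patient × timepoint
  observations; η² = (H − k + 1)/(N − k), clamped at 0. All-identical data
  report H = 0 with a warning.
* **PGIC chi-square**: goodness-of-fit of the 3 category counts against
  uniform expectation, df 2.
* **ROC**: AUC from the rank-sum U statistic (ties ½), identical to the
  trapezoidal area under the empirical curve; higher ΔFC is
  responder-positive. Significance by two-sided permutation of labels —
  exact enumeration of all C(n, n₁) assignments when that count is ≤ 5×10⁵
  (it is 352 716 for a 21-patient 11/10 split), otherwise 10⁴ seeded
  Monte-Carlo resamples; the normal-approximation Mann–Whitney p is reported
  alongside. The operating point maximises Youden's J, ties resolved toward
  higher specificity; J is rounded at 10⁻¹² before comparison so that exact
  ties are not split by floating-point noise.
* All p-values are two-tailed.

## Numerical and API notes

* BOLD data are processed in their native dtype (float32 for generated
  phantoms), which halves memory and runtime at desk scale; accumulations
  that define test oracles (sums, correlations) are done in float64.
* Correlations are clipped into [−1, 1] after computation; Fisher z clips
  its argument just inside ±1.
* Degenerate inputs (empty masks, all-zero weights, zero-variance series,
  singular affines, invalid fractions) raise named exceptions from
  `conntarget.errors`; warnings are reserved for recoverable conditions
  (dead voxels, degenerate error terms).
* The pipeline CLI validates its JSON config before any computation and
  embeds the config, its SHA-256 hash and the seed in every artefact;
  rerunning with the same config and seed is byte-identical.

## Known limitations

* No registration, motion correction, denoising or slice-timing — inputs
  are assumed fully preprocessed into a common space.
* The phantom's noise model is white plus one smooth confound; it cannot
  probe robustness to motion or hemodynamic variability.
* The seedmap weight map is a synthetic stand-in unless the user supplies a
  real group-average map; likewise the PGC mask.
* Kruskal–Wallis across timepoints ignores the within-patient pairing.
* The exact-permutation p is conditional on the observed score ranks; with
  heavy ties its resolution is limited by the tie structure.
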