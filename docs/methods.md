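# Methods

This note records the model behind `iansegmap`, the parameter choices that
matter, and what the synthetic validation does and does not demonstrate.

## Reference-slice geometry

All scoring happens on a single coronal reference slice per site (third
molar M3, distal root of the second molar M2). Two landmarks are given, not
detected: the alveolar crest of the buccal cortical plate and the midpoint
of the IAN. The baseline through the crest defines "horizontal" (default:
the image row direction; a `baseline_angle_deg` can be supplied when the
head orientation is known); the midline is the parallel line through the
nerve midpoint.

Where exactly the two perpendiculars cut the midline is a genuinely open
design point: we place them at **equal thirds of the midline chord** through
the canal mask — the only symmetric reading of "divided by two
perpendiculars into six segments" — and record the rule in every output. An
alternative (`bbox-thirds`, thirds of the mask extent projected on the
baseline) is available.

Tie-breaking is deterministic and half-open: a pixel center exactly on the
midline goes to the inferior band, exactly on a perpendicular to the middle
column. Comparisons carry a 10⁻⁶ mm tolerance so that only true geometric
ties — not floating-point jitter — invoke the convention. Pixel centers sit
at `(index + 0.5) × spacing` with the origin at the slice corner. Buccal is
+x for a left side and −x for a right side; `mirror_partition` maps between
sides and is an exact involution.

## Visibility rule and tables

`fraction_s = |nerve ∧ segment_s| / |segment_s|`, a 2D area ratio on the
reference slice ("segment volume" in a single-slice protocol is its area).
A segment is visible when `fraction_s ≥ 0.5` — inclusive at exactly one
half. Empty segments score 0 and carry a warning flag. The conditional
table entry (i, j) is `100 · count(i ∧ j) / count(i)`; rows with
`count(i)=0` are reported as undefined (NaN), never as 0. Joint counts are
kept so the identity `n_i P(j|i) = n_j P(i|j)` is assertable exactly, and
stratified tables (by retention label) sum elementwise to the pooled table.

Hyperintensity extraction is our own operationalization of a visual
judgment: threshold at the midpoint between the canal-interior background
(20th percentile inside the canal mask) and the nerve peak (98th
percentile), then keep the connected component containing the nerve
midpoint. A slice whose canal shows no usable contrast raises a
segmentation-failure error; such records are excluded and logged, never
imputed.

## Phantom model

Each subject side is a bone slab crossed by a straight elliptical canal
along the mesiodistal axis with an elliptical nerve tube inside it.
Defaults calibrate to published normative diameters: canal semiaxes
(1.95, 2.65) mm → 3.9 mm buccolingual / 5.3 mm coronal on CBCT; MRI canal
scaled by (1.072, 1.036) so it reads 4.18/5.49 mm; nerve semiaxes
(1.3, 2.05) mm → 2.6/4.1 mm. The nerve is a pair of semiaxes rather than a
single radius because the real nerve caliber is strongly anisotropic
(axial ≈ 2.6 mm vs coronal ≈ 4.1 mm).

Intensities are flat per tissue class with partial-volume antialiasing
(3×3 sub-pixel coverage averaging); MRI: bone 0.50, cortical ring 0.10,
canal interior 0.35, nerve 0.90; CBCT: bone 0.30, ring 0.90, interior 0.25,
and *no* nerve contrast. Additive Gaussian noise (default SD 0.02 ≈ SNR 27
on the nerve-interior contrast) rather than Rician: the pipeline
thresholds, it does not model noise physics. An optional extra Gaussian PSF
blur defaults to 0 — the coverage averaging already band-limits edges. The
cortical ring is 1.0 mm thick so that it remains a connected barrier at the
0.75 mm MRI voxel size.

Cohorts sample canal/nerve semiaxes, offsets and crest height from
truncated normals; left/right sides share anatomy up to exact mirroring
plus a 0.1 mm jitter; a 1/19 missing-side probability reproduces the design
scale (19 subjects, expected 36 evaluated nerves). The nerve offset is
constant along the tube, so M3 and M2 differ only by slice index and noise
— this keeps the analytic diameter truth exact; per-slice sinusoidal
undulation is available (amplitude default 0) but then the stored truth
diameters are approximate and flagged as such.

The FOV width is snapped to a multiple of the MRI spacing so the left/right
mirroring is bit-exact on the raster. Reference slices sit at ⅓ and ⅔ of
the slab (8 MRI slices = 6 mm by default).

### Analytic oracles

`truth_occupancy` rebuilds the partition in closed form (midline ∩ canal
ellipse via the quadratic, thirds of that chord) and integrates the nerve
disk over each segment on a 1500² sample lattice, independently of the
raster pipeline; the result carries its quadrature step and a perimeter-
based error estimate. True plane diameters are closed-form: coronal
`2·max(a,b)`; the axial cut through a straight tube of length L and
half-width a is an `L × 2a` strip with Feret `√(L² + 4a²)` — length-
dominated, unlike curved real anatomy, which is why the clinically quoted
numbers are the coronal ones.

## Segmentation and morphometry

Seeded region growing on robustly normalized intensities (1st–99th
percentile). For the IAC the criterion separates canal interior from
cortical bone: the cortical level is the extreme percentile of a 6 mm
context ball on the bone side of the modality (cortical bone is *dark* on
water-excited MRI, *bright* on CBCT — a modality fact, configured not
estimated), the interior level starts at the ball median and is refined to
the quartile of the first-pass region nearest the cortex, so the final
threshold sits at the half-coverage boundary; the refinement is accepted
only if it does not flood (thin rings under noise), otherwise the
conservative first pass stands. For the IAN, the seed neighborhood mean is
compared with a background shell that widens (1.4–2.8 → 2.8–4.2 → 4.2–6 mm)
until it clears the nerve; detection requires the seed to exceed the
shell's upper quartile — the nerve is hyperintense by definition, so a
non-bright seed means an absent or invisible nerve and raises an error
(IAN on CBCT is a modality error outright). Growth uses 6-connectivity,
is capped at 25 % of the volume (leakage error), and is followed by an
in-plane morphological closing (0.3 mm; in-plane so tubes spanning the
volume are not eroded at the end slices).

"Maximum extension of the diameter" in a plane is read as the **maximum
Feret diameter of the 2D cross-section** through the reference site (axial
section at the structure centroid's superoinferior level, sagittal at its
buccolingual level, coronal at the reference slice), not the global 3D
extent: this matches measuring on multiplanar reformations. Diameters are
measured on the binary mask at pixel resolution — no sub-pixel contour
fitting — as the maximum pairwise distance between boundary-pixel centers
(convex-hull accelerated) **plus one in-plane pixel width**, so a
single-pixel region has diameter one pixel and the discretization error is
bounded by √2 × spacing on both sides. Validation on 20 noiseless phantoms
holds every plane within that bound.

## Conversion statistics

Factors are per-observation ratios; summaries are the arithmetic mean and
sample SD (ddof = 1) **of the ratios**, which differs from the ratio of mean
diameters (a regression test pins the distinction: diameter pairs (4, 1)
and (2, 2) give mean factor 2.5, ratio of means 1.5). For inference,
observations are first averaged over the right and left sides, one value
per participant, and the per-subject difference between the CBCT-based and
MRI-based factors is tested with a one-sample Wilcoxon signed-rank test at
α = 0.05. Zero differences are dropped before ranking by default (the
classic test and the default of the common R implementation), with Pratt
handling available; the exact null distribution is used for n ≤ 25 without
ties, otherwise the normal approximation with continuity and mid-rank tie
correction. An all-zero difference vector is reported as degenerate with
p = 1, flagged, and never rejected. Tests cross-check exact p-values
against full 2ⁿ sign enumeration up to n = 12, and a simulated null (both
factor types from one distribution, 19 subjects, 1000 replicates) keeps the
rejection rate within [0.02, 0.09].

Both summary conventions are labeled in the outputs — means over all
subjects *and* sides, versus side-averaged per-subject values for the test
— since either n can be meant by "over all subjects and sides".

## Problem sizes and determinism

The shipped study configuration is 19 subjects (~36 sides), two sites,
full-resolution CBCT (0.16 mm, ≈ 0.5 M voxels per side) and runs in a few
seconds; validation suites use 20–200 phantom instances and 1000 Wilcoxon
replicates. All randomness flows from a single integer seed through
`numpy.random.default_rng`; synthetic end-to-end reruns are bit-identical
(provenance records a config hash and library versions; timestamps are off
by default for exactly this reason).

## What passing tests do and do not show

The phantom validates the *machinery*: exact tiling, oracle-equivalent
geometry, convergence of raster occupancy to analytic fractions
(≤ 0.02 at 0.05 mm pixels, ≤ 0.01 at 0.025 mm), diameter recovery within
√2 voxel, unbiased ratio recovery, calibrated inference. It does not
emulate curved canal courses, metal or motion artifacts, bone-density
variation, tooth anatomy, or reader variability in landmark placement — so
agreement on phantoms bounds discretization and algorithmic error, not
clinical accuracy. Occupancy percentages produced by the synthetic cohort
depend on the sampled nerve-offset distribution and are not expected to
reproduce any particular clinical cohort's table values.

## Known limitations

- Single-slice scoring by default; the multi-slice (slab) diameter mode is
  configurable but off.
- The axial/sagittal Feret of a straight-tube phantom is slab-length
  dominated (see above); cross-modality factors in those planes are
  correspondingly compressed toward 1 on phantoms.
- Landmarks are inputs; no automatic detection.
- The hyperintensity extractor is a histogram-midpoint threshold — adequate
  for the phantom's bimodal interior, simplistic for real DESS data.
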