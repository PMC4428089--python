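# Methods

This note records the models, conventions and numerical choices behind
`lungmorph`, in the order the pipeline applies them.

## Axis semantics and coordinates

All volumes are held in canonical order: array axis 0 = left-right (LR),
1 = anterior-posterior (AP), 2 = cranial-caudal (CC), in RAS sense after
loading (NIfTI via `nibabel.as_closest_canonical`, NRRD via SimpleITK
reorientation with ITK's LPS physical coordinates flipped to RAS).
Chord statistics are invariant to flips within an axis, so only the axis
*order* affects morphometry; the flip convention matters only for the
left/right lung labels, and the `orientation` config option (RAS vs LPS)
controls that assignment.

Voxel indices are 0-based and a chord of n in-mask voxels has physical
length n x spacing (voxel-as-cell convention), so a single-voxel object
has nonzero length. Default spacing is breath-hold MRI acquisition
geometry: 1.4 mm in-plane, 1.5 mm centre-to-centre slice spacing. Masks
are binary, so slice-profile overlap (3 mm slice thickness on a 1.5 mm
grid) is deliberately not modelled — a segmentation carries no partial
volume.

## Chord-length morphometry

Per lung and axis, every grid line parallel to the axis that intersects
the lung contributes one chord, defined as the *count of in-mask voxels
on the line* times the spacing. Counting voxels (rather than
last-minus-first extent) is robust to concavities and boundary noise;
the per-line extent is kept as a `median_span_mm` diagnostic column, and
the whole-lung bounding extent as `max_extent_mm`. Lines that miss the
lung are excluded, otherwise the median would depend on the size of the
bounding grid. The per-axis length is the median chord (even counts:
mean of the two middle values). Volume is voxel count x voxel volume.

Lung splitting keeps the two largest 26-connected components, labels
right/left by mean LR coordinate, discards smaller components with a
logged count, and warns when the second component is below 10% of the
largest (likely a single-lung mask plus noise). Masks with fewer than
two components are rejected with a pointer to single-lung mode
(`single_lung_labelmap`).

## Sparse annotation and reconstruction

Manual segmentation drawn on every second axial slice is emulated by
`sparsify(mask, step)`, which keeps slices 0, step, 2·step, ...
verbatim. Dense reconstruction interpolates along CC: each missing
slice strictly between two annotations is the `>= 0` superlevel set of
the distance-weighted linear blend of the neighbours' signed Euclidean
distance maps (positive inside). Choices within that scheme:

* **Half-pixel boundary.** Voxel-centre EDTs place the implied boundary
  midway between the innermost outside sample and vice versa; both maps
  are shifted by half the mean in-plane spacing so the zero level sits
  at the voxel edge. Without this, tie blends systematically dilate
  interpolated slices.
* **Degenerate slices.** All-empty (or all-full) slices have no
  distance map; they are assigned a constant at the in-plane diagonal
  scale so interpolation against a normal neighbour tapers over the gap
  instead of jumping.
* **Extrapolation.** Slices outside the annotated range copy the
  nearest annotated slice (clamping): no information exists beyond the
  range, and clamping biases lengths conservatively.
* **Resolution limit.** Cross-section changes smaller than about one
  voxel per annotated gap cannot be resolved: digital distance maps in a
  sub-voxel annulus are symmetric and the blend ties at zero, which the
  `>= 0` rule resolves toward the larger slice. For anatomically
  plausible tapers (a voxel or more per gap) reconstruction volume error
  is well under 1%; the test fixtures use such tapers.

Annotated slices always pass through unchanged, making reconstruction
idempotent on its own output.

## Motion ratios and decomposition

Per axis, ratio = median chord at inspiration / median chord at
expiration; raw change = difference in mm. The CC ratio is reported as
the diaphragmatic component, AP and LR as chest-wall components, under
the anatomical attribution that the diaphragm acts cranial-caudally and
the thoracic muscles in-plane. A subject is "diaphragm-dominant" when
the CC percent increase strictly exceeds both in-plane increases,
"chestwall-dominant" when it is strictly below the larger of them, and
"mixed" on exact ties (ties are quantization artifacts). Ratios below 1
are legitimate paradoxical motion: flagged, never clipped.

Per-subject values are produced per lung and as a "combined" entry, the
unweighted mean of the two per-lung values — transparent and
order-independent. Whole-thorax pooling can be obtained by running
single-lung mode on the union mask.

## Spirometry metrics

Postural drop ΔFVC = (FVC_sitting − FVC_supine)/FVC_sitting × 100%,
signed; negative drops (supine better than sitting) are kept with a
`paradoxical_drop` flag. The formula is scale-invariant, so
percent-predicted and absolute-litre inputs give identical drops; the
package takes percent predicted (reference equations are upstream).
Threshold flags are strict as worded clinically: weakness at ΔFVC
strictly above 25%, hypercapnia at expiratory CO2 strictly above
6.0 kPa — boundary values do not flag. Cohort tables are validated row
by row (numeric coercion, percent-predicted range [0, 200], non-negative
pressures) with a complete error list rather than first-error-only.

## Statistics

Pilot cohorts of this kind are far too small for asymptotics, so the
Mann-Whitney test defaults to the exact permutation null. U is computed
by pairwise win counting with 0.5 per tie; since U is a fixed function
of the pooled rank sum, the exact null distribution over all
C(n1+n2, n1) labelings is obtained by dynamic programming over the
doubled (hence integer, even with ties) pooled ranks — equivalent to
full enumeration but O(n·n1·Σranks). The two-sided p is
P(|U − n1·n2/2| ≥ |u_obs − n1·n2/2|); the permutation distribution of U
is symmetric about n1·n2/2 (negating all values gives a bijection on
labelings), so this matches the usual two-tailed convention. Above a
configurable labeling cap (default 2×10^5, far beyond a 10-vs-6 design's
8008) the tie-corrected, continuity-corrected normal approximation is
used. Every result records which path was taken.

Spearman's r is the Pearson correlation of average-method ranks. For
n ≤ 9 the two-sided p is the exact permutation share with |r| at least
the observed (vectorized over all n! orderings); above that, the t
approximation with n−2 degrees of freedom. |r| = 1 under the
approximation path is reported with its permutation bound 2/n!.
Descriptives are medians with (min, max) ranges.

The analysis battery compares every spirometry variable and all three
axis ratios between groups, and correlates the CC ratio with
{ΔFVC, FVC supine, FVC sitting, MIP, MEP} and the AP ratio with FVC
supine *within the patient group only* (controls would otherwise
manufacture correlation through the group difference); a sensitivity
flag includes them. Two-sided tests throughout, significance at
p < 0.05, no multiple-testing correction — the report records the
number of tests run instead.

## Synthetic phantoms

Two lung shapes, mirrored about the midline with a 16 mm mediastinal
gap:

* **cuboid** — box of edge lengths (2a, 2b, 2c); all chord statistics
  are exact arithmetic.
* **dome** — half-ellipsoid diaphragm dome (semi-axes a, b, c) whose
  flat base is displaced caudally by d at inspiration, leaving a
  full-cross-section cylindrical segment of height d. The CC chord over
  footprint position (x, y) is d + c·sqrt(1 − (x/a)² − (y/b)²); because
  the squared normalized footprint radius is uniform over the ellipse,
  the chord CDF is ((t − d)/c)² and the median CC chord is d + c/√2.
  The phantom's true CC ratio is therefore 1 + d·√2/c, and a target
  ratio r is realized by d = (r − 1)·c/√2.

Chest-wall expansion multiplies the in-plane semi-axes by the AP/LR
expansion factors (values below 1 model paradoxical motion). Boundary
jitter adds seeded uniform noise (± amplitude, mm) to the inside-positive
implicit function before thresholding, which can create speckles — the
lung splitter's component filtering is exercised by exactly this.

The ground-truth sidecar is computed by an independent analytic path:
closed forms for CC chords, volumes and all cuboid statistics, and dense
numeric integration of the continuous chord-length distribution (1200²
line samples) for the dome's in-plane axes. It never calls the voxel
morphometry.

Default expiration semi-axes (40, 70, 140) mm give roughly 1.05 L per
lung and an expiration CC median chord near 99 mm, so a healthy-type CC
ratio of 1.82 corresponds to ~81 mm of diaphragmatic displacement —
magnitudes typical of adult breath-hold studies.

## Cohort simulation

Each subject draws a true CC ratio from a group normal (defaults:
patients 1.35, controls 1.82, common SD 0.17 — group centres and spreads
of a weak-diaphragm pilot cohort; the SD puts the 10-patient expected
range near 1.07–1.64 and the 6-control range near 1.66–2.08), floored at
1.0 because this motion model cannot shorten the lung. The dome CC
semi-axis varies across subjects (SD 8 mm) so size normalization is
genuinely exercised. Spirometry is generated through monotone linear
links: FVC_supine = −58.25 + 75·r_CC and FVC_sitting = −21 + 60·r_CC
(percent predicted, truncated to [0, 130]), plus Gaussian noise
(default SD 5 %pred, which yields strong rank correlations around
0.85–0.95 between the CC ratio and supine FVC / postural drop). FEV1
tracks FVC at 95% with small noise; MIP/MEP/CO2 are group normals
centred at typical patient and control values. The links are a modelling
convenience: real data support a strong monotone association, not a
functional form, which is why only rank statistics are interpreted.

What the generator does *not* emulate: MRI intensities, artifacts and
segmentation error beyond boundary jitter; within-subject breath-hold
variability (no repeated measures); anatomical asymmetry between left
and right lungs; any causal structure beyond the single latent CC
ratio. Passing tests therefore demonstrate the correctness and
calibration of the measurement and statistics chain, not clinical
validity on real images.

## Monte-Carlo conditions and problem sizes

Calibration runs operate at the cohort-table level (no voxelization):
500 replicates for the strong-link Spearman rate, with link noise SD
0.5 %pred — "strong link" means the monotone relation is essentially
noiseless at rank scale, isolating the statistic's behaviour at n = 10 —
and 1000–2000 replicates for the null rejection rate, where both group
means are equal and the exact test's discreteness makes the rate
slightly conservative (observed ≈ 3.5–4%at nominal 5%). The full voxel
pipeline (phantoms at 1.4/1.5 mm spacing, every-second-slice emulation,
10 + 6 subjects) runs once per seed for median-recovery checks, at about
half a minute on one CPU; the determinism check repeats a coarse 3 mm,
3 + 3-subject configuration twice and compares bytes.

## Known limitations

* Median chords characterize length changes of roughly convex lungs;
  severe focal disease could move the median without a corresponding
  diaphragm excursion.
* The axis attribution is the standard anatomical assumption; shared
  volume change is not partitioned beyond it.
* Shape-based interpolation cannot recover structures thinner than the
  annotation step, and sub-voxel taper resolves toward the larger slice
  (see above).
* The exact Mann-Whitney path is exponential-in-principle but the DP
  keeps it trivial up to the default cap; beyond it the normal
  approximation is explicitly recorded in the method note of each
  result.
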