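# Methods

## Scope and model

`pettex` computes texture indices (TI) on a volume of interest (VOI) of a 3D
PET image in SUV units.  The pipeline is: (1) discretize the in-VOI SUVs to
gray levels 1..D+1, (2) build three texture matrices from the levels,
(3) reduce each matrix to scalar indices, (4) attach SUVmax (pre-resampling)
and metabolic volume.  Everything downstream of the discretization treats
the levels as pure labels with an order; all physical information enters
through the resampling step, which is why the resampling convention is the
scientific crux.

### Resampling

Two schemes, identical except for their bounds:

* relative (RR): bounds are the VOI's own min and max;
* absolute (AR): fixed bounds, default 0–20 SUV (presets AR15/AR20/AR25),
  out-of-range values clipped and counted.

Both use `level = round(D·(I−low)/(high−low)) + 1` with D = 64 by default.
Rounding is half-up, fixed explicitly because bankers' rounding would
silently move bin edges.  The raw rounded value lies in 0..D; the +1 shift
(applied identically to both schemes) keeps the gray-level-weighted indices
(LGZE's 1/i² in particular) defined.  A constant VOI maps to level 1 under
RR; the choice is arbitrary and only visible in gray-level-weighted indices
on degenerate input.  A fixed-bin-width scheme of width w is provided as an
alias for AR with high = w·D.

RR levels are exactly invariant under increasing affine maps of the
intensities; AR levels are equivariant under joint scaling of intensities
and bounds.  These two invariances are the mechanism behind every contrast
the package demonstrates.

### Texture matrices and indices

* Co-occurrence matrix: 13 sign-free unit-Chebyshev directions, distance
  1 voxel, accumulated symmetrically (both orderings), normalized per
  direction.  Homogeneity Σp/(1+|i−j|), entropy −Σp·log₂p (base 2 by
  default; the base only rescales entropy and cancels in every rank-based
  statistic), contrast Σp(i−j)².
* Run-length matrix: maximal collinear same-level runs per direction, a run
  ending at a mask boundary or level change.  SRE (1/H)ΣG/j², LRE
  (1/H)ΣG·j², RLNU (1/H)Σⱼ(ΣᵢG)².
* Zone matrix: maximal 26-connected same-level components in 3D
  (6-connectivity available for sensitivity checks).  LGZE (1/H)ΣZ/i²,
  HGZE (1/H)ΣZ·i².

CM and GRLM indices are unweighted means over directions that contain at
least one valid pair or run; a direction with no valid pair in a thin VOI is
undefined rather than homogeneous and is dropped.  Matrix extents follow the
maximum occupied level/length/size, since all indices are sums over occupied
cells.  Run mass (Σ runs × lengths per direction) and zone mass both equal
the VOI voxel count; these conservation laws are enforced in the test suite
against explicit-loop enumeration oracles.

### VOIs

Three VOI kinds: voxel-centered spheres of odd diameter d (membership:
Euclidean distance ≤ (d−1)/2 of the center voxel, so d = 3 is the 7-voxel
cross and the sphere spans exactly d voxels per axis); adaptive-threshold
lesion segmentation; and rigid integer-voxel relocation of a mask into
reference tissue, which preserves the sampling geometry exactly.

The segmentation is a background-corrected contrast-oriented rule: the
threshold is `T = β·mean(SUV over the 70% isocontour kernel) + background`,
with β = 0.3 by default, the kernel being the 26-connected component of the
0.7·(local max) isocontour around the seed and the background estimated in a
1–3 voxel shell outside it.  The VOI is the 26-connected component of
`SUV ≥ T` anchored at the seed (or at the local maximum when the seed sits
in a photopenic core).  A fixed-fraction-of-max mode is available.  The rule
family, not its exact constants, is what matters downstream: all results
carry the segmentation parameters as provenance.

Metabolic volume is voxel count × voxel volume (mm³ → mL).

## Synthetic data

### Uniform phantom

A water-filled cylinder (200 mm high, 160 mm diameter, 4 mm isotropic
voxels) with uniform uptake (SUV 3 by default — the level is arbitrary
since the phantom has no dose/weight bookkeeping) plus Gaussian white noise
(15% of the mean) convolved with an isotropic Gaussian PSF (7 mm FWHM,
typical of clinical PET).  This emulates the one property of reconstructed
PET that the phantom argument needs — spatially correlated noise — without
simulating reconstruction.  Default sphere positions: cylinder center plus
two radial (8 voxels) and two axial (12 voxels) offsets, all clear of the
wall for the largest sphere.

RR-based indices on this phantom depend only on the PSF width and the seed:
the noise field is an affine family in (mean, sd), which RR normalizes away.

A property of RR worth recording: on Gaussian noise the VOI min–max range
grows like √ln n with the voxel count n, so the RR bin width keeps widening
and the probability of equal-level neighbors keeps rising.  Entropy
saturates regardless and plateaus cleanly, but the run-emphasis indices
(SRE, LRE) and homogeneity retain a slow drift of roughly 5–7% of their
profile range per size step even at the largest sphere sizes used here
(diameter 15 → 17 voxels); under a strict last-step plateau detector they
hover at the detection boundary.  RLNU is different in kind: it is
essentially proportional to voxel count (Spearman r = 1 against volume) and
never approaches a plateau.

### Synthetic cohort

No patient data are available, so the cohort is a generative stand-in built
to exhibit the qualitative phenomena of interest, not to match any patient
table.  Per patient (28 adenocarcinoma-like, 13 squamous-like by default) a
64³ volume at 4 mm voxels contains:

* body background (SUV 0.5);
* a liver block (~10 × 10 × 9 cm, SUV 2.2) as the healthy reference;
* one spherical lung tumor with a multiplicative intra-tumor texture field
  (a smoothed Gaussian random field, length scale drawn 8–12 mm) and, for
  squamous-like tumors, a low-uptake core (0.45 × peak, 0.55 × radius).

Subtype parameters (defaults): radius U(10, 22) vs U(16, 30) mm, peak SUV
U(5, 8.5) vs U(8.5, 15), texture amplitude 0.50 vs 0.75 of the local mean.
Voxel noise is proportional to the local mean (drawn 25–40% per patient,
higher than the phantom's 15%, consistent with the much shorter per-bed
patient acquisitions), then the whole volume is PSF-smoothed.  The texture
field is clipped asymmetrically at −0.5 sd and +3 sd: shallow cold dips keep
the lesion above the segmentation threshold (so the segmented geometry stays
compact), while sparse tall hot spots widen each tumor's own min–max range.

Two calibration facts drove these choices, and both are general properties
of threshold-segmented VOIs rather than quirks of this generator:

1. A VOI produced by thresholding a blurred, noisy lesion carries a small
   systematic excess in min–max-resampled entropy relative to the same mask
   placed in uniform reference tissue (~+0.1 bits here).  It decomposes
   into a rim term (the blurred edge band inside the VOI) and a selection
   term (the VOI boundary follows the lesion's own noise field); eroded,
   interior-only VOIs show no excess, as the affine-invariance argument
   predicts.  The hot-spot tail of the texture field offsets this excess by
   compressing the in-VOI bulk into fewer relative bins.
2. For the subtype contrast to be visible to absolute resampling but not to
   relative resampling, it must be a pure difference of scale (amplitude ×
   peak), since RR sees distribution shape but not scale.  The strength of
   a pure-scale contrast under AR20 is bounded by the fixed 0–20 SUV window
   and, for entropy, by saturation at the pair counts of 200–800-voxel
   VOIs, which limits the attainable group separation at n = 28/13.

What the generator does *not* emulate: irregular tumor shapes, respiratory
motion, partial-volume effects at the liver boundary, reconstruction
artifacts, scanner harmonization differences, and any real histology-texture
link.  Results on this cohort demonstrate the *mechanism* by which the
resampling choice controls volume-dependence and tissue discrimination;
they are not evidence about real NSCLC subtypes.

### Exclusion filter

The patient-selection filter retains injection-to-scan delays inside a
closed [60, 90] min window and segmented metabolic volumes ≥ 2.5 mL, and
reports a tally per criterion in application order.  Default delays are
drawn U(62, 88) min, so the default cohort passes the filter intact.

## Statistics

Spearman rank correlations (average-rank ties; a zero-variance input is
reported as r = 0 with a degenerate flag so profile tables always render)
characterize TI-versus-volume and TI-versus-SUVmax relationships; tumor
profiles are restricted to metabolic volume < 60 mL by default.  Tissue
comparisons are paired Wilcoxon signed-rank tests (same patients, same VOI
geometry); subtype comparisons are unpaired rank-sum (Mann–Whitney) tests;
both two-sided, exact for small samples where the data permit and otherwise
a normal approximation with continuity correction.  Raw p-values are
reported, mirroring common practice in the field, with a Holm-adjusted
column emitted alongside because eight indices × four resampling schemes is
a non-trivial family.  The scipy implementations are used; the test suite
checks them against exact enumeration over sign assignments and group
assignments for small n.

The phantom experiment's plateau detector flags an index once the change of
its per-size mean between the two largest sphere sizes falls below 5% of
the full range of the means; an exactly flat profile counts as plateaued.

## Numerical and interface choices

* Half-up rounding everywhere in resampling; level storage is int64.
* A single-voxel VOI has no co-occurrence pairs in any direction and raises
  a degenerate-texture error; runs and zones remain defined.
* SUV conversion: SUV = C[kBq/mL] · weight[kg] / (dose[MBq] · 2^(−Δt/T½)),
  with the decay interval Δt a parameter defaulting to 0 (scanner output
  assumed decay-corrected; the convention is exposed rather than guessed).
  T½ defaults to 109.77 min (18F).
* NIfTI-1 is the on-disk format for volumes and masks (nibabel); spacing is
  taken from header zooms, and 4D files are rejected rather than squeezed.
* All generators take integer seeds and are bit-reproducible; experiment
  outputs are plain CSV.

## Known limitations

* The adaptive-threshold constants are a reasonable member of the
  contrast-oriented family, not a reimplementation of any specific
  published calibration; absolute segmented volumes shift with β.
* GZLM indices are computed from the single 3D zone matrix, so there is no
  direction averaging to damp their sampling noise; HGZE in particular is
  volatile for small VOIs.
* The cohort's statistical power at n = 28/13 is marginal for the weaker
  subtype contrasts (AR entropy especially); single-seed results near
  p = 0.05 should be read accordingly.
* Run-length emphasis indices under RR drift slowly with VOI size on
  Gaussian noise (see above); plateau claims for them depend on the
  detector's strictness in a way that entropy's does not.
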