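# Methods

## The problem

Mast-cell secretory granules (SGs, ~0.3–1.5 μm) are hard to label
exhaustively: no single membrane marker covers the whole population.
Negative contrast imaging (NCI) sidesteps markers by expressing soluble
GFP in the cytoplasm and reading organelles as *dark voids* — regions that
exclude the fluorophore — in confocal z-stacks.  `nci3d` implements the
complete analysis chain for such data: restoration, void segmentation by a
relative-intensity contour rule, serial-section 3D reconstruction, and
population/fusion statistics, together with a synthetic phantom generator
that provides exact ground truth for validation.

## Coordinate and data conventions

Arrays are indexed `(z, y, x)`, z index 0 at the bottom slice; physical
coordinates are micrometres with the origin at the stack corner, a voxel's
centre at `(i + 0.5) · d`.  Default calibration is 40 × 40 nm lateral
pixels with 0.20 μm z-steps for cells, and 0.10 μm z-steps for bead
benchmarks.  On disk, stacks are 16-bit OME-TIFF with the voxel size in
metadata; in memory they are float32 (deconvolution needs continuous
values).

## Phantom generator

The generator emulates what NCI acquisitions look like, with analytically
known truth:

* **Objects** — spheres, z-cylinders, strings of tangent spheres, and
  prolate spheroids (fusion products), voxelised by analytic sub-voxel
  coverage: boundary voxels are supersampled 8× per axis, so a planted
  sphere's voxelised volume matches `(π/6)d³` to ~10⁻⁵ relative error.
  `exclusion` sets the fraction of cytoplasmic intensity remaining inside
  a void (0 = fully excluding); `marker_level` fills a second channel.
* **Cell phantoms** — an ellipsoidal cell at a uniform cytoplasmic level
  (default 1000 counts) against ~0 background, an optional nucleus at 70%
  of the cytoplasmic level with darker substructures (free GFP enters the
  nucleoplasm but is partially excluded from dense substructures), and
  granules placed by seeded rejection sampling with a minimum surface gap.
* **Optics** — in order: object shadowing (below), depth attenuation,
  convolution with a Gaussian PSF (default lateral FWHM 0.25 μm, axial
  0.6 μm — typical for a 1.4 NA oil objective at GFP wavelengths; the
  instrument itself publishes no PSF, so these are stated assumptions),
  Poisson shot noise, then Gaussian read noise (SD 5 counts).  All
  randomness flows from one seed; identical (spec, seed) gives
  bit-identical stacks.
* **Shadowing** — polystyrene beads scatter strongly at 488 nm, so the
  bead benchmark attenuates light along z through objects
  (Beer–Lambert, default μ = 0.6 μm⁻¹ for bead baths, 0 for cells:
  transmission 0.74 / 0.55 / 0.41 for 0.5 / 1.0 / 1.5 μm beads).  The
  shadow is propagated slice by slice and diffused laterally at the
  aperture half-angle (`tan θ = 2.4`, from `sin θ = NA/n = 1.40/1.515`),
  which is why the narrow shadow of an in-window bead washes out within a
  fraction of a micrometre while a 1.5 μm bead keeps a deep shadow that
  corrupts the contours above it.  This reproduces the empirical validity
  window (accurate for 0.5–1.0 μm, inaccurate outside) with a single
  physical mechanism.
* **Fusion series** — scheduled pairs drift along their connecting axis
  (≤0.6 μm/frame, else the schedule is rejected) until they sit 0.3 μm
  apart, then are replaced by a prolate spheroid whose long axis spans the
  tangent pair pole-to-pole, whose volume is the exact parent sum, and
  whose marker level is the pooled marker divided by the combined volume —
  the fluorescence-dilution signature of granule–granule fusion.

What the phantoms deliberately do **not** model: vectorial/aberrated PSFs,
photobleaching, fluorophore photophysics, cell motion between slices, and
intracellular background structure.  Tests passing on phantoms therefore
demonstrate the correctness of the *analysis chain* under controlled
optics, not robustness to every property of real acquisitions.

## Restoration

Richardson–Lucy (RL) deconvolution with a user-supplied parametric PSF
replaces proprietary blind deconvolution: blind estimation is ill-posed,
and for phantoms the PSF is known exactly.  Defaults: 30 iterations,
reflect padding by half a kernel extent, non-negativity and ~1% flux
conservation.  Biggs–Andrews vector extrapolation is implemented
(`accelerate=True`) but **off by default**: measured on bead phantoms it
sharpens the axial 50% crossing only from 0.585 to 0.570 μm while
deepening background shot-noise dips from ~900 to ~400 counts (1st
percentile), which would seed spurious voids.  The plain update is
verified against `skimage.restoration.richardson_lucy` in the test suite.

The cytoplasmic reference level is the median over the cell mask after
iteratively excluding voxels below 50% of the running median (voids would
otherwise bias the reference down); spread is reported as 1.4826·MAD.

## Void segmentation: the 90–95% contour rule

A void boundary is defined relative to two references: the void **center**
(0%) and the surrounding **periphery** (100%); the contour is drawn where
intensity reaches a fraction (90–95%, default 92.5%) between them.
Implementation choices, all of which the source procedure leaves open:

* **Seeds** are per-slice regional minima deeper than 60% of the
  cytoplasmic level, merged within 0.25 μm, confined to the cell mask.
* **Center (0%) reference** is the *structure's* 3D minimum — the minimum
  over a z-reach of half a granule diameter around the seed — not the
  in-plane minimum.  Near the poles of a void the in-plane minimum is
  already half-filled by axial blur; anchoring the scale to the 3D minimum
  keeps the decision level consistent across the slices of one organelle.
* **Periphery (100%) reference** is local: the median in an annulus
  0.2–0.4 μm outside the void support, refined iteratively (support =
  region below the current level, annulus outside it) so the annulus sits
  on the intensity plateau, with the global cytoplasm median as fallback
  when the annulus is unusable (e.g. crowded neighbourhoods).  A local
  reference self-calibrates against depth attenuation and local shading.
* **Binarization.**  The pipeline's default follows the
  binarize-then-contour order of the original workflow: each void is
  converted black/white at the midpoint between the 0%/100% references (an
  isodata-style threshold) and the boundary is traced sub-voxel on the
  intensity image at that level.  For a restored, sharp-edged void the
  midpoint crossing localises the true edge; the 92.5% level applied
  directly to a blurred intensity profile instead sits in the blur skirt
  and overestimates 1.0 μm bead diameters by tens of percent even after
  heavy RL iteration (the Gaussian PSF is band-limited; the edge cannot be
  restored below ~1 residual σ).  `extract_contour` retains the literal
  fractional rule (`binarize=False`) — on an already-binary slice the two
  modes trace the same region, so re-extraction is idempotent.
* **Sub-voxel contours** come from marching squares with linear
  interpolation; on noiseless rasterised analytic profiles the extracted
  radius matches the closed form within ~0.002 μm (half a lateral voxel is
  the tested bound).
* **Touching voids**: seeds sharing one iso-region are first deduplicated
  (seeds on a flat minimum plateau with no intensity ridge >30% of the
  contrast depth between them are one void), then genuinely
  ridge-separated seeds split the region by seeded watershed on the
  intensity.
* **Floors**: contours below 0.3 μm equivalent circle diameter are
  discarded (below the validated window; small voids diffract away), as
  are open iso-curves at image borders and contours escaping the cell
  mask.

The cell body itself is segmented as the largest connected
above-background (Otsu) component with per-slice hole filling; its volume
is the voxel count times the voxel volume.  The nucleus is the largest dim
(<75% of the interior median) region exceeding 20 μm³ — three orders of
magnitude above granule volumes, so granule voids never qualify.

## 3D reconstruction

Contours in adjacent slices are linked when their polygon overlap is at
least 50% of the smaller area (the linking threshold is exposed; "same
position in the neighbouring image" is otherwise unquantified), ties
resolved by largest overlap then nearest centroid; each contour joins at
most one organelle.  Linking is symmetric under slice-order reversal.

Volume is computed by **lamination**: `V = dz · Σ areas`, one slab per
contour.  The slab model carries a small positive bias for spheres —
the hand-computable r = 0.5 μm sphere sampled at dz = 0.2 gives
0.5341 μm³ against the analytic 0.5236 (+2.0%) — which vanishes as
dz → 0 (<1% at dz = 0.02); the voxel-count volume is reported alongside
for QC.  Equivalent spherical diameter is `(6V/π)^(1/3)`.

Shape metrics: z-extent is one dz per contour (slab convention);
elongation is z-extent over the *largest* lateral equivalent diameter, so
a sphere scores ≈1 and a 2.0 × 0.6 μm z-cylinder ≈3.3.  (The mean lateral
diameter of a sphere's sections is (π/4)·d, which would force a sphere to
score ~1.27; the maximum is the reference that makes "elongation 1 =
isotropic" hold.  The mean is still reported.)  Objects whose contours
touch the first or last slice are flagged truncated — their volumes are
underestimates — and excluded from size statistics by default.

Compartment classes, in rule order: centroid inside the nucleus →
`nuclear`; thin tube in any axis (width < 0.4 μm, elongation > 2) →
`mitochondrion-like`; equivalent diameter in 0.3–1.5 μm → `SG`; else
`unclassified`.  Whether an elongated SG is one organelle or a tight
string is *not* decided — elongation is reported and interpretation left
to the user.

## Quantification

* **Size distributions** over lamination volumes, with small/large cell
  stratification at 1,500 / 2,500 μm³.
* **Cell volume vs granule count**: Pearson r (the published presentation
  implies a linear association) with Spearman's rho alongside, slope and
  intercept by least squares, 95% CIs from a seeded 1,000-resample
  bootstrap.
* **Marker colocalization**: an organelle is marker-positive when its mean
  interior marker intensity exceeds background mean + 3 SD (no criterion
  is published; 3σ is the package's choice).
* **Tracking**: greedy nearest-centroid matching, gate 1.0 μm per frame
  (appropriate for 1–3 min frame intervals); unmatched objects open or
  close tracks.
* **Fusion detection**: two tracks ending at frame t with a track starting
  (or a parent continuing) at t+1 near the parents' volume-weighted
  centroid, child volume within 0.6–1.4 of the parent sum.  The marker
  dilution ratio (child per-volume marker over the marked parent's) is
  reported when exactly one parent is marked; the approach axis is the
  unit vector between parent centroids.

## Problem sizes used in the shipped benchmarks

The bead benchmark simulates 12 beads per size at 0.1 μm z-steps in a
~13 × 10 × 3.6 μm bath (≈3M voxels); cell phantoms for counting and
correlation use 140–420 μm³ cells at (0.2, 0.08–0.1, 0.08–0.1) μm voxels
with 14–50 granules — the same geometry as full-size acquisitions at a
field size that keeps a complete benchmark run in minutes on one CPU.
Sizes scale linearly if larger cohorts are wanted.

## Known limitations

* The contour rule's accuracy rests on restoration sharpness; with the
  band-limited Gaussian PSF model, cap slices near a void's poles retain
  a ~+2% diameter bias at 30 RL iterations that no iteration count
  removes.
* Equivalence with the original commercial restoration chain
  (blind deconvolution + Neurolucida) cannot be established directly —
  only benchmarked through bead recovery.
* The scattering shadow model is scalar and single-pass (no multiple
  scattering, no refractive lensing); it reproduces the validity window's
  direction and rough magnitude, not exact bead-by-bead errors.
* Fusion detection assumes at most one event per track pair per frame and
  volume conservation within ±40%; fragmentation (one → two) is not
  detected.
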