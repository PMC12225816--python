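# Methods

## The model

Each hematopoietic bone site is decomposed into *segments*: regions of
near-uniform spongiosa microstructure and cortical thickness whose outer
envelope is one of six primitives — box, elliptic cylinder, deformed
cylinder, isosceles triangular prism, ellipsoid, tube.  A segment phantom is
a labelled isotropic voxel raster (background / marrow / trabecular bone /
cortical bone) built in three steps:

1. **Envelope rasterization.**  Voxels whose centers lie inside the analytic
   shape become marrow.  Center-point sampling makes axis-aligned boxes exact
   and gives first-order convergence of the voxel volume to the closed form
   for curved shapes.  The deformed cylinder is the ruled solid between two
   coaxial, axis-parallel ellipses linearly interpolated along the height,
   with volume V = πh/24 · (2ab + 2cd + ad + cb); the source description of
   the bases' mutual orientation is ambiguous about a possible center offset,
   and the coaxial reading was chosen (a truncated cone is the stated special
   case, which the coaxial form reproduces).
2. **Cortical shell.**  Shells grow inward from the outer surface, so the
   printed dimensions are outer dimensions.  Planar faces become coordinate
   slabs; lateral surfaces of (deformed) cylinders and tubes are eroded by
   reducing the ellipse axes by 2·Ct.Th; the ellipsoid's full-surface cover
   erodes all three axes; prism side faces are offset along their inward
   normals.  The spongiosa region is exactly the voxelization of the eroded
   interior, so the analytic and voxel cortical volumes converge together.
   Faces not listed in a record keep marrow at the surface — newborn
   vertebrae and sacral bodies carry no cortex at all.  Face pair suffixes
   (ab1/ab2) are assigned to the lower/higher coordinate side arbitrarily but
   consistently; the faces are mirror images, so the choice carries no
   physical content.
3. **Spongiosa.**  Trabeculae are a Boolean process of finite cylindrical
   rods: centers homogeneous in a margin-dilated bounding box, orientations
   uniform on the sphere, diameters and lengths lognormal.  Rods are clipped
   at the spongiosa boundary and union freely (no exclusion).

The default voxel size is 0.7 × Tb.Th, clamped to 0.04–0.25 mm.

## BV/TV calibration

The triple (BV/TV, Tb.Th, Tb.Sp) over-determines a rod process, and BV/TV
dominates dose formation (it sets the spongiosa density and the energy
fraction absorbed in marrow).  BV/TV is therefore binding, Tb.Th is enforced
through the diameter distribution, and Tb.Sp is an emergent diagnostic: the
generator logs a warning when the measured separation deviates more than 25%
from the record's value, which reliably happens in dense spongiosa.

Calibration is exact rather than iterative-stochastic: the starting
intensity comes from the Boolean-model identity p = 1 − exp(−λ·E[v]); a rod
pool of about 1.6× that count is stamped once, recording for every marrow
voxel the index of the first rod that covers it, which makes measured BV/TV
a monotone step function of the number of active rods.  The smallest prefix
whose coverage is nearest the target is selected; the pool is extended while
the target is unreachable (each extension is one "calibration iteration",
capped at 50).  Because one rod adds ~10⁻⁴ of the region volume, the
realized BV/TV sits within a fraction of a percent of the target —
comfortably inside the 2% relative contract — and the whole construction is
bit-reproducible from the seed.

## Tb.Th convention and morphometry

Printed Tb.Th values are micro-CT local-thickness indices, which are
volume-weighted.  The sampler therefore scales the lognormal's number-mean
diameter by (1 + CV²)⁻² so that the volume-weighted mean E[d³]/E[d²] equals
the target; with CV = 0 the diameters equal Tb.Th exactly and the CV of the
distribution is unchanged by the weighting.

Measurement uses the standard largest-inscribed-sphere local thickness,
computed with two distance transforms per radius step (0.5 voxel), plus a
half-voxel surface offset: the Euclidean distance transform measures to the
nearest background voxel *center*, which sits half a voxel beyond the phase
boundary.  On ideal rods and generated phantoms the measured mean is within
a few percent of truth once a structure spans ≥ 2.5 voxels; below ~2 voxels
the measurement is floor-limited, which at the default 0.7 × Tb.Th
resolution (1.43 voxels per trabecula, for every record in the database)
applies to all phantoms — thickness verification is done at elevated
resolution.  Above BV/TV ≈ 0.4 the rod union coalesces into plate-like
clumps and the local thickness genuinely exceeds the rod diameter (about
+23% for the newborn skull at BV/TV 0.53); BV/TV remains exact there, and
this regime limit is asserted by a characterization test.

## Variability model

Inter-individual sampling follows the stated correlation structure with the
magnitudes left configurable because only the signs are established:

- linear dimensions: normal, multiplied by factors with rank correlation +1
  by default (one shared factor), CV in percent of the nominal value;
- Tb.Th and Tb.Sp: lognormal marginals matched in mean and CV, joined by a
  Gaussian copula with rank correlation −1 by default (Pearson parameter
  2·sin(πρ/6));
- Ct.Th: independent normal factor, truncated at zero by resampling;
- BV/TV: uniform in a per-segment admissible band (default width 0, i.e.
  fixed, because the per-segment bands are not published in the main tables).

A draw that violates a record invariant (e.g. a cortical shell consuming the
interior) is resampled up to 200 times before failing.  Cohort media-volume
CVs use the analytic volume path, so 10⁴-draw cohorts cost milliseconds; the
default per-parameter CVs are declared placeholders — the segment-resolved
values live in unpublished supplementary material and enter via the config.

## Multiplicities and truncation

Segments that recur in the skeleton carry a multiplicity n_s (paired bones
×2, ribs ×24 in age-dependent groups, vertebra bodies ×5/7/12, process
records multiplied per vertebra, 76 tubular hand/foot bones in the newborn),
and segments modeled as 30 mm fragments or 30 × 30 mm plates carry a
truncation factor k_s = whole-structure extent / modeled extent.  Neither is
printed in the main tables; the shipped defaults (data/multiplicity.tsv)
derive from typical whole-bone dimensions, anchored to the one printed
datum — the adult iliac ala plate covers 9 cm² of a 91.2 cm² segment — and
every value is overridable per record key.  With these defaults the eight
whole-phantom TBV/CBV/BMV totals land within ~30% of the published reference
set; exact reproduction is not claimed, and the totals are exactly linear in
n_s and k_s by construction.

## Effective parameters

Skeleton-level "effective" spongiosa volume, BV/TV and Ct.Th mirror dose
averaging: sites are weighted by their AM fraction; within a site (or a
grouped AM cell, resolved by marrow-volume share with no invented split)
segments are weighted by corrected marrow volume.  Per segment, Ct.Th is the
area-weighted mean over cortex-bearing faces, with cortex-free segments
contributing zero — area weighting was chosen where the averaging convention
was not stated, and the effective spongiosa volume refers to a single
segment copy.  Under the default weights the effective BV/TV decreases
strictly from newborn (0.385) to adult (0.188).

## Curation

The printed tables contain internal inconsistencies (a 240 mm clavicle
width against a stated 88 mm database maximum; adult sternum heights printed
in the wrong decade; a shape census that disagrees with its own row data by
one box/cylinder at age 1; four 15-year rows printed identical across sexes
although the census counts them separately).  Raw mode preserves all of it;
curated mode applies the entries in `data/curations.csv`, each with the
printed value, the repaired value and a justification, and the census and
extremal-value tests run against curated mode only.  The sex-shared segment
counts (28 at 15 years, 23 for adults) are computed from record equality
after name normalization, not hard-coded.

## Numerical choices and limits

- Rasterization: center sampling; voxel grids capped (default 150 M voxels)
  with a stated-refusal error beyond the cap.
- Rod length: mean 4 × (Tb.Sp + Tb.Th), CV = σ_Tb.Sp — a few repeat lengths,
  long enough to percolate; the original generator's connectivity rules are
  not recoverable, so only the statistical contract (BV/TV, diameter
  distribution) is guaranteed.
- Test regions for database-wide sweeps are cubes of at most 30 mm, shrunk
  to 8 structural repeat lengths within a 1.5 M voxel budget; this keeps the
  289-segment BV/TV sweep around four minutes on one CPU without loosening
  the 2% contract.
- No plate-like trabeculae, no anisotropy, no multi-segment assembly, no
  radiation transport.
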