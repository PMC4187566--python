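# Methods

`acinostat` implements an efficient stereological method for counting
pulmonary acini — the gas-exchange units of the lung — in 3D tomographic
image stacks, together with the synthetic phantoms used to validate every
image-processing step against known ground truth.

## Background and model

In rodent lungs the conducting airways (bronchi, bronchioles, terminal
bronchioles) hand over to the gas-exchange region within a single generation
of *transitional bronchioles*: the proximal part of such a bronchiole is
purely conducting, and the first alveoli appear in its distal part. The
locus of that hand-over — a sudden change from the thick wall typical of
conducting airways to the thin wall of the gas-exchange area, with alveoli
directly distal — is the *acinar entrance*, and counting entrances counts
acini. Because acinar entrances are distributed very unevenly inside a lobe
(they concentrate on a cylinder around the central bronchi, and an
airway-free cortex wraps the lobe), subsampling strategies fail and the
method counts an entire lobe exhaustively. One counted lobe is then scaled
to the whole lung through parenchymal volumes:

    N_lung = n_lobe / (V_lobe · d_lobe) · Σᵢ (Vᵢ · dᵢ)

with `Vᵢ` the per-lobe volumes by water displacement (mL), `dᵢ` the per-lobe
parenchyma volume densities (0.888, 0.839, 0.843, 0.865, 0.862 for RUL, RML,
RLL, LC and left lung). The mean acinar airspace volume uses the airspace
density of parenchyma (0.658):

    v_airspace = V_lobe · 0.658 / n_lobe ,
    v_acinus   = V_lobe · d_lobe / n_lobe .

Water-displacement volumes are used in all scaling calculations; the
Cavalieri point-count volume measured on the tomographic stack serves only
to quantify embedding shrinkage, `100·(1 − V_cavalieri/V_wd)`.

## Synthetic lobe phantoms (`acinostat.phantom`)

The original micro-CT scans are not publicly deposited, so detection and
segmentation are validated on voxelized phantoms in which the number and
position of acinar entrances are known exactly.

**Tree grammar.** A monopodial main stem (the rodent pattern: a persistent
axial stem with lateral branches) runs along z from the lobe entry at the
z=0 face. Each junction depth carries exactly one lateral: a terminal
bronchiole carrying one or two transitional bronchioles, a side-stem, or a
short conducting stub (so that junction counting — the intralobar
generation — is well defined). Entrance generations are allocated by
stratified sampling over the configured range (default 4–15, the span
observed in rat lobes); side-stems are spawned when one stem cannot host
the allocation. A configurable fraction of transitional bronchioles
(default 0.15, "relatively frequent") contains a branch point inside the
transition zone: the vertex wall remains thick and each daughter carries its
own entrance — such dual entrances count as two acini.

**Geometry.** All airways are capsules (cylinders with junction spheres) on
straight centerline segments; lumen radii decay per generation
(root 32 µm·0.8^g, floored at 14 µm for conducting airways; transitional
bronchioles 11 µm, alveolar ducts 9 µm). Conducting walls are 16 µm,
gas-exchange walls 6 µm; the published data give no wall thicknesses, so
these were fixed once such that (a) the acinar wall spans at least two
native voxels at 2.35 µm (watertight rendering), (b) the conducting/acinar
contrast stays comfortably above the 2.0 detection ratio, and (c) the walls
are the feature that limits resolution, as the original study argued.
Alveoli are hemispherical outpocketings (radius 16 µm) on the alveolated
airway walls, starting directly distal of the entrance; the transition plane
is an oblique ellipse tilted up to 15° against the airway axis. Each acinus
is a closed unit: the collision rules allow walls of different airways to
fuse, but never allow one airway's air to breach another's wall, and never
let two acini share airspace. Placement uses golden-angle azimuth spacing
with seeded retries; impossible configurations raise an explicit error
rather than silently truncating.

**Rendering.** Two-class absorption contrast: tissue 200, air 30, Gaussian
noise (default SD 10) clipped to [0, 255], 8-bit. The renderer seals
sub-voxel pinholes at shell seams so the airway lumen is watertight by
construction. Ground truth carried with the stack: entrance voxel
positions, acinus ids, dual pairings, per-branch generations, and disjoint
conducting/acinar lumen masks.

Identical parameters and seed give bit-identical volumes.

## Entrance detection (`acinostat.detect`)

The manual criteria — sudden wall-thickness drop plus appearance of
alveoli — are operationalized as follows.

1. **Lumen segmentation.** Tissue is thresholded (Otsu by default). Air
   components touching an x/y face are background (the cortex is
   airway-free; the bronchus enters along z). If marginally resolved walls
   have broken and merged the lumen with the background, the air phase is
   eroded by one or two voxels to recover the component topology (recorded
   in provenance); wall thickness is always measured on the raw grayscale.
2. **Centerline.** The lumen is skeletonized; spurs shorter than 30 µm are
   pruned in a single pass (alveolated ducts carry a dense series of short
   side spurs, and repeated pruning would eat its way down the duct). The
   root is the largest-radius skeleton point near a z extreme of the
   skeleton (thinning retracts about one tube radius from the open end).
3. **Circumferential wall thickness.** For every skeleton voxel, eight rays
   perpendicular to the local tangent are cast through the grayscale; each
   measures the wall chord between the half-maximum up-crossing and the
   next down-crossing that is confirmed by a return to near-air gray (this
   rejects shallow dips inside fused double walls at junctions). The
   voxel's thickness is the median over the eight rays — the circumferential
   judgment an observer makes — floored at two voxels, since a width
   sampled at pitch v cannot be established below that.
4. **Transition test.** Along every root-to-leaf path, a candidate is the
   first index where the proximal median thickness is at least
   `thickness_drop_ratio` (2.0) times a robust low quantile of the distal
   window, the distal wall is of gas-exchange thinness (≤ 8 µm), and
   concave air pockets (morphological closing residue of the lumen,
   ball radius 12 µm) amounting to ≥ 5000 µm³ lie within 60 µm — the
   "appearance of alveoli". The entrance is localized at the steepest step
   of the profile; everything distal of the first transition is acinar.
5. **Duals and dedup.** Entrances whose skeleton arc separation is below
   ~70 µm share a transitional bronchiole and are linked as a dual pair;
   detections closer than 12 µm are duplicates of one transition crossed by
   several paths and are merged.

The two-voxel resolvability floor is what ends reliable counting at coarse
voxels: once two voxels exceed the 8 µm gas-exchange bound the thin distal
wall can no longer be recognized as thin. With the phantom's wall scales
this reproduces the observed behavior — identical counts from native
resolution through 3.6–4 µm, collapse at 5 µm and beyond.

**Substack counting.** Stacks are split into 250–500-section substacks (the
memory-bounding workflow); each substack is analyzed with 80 halo sections
of context on both sides and an entrance is attributed to the unique
substack whose core z range contains its transition locus — the automated
form of handing labels of overlapping acini to the next substack. Counting
whole stacks and any legal substack layout give identical results.

**Resolution study.** `minimal_resolution` degrades a region of interest
through a voxel-size ladder, recounts at every size, and returns the
largest size whose count still equals the native count (one step better
than where counts start to decrease). Degradation uses bicubic
interpolation with a Gaussian band-limiting prefilter matched to the size
ratio: a coarser acquisition integrates over its larger detector element,
so the prefilter is part of simulating it — pure spline resampling without
it aliases marginally resolved walls into spurious holes at any size, which
no real acquisition (nor a human counter) exhibits.

## Conducting-airway segmentation (`acinostat.airway_seg`)

Spherical segmentation stoppers are placed at the entrances (radius 1.5×
the local lumen radius, which covers the full cross-section; the largest
radius in the immediate neighborhood is used so an entrance marked a voxel
off the centerline is not under-covered). Gray-level threshold region
growing runs from seeds inside the conducting airways on a grid downsampled
by factor 2 with block-minimum pooling — air-preserving, so lumina are
never pinched shut, and the thick conducting walls survive while thin
alveolar septa may not (harmless behind the stoppers). The grown set can
never enter a stopper sphere, and any voxel of the same lumen component
gives the identical mask regardless of which seed is chosen.

The grown mask is skeletonized, radius-scale spurs (22 µm at the
downsampled grid) are pruned — this also removes the short daughter stubs
behind dual-entrance stoppers, whose internal branch point is not a
conducting junction — and intralobar generations are numbered from the
root edge (generation 0 at lobe entry, +1 at every branching vertex).
Each entrance is annotated with the generation of its nearest conducting
skeleton point. At the downsampled grid this annotation agrees exactly
with the generator's bookkeeping for roughly three quarters of entrances
and within ±1 generation otherwise (junctions displace by a few voxels at
4.7 µm); the tests assert majority exact agreement and range agreement
within ±1.

## Stereology and statistics (`acinostat.stereology`, `acinostat.stats`)

The estimators are direct transcriptions of the formulas above, with
mL↔µL conversions explicit and counts rounded half-up only at the final
step. `cavalieri_volume` lays a systematic uniform random point grid
(seeded offsets) over every k-th section; the estimate ΣP·a(p)·t is
unbiased over grid offsets (verified to 1% over ≥100 offsets against
analytic solids). Validation statistics: coefficient of variation (sample
SD, n−1), Welch's t-test by default (the pooled-variance variant is a
flag; the original analysis does not state which was used), one-way ANOVA
for more than two groups, and least-squares regression with the R²
categories none (≤0.5), weak (≤0.7), strong (>0.7).

Aggregation note: the published matching accuracies are means of
per-animal ratios, which cannot be recomputed exactly from printed
summary rows; the ratio of printed means agrees within 0.5 percentage
points and the tests assert that tolerance.

## Problem sizes and defaults

Phantom validation runs at native 2.35 µm voxels on volumes of roughly
250–350³ voxels: counts are verified exactly over ten seeded phantoms with
13, 25, and 39 acini (the smallest regions of interest analyzed in the
original study contained 13–39 acini; per-lobe counts of ~686 are reached
by the same machinery at proportionally larger volumes). The resolution
ladder uses the published sizes 2.35 → 3, 3.5, 3.6, 4, 5, 10 µm on a
13-acinus region. The synthetic-data generator's defaults are the study
conditions stated throughout this note; they are deliberately not varied
between tests.

## What the phantoms do and do not show

The phantoms emulate the morphological structure the method relies on —
monopodial branching, one transitional-bronchiole generation, a sudden
wall-thickness transition with proximal alveoli, dual entrances, an
airway-free cortex, two-class absorption contrast with noise. They do not
emulate anatomically faithful lobe shapes, vasculature, tissue texture,
reconstruction artifacts (rings, beam hardening), or the gradual wall
tapering of real airways. Passing the phantom suite therefore shows that
the operators implement the stated criteria correctly and robustly at the
stated scales; it does not by itself establish detection accuracy on real
scans, whose contrast and morphology are richer.

## Known limitations

- Detection assumes the lobe is oriented with the bronchus entering along
  z and an airway-free margin on the x/y faces; other orientations need a
  prior rotation.
- The detector's defaults encode the rat acinus scale (wall bounds,
  closing radius, search distances); other species or ages require
  re-derived defaults, as does the resolution limit.
- Entrance-generation annotation is exact only to ±1 at downsample
  factor 2.
- The lobe-scaling estimators assume a homogeneous mean acinar volume
  across lobes; the per-lobe bias equals the ratio of true to reference
  mean acinar volume (tested), which is exactly the caveat the validation
  tables quantify.
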