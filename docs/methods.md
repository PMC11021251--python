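# Methods

This note documents the models and procedures `neoseg` implements, the
parameters that matter, the synthetic data the package is validated on,
and the numerical choices made where the design was genuinely open.

## The processing chain

The package covers the bespoke computational stages of a neonatal
T2-weighted segmentation-and-surface pipeline.  The surrounding machinery
— the registrations that put atlases and template masks into subject
space, bias-field correction, the deformable surface solver — is out of
scope: registrations are assumed done (the phantom provides inputs
directly in target space), and the force images are produced for an
external solver, not consumed here.

### Brain-mask refinement (`skullstrip`)

Input is an intentionally over-inclusive mask (in production, BET at a
conservative threshold), which keeps all brain at the cost of scalp and
eye fragments.  The refinement is a fixed four-step recipe:

1. K-means with k classes (default 4) on the intensities inside the mask;
   the darkest class is background and is removed.
2. Binary opening with a 4 mm spherical element detaches the thin bright
   scalp stripe from the head.
3. The largest 26-connected component is retained.
4. Binary closing with a 7 mm spherical element smooths the boundary and
   closes interior holes; the closing element is deliberately larger than
   the opening element.

The K-means is a 1-D Lloyd iteration with quantile initialisation at the
(i+0.5)/k quantiles.  This makes clustering deterministic, independent of
voxel ordering, and equivariant under global intensity shifts — three
properties a seeded k-means++ cannot guarantee.  Degenerate inputs (fewer
distinct values than classes) fall back to an Otsu two-class split, and
if that is also impossible the background-removal step is skipped rather
than failing the stage.

Cropping reduces to the mask bounding box plus padding; resampling is
trilinear for intensities and nearest-neighbour for labels, to an
isotropic target that defaults to the voxel-volume-preserving spacing
`(sx·sy·sz)^(1/3)` (reported to two decimals; 0.5 × 0.5 × 1.0 mm gives
0.63 mm).

### Registration-guide masks (`maskgen`)

These masks guide registration cost functions; they are deliberately
approximate and err on the side of capturing the target structure.

**Cortical GM.**  The ribbon is the image's locally dark stripe, detected
as positive values of the second directional derivative of the
Gaussian-smoothed image along the local gradient direction,
`g^T H g / |g|²` (σ = 1 mm by default).  Candidate voxels minus Canny
edge voxels are grouped into 26-connected components; each component is
scored by the fraction of its 6-connected exterior perimeter lying inside
the 1 mm-dilated coarse tissue-GM label, and components scoring ≥ 0.2 are
kept.  The perimeter score is what separates cortical ribbon (embedded in
the tissue GM) from dark periventricular WM (perimeter score 0).

The Canny step exists to cut spurious connections between dark
components.  Its thresholds default to 0.5/0.8 of the maximum gradient
magnitude: edge removal targets the image's strongest edges (GM/CSF,
brain boundary, skull), which are the bridges that need cutting, while
the weaker WM→GM flank stays below threshold and the ribbon interior
survives.  Both thresholds are fractions of a gradient statistic, so the
mask is invariant under global intensity offsets.  The detector itself is
a 3-D Canny (Gaussian gradient, non-maximum suppression by trilinear
sampling one voxel along ±g, hysteresis via connected components seeded
by strong maxima), written in-package because the library ecosystem only
provides 2-D Canny.

**Septum pellucidum.**  From each warped template-seed voxel a march
proceeds laterally (away from the midline, ±x) up to 10 mm and adds the
first "relatively dark" voxel: positive Laplacian of Gaussian, or
intensity below the 3 mm-neighbourhood mean minus τ (default 0.5 × the
within-brain SD).  Note the discrete LoG of a dark sheet has a positive
lobe that includes the sheet's surface voxel, so the march typically
stops at the structure's near boundary — acceptable for a registration
guide.

**Ventricles.**  Components of the coarse ventricle label that intersect
the majority-vote lateral-ventricle labels are kept; dark voxels
(positive LoG — the dark rim) and the periventricular stripe label are
then removed.  Component filtering runs before the intensity exclusion.

**Fissure.**  Convex hull of the brain mask minus the brain mask,
windowed by the warped template fissure mask dilated 5 mm (the dilation
radius is a free choice; 5 mm absorbs typical affine misalignment).

**Non-brain training labels.**  Extra-cranial background is the 3 mm
shell outside the brain; the skull label is the negative second
directional derivative (locally bright stripes) outside the brain.  The
CC guide is a passthrough of the warped majority-vote CC label.

### Label fusion (`fusion`)

Literal similarity-weighted voting: for target voxel v, atlas a searches
integer offsets within the per-voxel radius map (2 mm inside the 2 mm
dilation of the GM mask, 1 mm elsewhere), evaluates the Pearson
correlation between the target patch at v and the atlas patch at v+d
(patch = box of half-width 2 mm per axis, clipped at borders, correlation
over the valid overlap), votes for its label at the best-matching
location with weight max(r, 0)^β (β = 2; negative correlations carry no
weight), and the label with the largest summed weight wins.  Ties go to
the lowest label code; all-zero weight falls back to per-voxel majority.
The correlated-error joint weighting of more elaborate fusion algorithms
is intentionally not reproduced — this module stands in for that step
with the straightforward weighted voting described above.

Offsets are enumerated in (distance, lexicographic) order and a strict
improvement rule makes the per-atlas argmax deterministic, which in turn
makes the output invariant to atlas order.  The implementation is
vectorised — for each (atlas, offset) pair the local correlation is
computed for the whole grid at once with box-filter sums — and an
exhaustive per-voxel oracle verifies it on small grids.  "Patch size
2 mm" is read as a radius (5³ voxels at 1 mm); a diameter interpretation
is available via `patch_interpretation="diameter"`.

### Postprocessing (`postfix`)

Order: sentinels → CSF islands → sulcal banks → regions image.

*Sentinels.*  Codes 254/255 mark manually edited LH/RH WM; they are
rewritten to 2/41 and the marked voxels are excluded from every later
automated modification, bit-identically.

*CSF islands.*  CSF components (6-connectivity, as is every "touch" test
here, preventing diagonal leakage) face-adjacent to the largest WM
component of a hemisphere become that hemisphere's WM; components
touching both hemispheres are split voxelwise by Chessboard distance to
the two main components, ties to the left (lower code).

*Sulcal banks.*  For each configured parcel pair (A, B) facing each other
across a sulcus, WM voxels inside dilate(A) ∩ dilate(B) (2 mm spheres)
are reset to CSF.  The shipped pair list covers the canonical superior
temporal / supramarginal case per hemisphere; the full list is user
configuration.

*Regions image.*  The WM composite is the hemisphere WM labels, the
closing (25 iterations of the unit 6-neighbourhood element) of CC plus
thalamus — which bridges the hemispheres at the midline so the LH/RH
border approximates the medial wall — the subcortical absorption set
(lateral ventricles, thalamus, caudate, putamen, hippocampus, choroid
plexus, amygdala, accumbens, ventral diencephalon), and the third
ventricle dilated 2 iterations.  Composite voxels go to the hemisphere
whose warped ribbon label is nearer in Chessboard distance (ties left);
cortical GM, brainstem+cerebellum, and the lateral ventricles translate
directly, the ventricles overwriting the composite so they remain their
own classes.  Iteration counts use the unit 6-neighbourhood element, the
common morphology-iteration semantics.

The label scheme follows FreeSurfer codes (LH/RH WM 2/41, ventricles
4/43, DKT parcels 1000+/2000+) except that CC is the single code 192,
because 254/255 are reserved for the sentinels.

### Force images (`forces`)

Both forces are normalised to [−1, 1]; the solver consuming them defines
the physical scale, so only supports and signs are meaningful.  The
region force is −1 inside hemisphere WM, +1 in CSF and within `decay_mm`
(default 2) of the brain boundary, with a linear ramp to 0 in between;
zero outside the brain (WM composite voxels that poke outside the brain
mask — possible after the 25-iteration midline closing — are zeroed with
everything else there).  The thin-strand force is −1 on locally bright
voxels (negative second directional derivative) outside the WM label but
within `depth_mm` (default 2) of it, restricted to the dilated
pericalcarine label — the region where thin-gyrus penetration failures
concentrate and outside which a global bright-strand force causes more
errors than it fixes.  The voxel band outside the WM label approximates
"just beneath the WM surface" since the mesh itself is out of scope.

## The phantom

The phantom provides ground truth for every stage.  Geometry: two
ellipsoidal hemispheres (semi-axes 0.19/0.36/0.33 of the grid extent)
separated by a 2-voxel CSF midline gap whose posterior segment is a
notch outside the brain mask (the fissure); a radial layer model per
hemisphere — 3 mm CSF rim, 3 mm GM ribbon, WM core — with sinusoidal
fold modulation (6 folds, amplitude 0.055); one deep planar sulcus on
the inferior convex surface, GM-lined, with superior-temporal / supra-
marginal parcel banks; a pericalcarine zone containing a 1 mm bright
strand through the ribbon (the thin-gyrus partial-volume failure case);
deep lateral ventricles wrapped in a 1-voxel dark periventricular
stripe; dark septum slabs one column into the medial WM wall with
template seeds placed 2 voxels medially; a CC box bridging the midline;
a third ventricle; thalami; a cerebellum+brainstem blob; a bright skull
shell 2–4 mm off the head's convex envelope plus a bright scalp bridge
attaching it to the head; ≤ 10 % smooth multiplicative bias and additive
Gaussian noise.

Intensity means (arbitrary units): background 10, periventricular/septum
30, GM 40, cerebellum 55, WM/CC/thalamus 70, skull 90, CSF/ventricles
100.  The default noise SD of 3 keeps adjacent classes ≥ 3 SD apart.
Two deliberate realism decisions: the thalamus carries WM-like intensity
(neonatal thalamus is near-isointense with unmyelinated WM on T2, and a
dark rim around it would fabricate spurious dark-stripe components
bridging deep structures), and the CSF rim is 3 mm (neonatal cortex is
surrounded by generous subarachnoid CSF; a thinner rim lets the
brain-boundary intensity ridge suppress the dark-stripe response of the
outermost ribbon voxels).

Construction enforces two invariants the postprocessing rules rely on:
no CSF voxel is ever face-adjacent to a WM voxel (a repair pass relabels
violating WM to GM, mimicking the anatomical fact that the ribbon and
ventricle linings separate CSF from WM), and the dark structures
(ribbon, stripe, septum) are geometrically separated so their
dark-stripe responses form distinct connected components.

Atlas sets are made by warping the phantom with independent
Gaussian-smoothed (8 mm) white-noise displacement fields normalised to a
maximum magnitude (default 1 mm), trilinear for intensities and
nearest-neighbour for labels, plus intensity noise (default SD 5).
Planted corruptions mirror the three error patterns the postprocessing
repairs: a CSF pocket inside the main LH WM component, sulcal CSF
between the parcel banks filled with WM, and a gyral WM crown around the
thin strand relabelled as GM (the manual-edit scenario: the test writes
sentinels over the planted voxels and verifies exact restoration and
protection).

**What the phantom does not emulate:** MR acquisition physics, partial
volume averaging, realistic cortical-thickness variation and curvature
statistics, motion or Gibbs artefacts, and pathology.  Passing tests
therefore demonstrate the correctness of the implemented rules and their
interactions under the stated contrast model, not clinical-grade
performance on real scans.

## Validation sizes and numerical choices

- Unit and property tests validate the low-level operators against
  brute-force oracles (flood fill, exhaustive distance minimisation,
  offset-set morphology, per-voxel exhaustive fusion) on grids up to
  12³ across 100+ random seeds.
- Skull-strip recovery runs on ten 64³ phantoms at 1 mm (Dice ≥ 0.95,
  zero skull-stripe voxels retained).
- GM-mask behaviour is evaluated on a 96³ phantom at 0.63 mm — the
  production sampling, where the ribbon is ~5 voxels across; recall of
  the true ribbon is ≥ 0.8 with the planted periventricular component
  removed entirely.  At 1 mm sampling the 3-voxel ribbon loses its
  outermost layer to the GM/CSF edge and recall drops accordingly; this
  is a property of the method's edge-removal step at coarse sampling,
  not of the implementation.
- Fusion recovery runs at 64³ with five atlases (1 mm warps, noise SD
  5): structure Dice ≥ 0.90 for WM, GM, ventricles.
- Postfix round-trips, regions-image checks and force-image checks run
  on 64³ phantoms.

Numerical details worth knowing: mm→voxel kernel conversion uses exact
centre-distance thresholding with a 1e-9 epsilon (no radius rounding);
metric ball morphology is implemented via Euclidean distance transforms
and proven equal to footprint morphology in the tests; closings pad the
grid so border voxels are never clipped (guaranteeing
mask ⊆ closing(mask)); the "almost zero" gradient tolerance for the
directional second derivative is 1e-6 of the intensity range, which maps
perfectly symmetric stripe centres (zero gradient) to 0; discrete
Gaussian-derivative kernels leave a ~0.1 % residual on constant images,
so exact-zero assertions use tolerances; component and vote ties break
deterministically (scan order / lowest code) and are tested.

## Known limitations

- The fusion stage is a stand-in for a more sophisticated joint-fusion
  algorithm; it reproduces the weighted-voting description, not the
  correlated-error model.
- The SP march inherits the discrete LoG's positive lobe and stops one
  voxel short of a sheet centre; adequate as a registration guide.
- Hemisphere assignment uses Chessboard distance throughout; an
  alternative Euclidean assignment for the late "added voxels" step
  would differ on a small set of far-from-midline voxels.
- The sulcal-bank pair list ships with the canonical illustrative pairs
  only; production use requires the full pair configuration.
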