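# Methods

## Partition model

The liver is divided by explicit geometry derived from eight anatomical
landmarks, all in world millimetres (RAS+, the native NIfTI frame; data
in other conventions must be reoriented upstream). The IVC axis runs
from the inferior to the superior IVC landmark. Three vertical planes
are constrained to contain this axis, reflecting the anatomy of the
hepatic veins, which run roughly parallel to the IVC:

- **main (Cantlie) plane** — least-squares axis-plane through the
  middle hepatic vein and the gallbladder fossa; right hepatic vein on
  the positive (patient-right) side;
- **right intersegmental plane** — through the right hepatic vein;
  gallbladder fossa positive (anterior);
- **left intersegmental plane** — through the umbilical fissure; middle
  hepatic vein positive (medial).

The axis-constrained least-squares fit has a closed form: project the
target offsets onto an orthonormal basis of the axis-orthogonal
subspace and take the smallest-eigenvector of the resulting 2×2 scatter
matrix. With one target, or targets coplanar with the axis, the fit is
exact. The transverse division uses two planes perpendicular to the IVC
axis, one through each portal-vein landmark (not a single oblique
plane): the right portal plane splits 5/8 and 6/7, the left splits
4b/4a and 3/2, which lets the two hemi-livers be divided at different
heights, as the portal bifurcation sits lower on the right in most
livers. The caudate lobe (segment 1) hugs the IVC and is not separated
by any hepatic-vein plane; it is modelled as a cylinder of configurable
radius around the IVC axis, evaluated before all plane splits.

Classification is per voxel centre, no partial-volume weighting; signed
distances of exactly zero count as the positive side, making the
classifier a total deterministic function. Volumes are voxel counts ×
voxel volume (|det| of the affine's 3×3 block), so segment volumes sum
to the whole-liver volume exactly and volume fractions sum to one.

### Parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| `caudate_radius_mm` | 30 | mm | cylinder radius delimiting segment 1 |
| `min_voxels` | 10 | voxels | minimum map sample for a segment median |
| FLR thresholds | 20 / 30 / 40 | % | healthy / steatosis / fibrosis-cirrhosis safe lower limits |
| LOA multiplier | 1.96 | — | 95% limits of agreement |

The caudate radius is the one free geometric parameter: no landmark
marks the caudate boundary, so a single interpretable radius was chosen
over any multi-parameter rule; 30 mm gives a compact periaxial region
on a human-sized liver. FLR thresholds are configuration, not hard-coded
clinical advice. The LOA multiplier is the conventional Normal 95%
factor (no small-sample t correction), and the difference SD uses the
n−1 denominator, so reported LOA match the standard Bland–Altman
presentation. Percent-mode differences are normalised by the pair mean.

## Quantitative maps

cT1 and PDFF arrive as a handful of thick axial slices (cT1: 5 slices,
8 mm thick with a 12 mm gap; PDFF: 5 contiguous 20 mm slices). A shared
scanner world frame is assumed — no registration step: same-session
acquisitions share a frame, and breath-hold misalignment is therefore a
documented limitation, not corrected. The slab model assigns a volume
voxel the nearest in-plane pixel value of the nearest slice whose plane
lies within ±thickness/2 (closed interval; overlap ties go to the
earlier slice); voxels in gaps or outside the field of view are
missing. Nearest-neighbour lookup, not interpolation: medians of
quantitative maps should not invent values. Segments with fewer than
`min_voxels` non-missing values report no median — a segment clipped by
the 5-slice coverage can have an unstably small sample.

Two consequences of the slab model matter for interpretation. First,
each in-plane pixel is replicated across every voxel plane inside its
slab (about three at 3 mm spacing under an 8 mm slab), so the number of
independent measurements behind a segment median is the count of
distinct contributing pixels, not the voxel count. Second, where a
segment boundary is transverse to the slice normal, a slab mixes
neighbouring segments: the pixel value is generated at one height but
spread across the slab, so a segment's sample can contain values from
its neighbour. Noise-free medians still recover per-segment constants
exactly while the contamination stays below half the sample, but under
noise the sample median converges to the population median of the
mixture, not of the pure segment. The recovery tests therefore compare
against that population value (the root of the mixture CDF at 1/2) with
a 3·SD/√n tolerance, n being the distinct-pixel count.

## Synthetic phantom

The phantom is geometric, not anatomically realistic: the tests need
known ground truth, not realism. It is an ellipsoid (default semi-axes
90 × 60 × 75 mm, ~1.70 L) voxelized by centre inclusion at
1.2 × 1.2 × 3.0 mm, optionally perturbed by a smooth seeded radial
field (a normalized linear-plus-quadratic form of the direction vector).
Landmarks sit at fixed anatomical fractions of the semi-axes (IVC
posterior-midline, hepatic-vein points superior, gallbladder fossa
anterior-inferior, umbilical fissure left-anterior-inferior, portal
points mid-height), so the canonical phantom reproduces a fully
hand-checkable geometry: main plane x = 0, portal planes z = 45 and
z = 50. Map generation uses per-segment constants (cT1 700–860 ms,
PDFF 2–10%, distinct per segment so each median is attributable) plus
Gaussian noise (default SD 50 ms / 1%). Paired "repeat acquisition"
measurements follow a proportional error model: reading B equals truth
× (1 − (bias + ε)/100), ε ~ Normal(0, sd). All randomness is behind
explicit integer seeds.

What the phantom does **not** emulate: real liver shape and its
segment-volume distribution; vessel-tracked (curved) intersegmental
surfaces; scanner boundary-contrast bias (the volume underestimation
seen between scanner models arises from image contrast, which is not
modelled); breath-hold misalignment between maps and volume; lesions.
Passing tests therefore demonstrate the correctness of the geometry,
volumetry and statistics — not segmentation accuracy on patient MRI.

### Independent oracles and problem sizes

The test suite checks the implementation against independent
re-computations: a 10⁴-point brute-force angular grid for the
axis-plane fit; a scalar per-point classifier re-run at every voxel
against the vectorized labeller (100 random ~20³ phantoms); the
analytic ellipsoid volume and a 3× supersampled analytic labeling
(points tested against the ellipsoid equation, not the voxelized mask)
for volumetry; analytic Normal quantiles for Bland–Altman recovery
(n = 10⁴); and exact conservation and rigid-equivariance identities.
Recovery statistics use 100 seeds at the default phantom size; the
acceptance script uses 50 where the estimate is a hit-rate, which keeps
its full run around ten seconds.

## Numerical choices and edge cases

- Exact zeros of signed distance (a voxel centre on a plane, or a point
  at exactly the caudate radius) classify to the positive side.
  Bit-identical rigid equivariance consequently holds for grids whose
  voxel centres avoid the decision planes: an exact floating-point zero
  in one frame is a ±2⁻⁵² residue in a rotated one, so a lattice aligned
  with a plane (a measure-zero configuration) may flip those boundary
  voxels.
- Degenerate geometry raises named errors rather than guessing:
  coincident IVC landmarks, fit targets all on the axis, an orientation
  point on the fitted plane.
- The plane fit's eigen-decomposition is of a 2×2 symmetric matrix;
  with a single target the smallest eigenvalue is exactly zero and the
  fit passes through the target.
- Affines with negative determinant (e.g. LAS-ordered voxel axes) are
  handled throughout via |det|.
- Empty masks, 4D images, missing or extra landmarks, non-mm units and
  malformed pairs tables are rejected with specific errors; the CLI
  maps them to exit code 2.
- Bland–Altman percent mode rejects zero pair means; `a ≡ b` yields
  bias 0 with LOA [0, 0].

## Known limitations

Plane-based boundaries are an idealisation of vessel-following
intersegmental surfaces; the caudate cylinder is a pragmatic rule, not
anatomy; no connected-component post-processing is applied, so a
plane-defined segment can in principle be spatially disconnected on a
non-convex mask; map-to-volume alignment trusts the scanner frame. The
voxel-centre volumetry carries a quantization error of order half a
voxel along each plane, noticeable (±2–3%) for segments bounded by
transverse planes at 3 mm slice spacing.
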