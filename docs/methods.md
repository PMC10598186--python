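# Methods

This note documents the models, numerical choices and limitations of the
airway quantification pipeline, in the order the stages run.

## Inputs and geometry

All images are reoriented at load to RAS+ voxel order (increasing index →
patient Right / Anterior / Superior); every downstream computation works in
world millimetres, `world = origin + index · spacing`. Masks must share the
CT's grid exactly — the package never resamples, so a measurement can always
be traced back to the voxels that produced it. The display windowing helper
(level −500 HU, width 1500 HU by default — the standard lung window) is a
linear clip to [0, 1] used only for visualization; measurements always use
raw HU.

## Mask preparation

Airway segmentations stitched from several sources typically contain
single-voxel gaps and small disconnected islands. The clean-up is the
standard pair: morphological closing with a spherical element (radius in
voxels = radius_mm / spacing per axis, rounded up, minimum 1; default
radius = one voxel-equivalent, the smallest bridging that reconnects a
1-voxel gap), then retention of the largest 26-connected component.
26-connectivity is used throughout for foreground because thin distal
airways frequently touch only diagonally. Ties between equally large
components are broken by lowest flat voxel index, making the stage
deterministic.

## Skeletonization

The trachea seed is the foreground voxel nearest the centroid of the
largest component in the most superior 5% of foreground-bearing axial
slices — in an inspiratory chest CT the trachea is the only airway reaching
the lung apex level.

Thinning is a sequential, distance-ordered homotopic thinning written for
this package (`airquant._thinning`, numba-compiled): border voxels are
deleted one at a time in increasing order of the Euclidean distance
transform (anisotropy-aware, so the surviving curve stays medial in mm),
and only when the voxel is *simple* in the Bertrand–Malandain sense for
(26, 6) connectivity — exactly one foreground 26-component in the
26-neighbourhood and exactly one background 6-component in the
18-neighbourhood touching the centre's faces. Voxels with a single
foreground neighbour (curve endpoints) are preserved. Sequential deletion
with re-checks makes topology preservation unconditional: tubes reduce to
their centrelines and total erasure is impossible, for even- as well as
odd-width structures. Distance ties are broken by flat voxel index, so the
skeleton is a pure function of the mask.

## Graph construction

A 26-connected thin curve carries redundant diagonal adjacencies whose
"cycles" span only three voxels; these are not loops. `break_cycles`
therefore builds a shortest-path spanning tree from the root (Dijkstra,
Euclidean step weights) and, for every non-tree adjacency whose fundamental
cycle has at least four voxels, deletes the cycle's farthest degree-2 voxel
from the root — removing a genuine loop without ever orphaning a subtree.
Chain extraction then walks the spanning tree: nodes are voxels with ≠ 2
tree neighbours (plus the root); edges are maximal degree-2 chains,
oriented away from the root.

Two clean-ups follow, both logged: terminal spurs shorter than 2 mm
(configurable) are pruned as thinning artefacts of bumpy masks, and
internal edges shorter than the same threshold are suppressed by
contracting their distal junction into the proximal one — a trifurcation
that thinning split into two nearby bifurcations becomes a single division
again, with the short path prepended to the children's paths so geometry
stays contiguous.

## Anatomy

Generations count divisions from the trachea: the trachea is generation 0,
main bronchi 1, lobar bronchi ≈ 2. The default analysis window of
generations 2–6 therefore starts at the lobar bronchi; the window and the
numbering origin are configurable. A per-lobe ("lobar") generation —
counted from each lobe's seeding bronchus — is computed and exported but
not used in default summaries.

Lobe labels come from a direction-based heuristic on edge chord directions:
the first division splits right/left by the lateral (x) sign; on each side
the most superior-directed child seeds the upper lobe, and the most
anterior-directed child of the lower stem seeds the middle lobe (on the
left this is the lingula, labelled LML), the rest the lower lobe. All
descendants inherit their seed's lobe. The left rule deliberately mirrors
the right rule — treating the lingula as a left middle lobe — so that
mirroring a volume swaps R↔L labels exactly; this symmetry is a tested
invariant. Real lingular anatomy (branching from the upper-lobe bronchus)
deviates from this idealization; for atypical anatomy an explicit
`node_id → lobe` override file wins over the heuristic, with deeper
overrides beating shallower ones, and unresolved segments inherit their
nearest labelled ancestor and are flagged.

## Centreline splines and lengths

Voxel paths staircase, which inflates arc length; FITPACK smoothing splines
with a residual budget big enough to remove the staircase turned out to
oscillate at the millimetre scale on curved branches (inflating arc by ~2%),
so the spline stage instead (a) Gaussian-smooths the voxel path along its
index with σ = 2 × min-spacing (odd-reflection padding preserves end
positions and slopes), then (b) fits a near-interpolating cubic spline
(residual budget 0.1 voxel rms) parameterized by normalized cumulative
chord length. Arc length L_a uses quadrature at a step ≤ interval/10;
Euclidean length L_e is the distance between the spline's endpoints.

The medial axis bends into a junction over roughly one lumen radius, and
cross-sections there are not single-airway. Ends of a path that terminate
at a junction are therefore trimmed by min(25% of length, 3 mm) before
spline fitting; free ends (trachea origin, terminal tips) are not trimmed.
Diameter sampling keeps a further standoff of min(10%, 1 mm) per end.
Without the trim, short branches in non-tapering (bronchiectasis-like)
trees are dominated by junction cross-sections and read 10–30% too wide.

## FWHM edge-cued ellipse calipers

At every arc position (interval = half the smallest voxel dimension, the
dynamic rule; 0.4 mm for 0.8 × 0.8 × 1.0 mm voxels) a patch perpendicular
to the spline tangent is interpolated on a grid of the same pitch, at most
40 × 40 mm, with a deterministic in-plane basis (tangent × ẑ, falling back
to tangent × x̂ when vertical). Out-of-volume pixels are filled with
−1000 HU and counted; a sample whose centre leaves the volume is invalid.

The ray origin is re-centred to the centroid of the connected dark
(< −800 HU) region containing the initial centre, capped at a 2 mm shift —
the skeleton is only slightly off-axis, while near junctions the dark
region merges with the neighbouring lumen and its centroid can run away.

60 rays (configurable) at equal angles sample the profile at half the
patch pitch. Ray profiles are interpolated from the volume with a cubic
spline (coefficients prefiltered once per volume): linear interpolation
low-passes the wall bump, widening the fitted Gaussian and biasing the
half-maximum radius inward by ~0.3 voxel on coarse grids. Per ray: the
wall peak is the HU maximum beyond a 0.5 mm dead zone (rejected if it sits
at the patch border or its prominence over the lumen baseline — the
minimum HU between centre and peak — is under 100 HU); the wall is fitted
as a Gaussian by Caruana's log-parabola least squares over peak ± 2 mm
(points ≥ 20% of peak amplitude), falling back to a direct linear
interpolation of the half-maximum crossing when the fit degenerates; the
boundary radius is μ − σ·√(2 ln 2), the inner half-maximum point.
Boundary radii more than 3 scaled-MAD from the median are discarded; a
direct least-squares ellipse (Halir–Flusser, via scikit-image) over the
surviving points gives diameter = 2·√(r_minor · r_major). A fit is valid
with ≥ 60% accepted rays; a segment with ≥ 50% valid samples; a segment's
diameter is the mean over valid samples.

## Biomarkers and summaries

Tapering is 100·(d_p − d)/d_p — positive when the child is narrower, so
normal airways score ≈ 25–30 and traction bronchiectasis lowers the value;
the sign convention is written into the exported metadata. The root has no
parent and contributes no tapering. Tortuosity is L_a/L_e, clipped to 1
when marginally below from numerical noise. Patient summaries take medians
(midpoint convention) over valid window segments, report per-lobe and
per-generation breakdowns, and count every identified segment in the total.
A summary with zero valid window segments is flagged invalid. The survival
export emits one row per patient (tapering, tortuosity, segment count,
joined clinical covariates); an optional cohort z-standardization of
tortuosity is provided because cohort-level analyses often use it.

## Phantoms

Branches are tubes around `chord + A·sin(2πkt)·n̂` centrelines with radius
linear in t. The intensity model deliberately exercises the caliper's
assumptions rather than trivially satisfying them: dark lumen (−1000 HU),
parenchymal background (−850 HU), and a Gaussian wall (σ = 0.6 mm, peak
0 HU) centred at r + σ√(2 ln 2) so the analytic inner half-maximum falls
exactly on the lumen boundary. Rasterization supersamples 2× per axis and
averages, giving genuine partial-volume edges; the mask takes subsample
majority. The grid auto-sizes around the geometry with a fixed sub-voxel
origin offset so tube axes never align with voxel-centre symmetry planes
(real CT grids are never anatomy-aligned). Overlap of branches that share
no node is an error naming the pair; junction-sharing pairs legitimately
meet. Truth tables (lengths, tortuosity, arc-weighted mean diameter,
tapering versus parent) come from quadrature on the continuous centreline,
never from the image.

The standard six-lobe tree descends a 40 mm trachea from the most superior
slice, splits into main bronchi, seeds the six lobes with the directional
conventions the classifier expects, and grows each lobe as a herringbone
(one continuing child at −18°, one terminal child at +50°, alternating
rotation axes) to generation 6. Lengths decay gently (× 0.85 continuing,
× 0.70 terminal from 12–14 mm lobar bronchi) so distal branches remain
several times longer than their diameter, as real airways are; radii scale
by a per-tree child ratio (0.75 by default → 25% tapering; 1.0 with a 2 mm
radius is the bronchiectatic control). The cohort generator draws a
per-case taper fraction from U(0.20, 0.30) and a sinusoid amplitude from
U(0.0, 1.5) mm — plausible severity ranges for a fibrosis cohort — with
all randomness derived from a single seed; identical seeds give
bit-identical volumes.

What the phantoms do *not* emulate: fibrotic parenchymal texture
(honeycombing, reticulation), CT noise and reconstruction kernels beyond
optional white Gaussian noise, airway wall thickness variation, cartilage,
adjacent vessels, and segmentation errors. Passing the phantom suite
therefore demonstrates the geometric and numerical correctness of the
chain under the stated intensity model, not clinical-grade robustness.

## Problem sizes and determinism

Validation uses desk-scale cases chosen to keep the default suite quick:
single tubes of 40–60 mm at 0.6–1.0 mm voxels, full six-lobe trees at
(0.6, 0.6, 0.7) mm (~50 branches, grids ≈ 200×120×180), and a two-case
cohort for the determinism check. The main pipeline contains no random
number generation; all orderings are tie-broken deterministically, so
identical inputs and configs give byte-identical CSV outputs. Phantom
noise, when enabled, is seeded.

## Known limitations

* FWHM diameters carry a partial-volume bias of a fraction of a voxel;
  lumens below ~2 voxels diameter are at the resolution limit of any
  half-maximum estimator (the blurred lumen floor never plateaus).
* The lobe heuristic assumes a broadly typical branching geometry; the
  override file is the guaranteed-correct path.
* Tortuosity of very short segments (a few mm) is sensitive to the
  junction trim; values are reported but the generation 2–6 window keeps
  most analysed segments comfortably longer.
* The skeleton inherits any topological defects of the mask (loops from
  segmentation leaks are cut, but their geometry is not re-estimated).
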