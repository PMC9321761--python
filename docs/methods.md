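# Methods

This note documents the models, estimators and conventions implemented in
`pyporoscope`, the choices made where the design was genuinely open, and
what the synthetic phantoms do and do not demonstrate.

## Data model and conventions

Volumes are 3D scalar grids of isotropic cubic voxels with edge
`voxel_size` (µm). Indices are 0-based, axis order `(x, y, z)` with `z` the
slice index; arrays are indexed `data[x, y, z]`. All physically scaled
outputs are reported in mm, mm⁻¹, mm⁻², mm⁻³.

Raw files are headerless little-endian, x-fastest, with a JSON sidecar
`{nx, ny, nz, bits, voxel_size_um}`; TIFF stacks store one z-slice per
page. Voxel size is required metadata and never read from TIFF tags,
because every reported quantity carries physical units. The raw dialect is
a declared convention of this package, not a property of any particular
scanner pipeline.

Object connectivity is 26, background connectivity 6, everywhere —
segmentation, components, Euler characteristic, skeletonisation — the
standard complementary pair that avoids topological paradoxes.

Border handling for neighbourhood filters (median, erosion, dilation) is
edge-repeating reflection (scipy's `reflect`). On production-size volumes
borders are negligible; on the ≤ 20³ test fixtures they are not, which is
why the convention is fixed and the brute-force oracles use the same one.

## Filtering and segmentation

**Median filter.** Cubic window of odd width (default 3), reflect-padded.

**Otsu.** The threshold maximises between-class variance on the *native*
gray-level histogram (256 bins for 8-bit, 65,536 for 16-bit); the lowest
maximiser wins ties, so reported thresholds are reproducible gray levels
of the input. Object polarity is a flag (`above`, default, or `below`):
pores can be dark or bright depending on contrast mode.

**k-means.** 1-D Lloyd iterations on the gray histogram. Centroids are
initialised at evenly spaced quantiles of the gray distribution, which
makes the clustering deterministic for fixed data — for 1-D data this is
also a robust initialisation. Equidistant levels join the lower-centroid
class; classes are relabelled by ascending centroid. The within-class sum
of squares is recorded per iteration and is non-increasing; on
well-separated modes the final objective matches the exact 1-D
dynamic-programming optimum (tested). With more classes than phases the
surplus class does not come out empty: Lloyd splits the heaviest mode into
two balanced sub-classes with nearly coincident centroids, and that
centroid proximity — not an empty class — is the practical signature that
the sample has fewer phases than `k`.

## Morphology and grain separation

**Chamfer distance.** Two-pass 3-4-5 propagation divided by 3, i.e. face
step 1, edge step 4/3, vertex step 5/3 — within −6 %/+5 % of Euclidean on
the test geometries. Distances are measured to background voxels *inside*
the volume; an all-object volume is an error. The separation chain is
distance → negation → H-minima(h) → watershed, in that order.

**H-minima.** Morphological reconstruction by erosion of `f + h` over `f`
(26-connectivity). Regional minima shallower than `h` are absorbed;
surviving basin floors are raised by up to `h` (a constant field is raised
by exactly `h` — the relief, which is all the watershed sees, is
unchanged).

**Watershed.** Meyer-style flooding (scikit-image) from the regional
minima of the relief restricted to the mask, minima labelled in
linear-index order so results are deterministic. Ridge voxels are absorbed
into the first-flooding basin: the output is a partition of the mask, which
downstream blob counting requires.

## Basic Analysis (Minkowski + MIL)

**Volume density** `VV` is the object-voxel fraction.

**Euler characteristic** is computed exactly as `χ = V − E + F − C` on the
cubical complex of closed voxels (solid ball → 1, solid torus → 0, hollow
shell → 2), which realises 26/6 connectivity. The specific value
`χ_v = χ / VOI volume` indexes network connectivity.

**Surface area** uses the discrete Cauchy–Crofton formula
`S_V = 2 ⟨P_L⟩`: phase transitions are counted along the 13 lattice
directions (3 axes, 6 face diagonals, 4 body diagonals) and averaged with
spherical-Voronoi solid-angle weights of the direction set. The weights
are computed from the direction geometry at import time rather than copied
from a table. Accuracy: ~4 % high on a digitized r = 12 ball; up to ~7 %
low for plates exactly aligned with a lattice plane (the worst case of any
13-direction quadrature).

**Integral of mean curvature** uses the section formula `M_V = 2π ⟨χ_A⟩`,
with the planar Euler-characteristic density averaged over the three
axis-aligned section stacks (2D closed-pixel complexes, 8-connectivity).
For a ball this is exact up to the `(2r+1)/2r` slice-count factor.

**MIL fabric.** For each of `n_directions` (default 512) spherical-
Fibonacci directions, parallel test lines spaced `line_spacing` voxels
(default 2) are traced through the volume with a 1-voxel sampling step;
`MIL(ω)` = sampled line length inside the VOI / object↔background
crossings. Directions with zero crossings are dropped with a warning;
fewer than 9 usable directions is an error (the tensor fit would be
underdetermined). The MIL ellipsoid `1/MIL(ω)² = ωᵀHω` is fitted by least
squares; its sorted semi-axes `m1 ≥ m2 ≥ m3` give the Benn indices
`I = m3/m1` (isotropy) and `EA = 1 − m2/m1` (elongation). The `seed`
randomises only the global rotation of the direction set — two seeds agree
to ~3 % on the test phantoms, and the defaults resolve a single-axis
fabric direction to well under 5°.

## Blob analysis

Per component: voxel count, volume `= count · a³`, equivalent-sphere
diameter `d_eq = (6V/π)^{1/3}`, maximum-inscribed-sphere diameter, and
sphericity `= d_ins / d_eq`.

`d_ins = 2 (D_max − ½) · a`, where `D_max` is the maximum over blob voxels
of the exact Euclidean distance (scipy EDT) to the blob's complement. The
half-voxel term converts a centre-to-centre distance into a distance to
the blob boundary; it makes the convention exact for boxes: an a-cube
(including the degenerate 1-voxel blob) measures `d_ins = a` and
sphericity `(π/6)^{1/3} ≈ 0.806`. The exact EDT is used instead of the
chamfer transform because the chamfer's ~6 % off-axis bias is of the same
order as the discretisation slack the sphericity bound has to live inside.
Digitized balls approach sphericity 1 from below slowly (≈ 0.76 / 0.87 /
0.94 at r = 5 / 10 / 20): background voxel corners genuinely intrude into
a digitized sphere, so small-radius balls measure distinctly below 1.
Blobs touching the VOI border are flagged (`touches_border`), not removed;
`min_voxels` (default 1 = keep all) can drop sub-resolution blobs.

## Skeleton analysis

**Thinning.** Sequential directional border peeling in six sub-cycles
(U, D, N, S, E, W = +z, −z, +y, −y, +x, −x), iterated until stable. A
voxel is deleted only if it is *simple* — its removal preserves
26-object/6-background topology, tested via connectivity of the object in
the 26-neighbourhood and of the background in the 18-neighbourhood — and
not a curve endpoint (≤ 1 object neighbour). The border set of each
sub-cycle is frozen at sub-cycle start; a live border test would let one
sub-cycle cascade through the object and bias the skeleton towards one
face. Within a sub-cycle voxels are visited in linear-index order. The
thinning family leaves these order choices open and different valid orders
yield different, equally valid skeletons; determinism, not uniqueness, is
the contract here.

**Graph.** Skeleton voxels are classified by 26-neighbour count (1 = end,
2 = branch interior, ≥ 3 = junction). Junction voxels touching under
26-adjacency are merged into a single node: at a grid T-junction the
straight-through neighbours are unavoidably diagonal to the first crossbar
voxel, so per-voxel junctions would split one anatomical node into a
cluster and manufacture spurious cycles. Maximal interior chains between
terminals form branches, typed node-to-node, node-to-end or end-to-end;
a closed ring with no terminal is one self-closing branch of type `cycle`;
an isolated voxel is an end-to-end branch of length 0. Branch length sums
voxel steps weighted 1/√2/√3 × voxel size.

**Pruning** removes node-to-end branches shorter than `min_length` voxels
(the reference protocol uses 5), keeping the junction side, then re-thins
and re-extracts until stable — pruning can demote a junction and merge its
remaining branches, and re-thinning clears spur bases held only by
diagonal contacts. Node-to-node, end-to-end and cycle branches are never
pruned, so loop topology is preserved. Pruning happens on the skeleton
volume; the graph is re-extracted afterwards.

**Connectivity density** is the first Betti number of the branch
multigraph, `β1 = E − V + C` (cycle branches contribute a self-loop on a
base vertex; zero-length isolated-voxel branches contribute a vertex
only), divided by the VOI volume in mm³. For connected skeletons without
cavities `β1 = 1 − χ`, which the tests cross-check against the Euler
module.

## Trabecular morphometry

The indirect plate-model identities: `TbTh = 2/BsBv`, `TbN = BvTv/TbTh`,
`TbSp = 1/TbN − TbTh`, with `BvTv` the solid voxel fraction and `BsBv` the
Crofton surface estimate over solid volume. The identities hold to machine
precision by construction; accuracy on a structure is governed by how
plate-like it is and by the surface estimator (a parallel-plate phantom
reproduces its constructed thickness and separation to ~7 %, dominated by
the aligned-plate worst case of the surface quadrature). A fully solid VOI
has no internal surface: the result degenerates to `TbTh = ∞`, `TbN = 0`,
`TbSp = 0` rather than erroring. The scalar entry point
(`morphometry_from_scalars`) applies the identities to externally measured
`BvTv`/`BsBv` pairs.

## Phantoms

Every phantom digitizes an implicit solid by the centre-inclusion rule (a
voxel is object iff its centre satisfies the inequality; no antialiasing),
so voxel-count ground truths are exact enumerations. Each generator
returns an analytic truth record (volume, surface, χ, fabric axis,
plate-model indices, grain count — whatever applies) alongside the volume;
tests consume the record rather than recomputing ground truth. Random
phantoms draw from one `numpy` generator seeded per spec; gray-level noise
uses a decorrelated sub-seed.

Default study conditions used by the tests and the acceptance script:

* Boolean ball model: grain radius 6 vox, target coverage 0.3 in 64³
  (stationary: centres Poisson in the r-dilated domain; coverage follows
  `1 − exp(−λv̄)`).
* Gray phantoms: phase means 60/180 (two-phase) or 20/110/220 (three-phase
  air/brine/grain contrast), Gaussian σ = 10 or 8 gray levels — mode
  separations comfortably above noise, as in well-exposed µCT data.
* Touching-grain pack: 8 ball grains, r = 16 vox, on a 28-voxel jittered
  lattice in 72³. Axis-neighbour overlaps give neck radius ≈ 7.8 vox and
  catchment-basin depth ≈ 8 vox, so the reference H-minima depth h = 4
  separates all grains; substantially heavier fusion genuinely merges
  basins at h = 4 and would test the geometry, not the algorithm.
* Parallel-plate stack: thickness 8, period 40 vox at 5 µm, offset so all
  plate faces are interior (a face on the VOI border is invisible to
  surface estimation).

What the phantoms do *not* emulate: CT physics (beam hardening, rings,
phase-contrast fringes), partial-volume gray gradients at interfaces,
polydisperse grain packs, and anisotropic voxels. Passing tests therefore
demonstrate correctness of the estimators on clean digitized geometry and
the documented noise model, not robustness to acquisition artefacts.

## Protocols

Three pipelines mirror the standard analysis workflows: pore analysis
(median → Otsu → opening → basic/blob/skeleton analysis), multiphase
separation (k-means → phase mask → chamfer → negate → H-minima → watershed
→ components → blob table), bone morphometry ((Otsu) → plate-model
indices). Defaults follow the reference parameter set: median width 3,
erosion/dilation width 3 (erosion-first opening by default; `closing`
swaps the order), pruning length 5, h = 4, connectivity 26. Blob analysis
runs on the opened mask, before any watershed. Config files are flat
`key = value` text; CLI flags override file values; every stage parameter
is echoed to the run log, intermediates are written with stage-indexed
names, and no protocol path contains unseeded randomness — identical
config and input reproduce reports byte for byte.

## Problem sizes

The test suite and the acceptance script run phantoms at 32³–72³ and
oracle comparisons at ≤ 12³ with 100 random draws per operator — sizes at
which brute-force enumeration is exact and the whole validation completes
in about a minute on one core. The estimators are resolution-consistent
(tested via voxel-size scaling relations), so conclusions transfer to
production volumes up to the stated discretisation errors, which shrink
with resolution.

## Known limitations

* Surface/curvature estimates carry the anisotropy of their direction and
  section quadratures (worst case ~7 % for lattice-aligned plates).
* MIL uses nearest-neighbour line sampling at 1-voxel steps; structures
  thinner than ~2 voxels can be undersampled.
* Junction merging reports one node per 26-connected junction cluster;
  degenerate tangles (e.g. three mutually adjacent junction voxels fed in
  as hand-drawn fixtures, not produced by the thinning) can still inflate
  β1.
* The plate model is exact only for plate-like architectures; rod-like
  structures bias TbTh low.
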