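# Methods

This note documents the models, conventions and numerical choices behind
vtscope, and what the synthetic phantoms do and do not establish about
real light-sheet data.

## Coordinate and intensity conventions

Stacks are `(channel, z, y, x)` with anisotropic spacing `(dz, dy, dx)` in
µm (default 1 × 0.5 × 0.5 µm, the native sampling of the targeted
light-sheet acquisitions).  A voxel centre sits at `index * spacing`; all
distances, lengths, diameters and volumes are reported in µm / µm³.
Channels are treated independently and never normalized against each
other — across imaging sessions only the signal/background thresholds are
meant to be adjusted, which the configuration exposes per channel.

## Preprocessing

* **Median filter**: "setting 2.0 per axis" is interpreted as a box
  neighbourhood of half-width 2 voxels (5×5×5), the convention of the
  classic ImageJ Median 3D filter, with replicated edges.  The filter is
  verified voxel-for-voxel against a brute-force sliding-window median.
* **Combined channel**: voxelwise sum of all fluorescence channels,
  saturating at the dtype maximum; idempotent (an existing combined
  channel is not summed again).
* **Spheroid body**: the commercial surface tool the workflow emulates is
  proprietary, so "surface detail *d*" is fixed as a documented surrogate:
  Gaussian smoothing with σ = d/2 before thresholding (d = 10 µm for the
  body, 2 µm for individual channels).  The body mask keeps the largest
  26-connected component and fills interior holes (6-connected
  background); reported volume is exactly voxel count × voxel volume.
* **Thresholds**: the default rule is Otsu on the smoothed channel.  A
  fixed quantile was considered but presumes a fixed foreground fraction,
  which varies over two orders of magnitude between channels (vessels vs
  the tissue-filling tumor signal); Otsu is parameter free and behaves
  consistently across the panel.  Quantile and absolute rules remain
  available per channel in the configuration.

## Cell detection

Point-like cells (nominal diameter 10 µm) are localized with a
single-scale Laplacian of Gaussian at σ = diameter/(2√3) µm, converted to
voxel units per axis.  Local maxima of the negated response are kept if
above mean + k·σ of the response volume (k = 5 by default) and if their
centre lies at least 0.45 diameters deep inside the body mask — the depth
cut suppresses the rim response of the spheroid surface itself, at the
cost of missing genuinely superficial cells.  Detection is fully
deterministic.

## Vessel tracing

The CD31 mask is thinned to a one-voxel skeleton (3D topological
thinning, performed on the voxel grid; an approximation when dz ≠ dx,
since all subsequent geometry is computed in µm).  Skeleton voxels are
assembled into a graph: junction voxels (26-degree ≥ 3) are clustered
into branch nodes, degree-1 voxels are endpoints, and maximal branch-free
chains become segments.  Tip ("spur") segments shorter than 5 µm are
removed and the skeleton re-collapsed; 5 µm suppresses single-voxel
thinning artifacts without deleting real tips at this resolution.

A degenerate case is handled explicitly: the thinning implementation can
annihilate perfectly mirror-symmetric tubes of even voxel width (an
axis-aligned rendered cylinder can trigger this).  If the skeleton of a
non-empty mask comes back empty, the mask is shaved by one voxel plane on
one side (z, then y, then both) and re-thinned — a half-voxel geometric
bias that is logged when it occurs.

* **Diameters**: the local radius at a skeleton point is its anisotropic
  Euclidean distance to the nearest background voxel centre; a segment's
  mean diameter is twice its mean point radius.  Voxel-centre semantics
  bias radii by up to half a voxel diagonal.
* **Branch levels**: per network, the main branch is the
  endpoint-to-endpoint path of maximal total length on a maximum-length
  spanning tree (ties broken by the lexicographically smallest endpoint
  pair).  Its segments are level 0; every other tree segment is 1 + the
  level of the segment it attaches to; cycle-closing chords (anastomoses)
  get 1 + the minimum level at their two attachment nodes.  The
  assignment is verified against exhaustive path enumeration on random
  trees.
* **Network statistics**: mask voxels are assigned to the network of the
  nearest skeleton voxel, partitioning the CD31 volume exactly.  The
  segments-per-network scalar (S/N) used by the ranking model is the mean
  over networks — the aggregation is not uniquely determined by the
  source description; the mean was chosen and is used consistently.

## Distance fields and supply index

Distances are voxel-centre to voxel-centre in µm, computed with the
anisotropic Euclidean distance transform, and defined only inside the
body mask and outside the vessels; out-of-domain voxels carry NaN.  The
fixed-range 8-bit export (255 = outside) is provided separately so the
sentinel can never contaminate histograms.  The supply index is
`SI = relative CD31 volume (%) / median distance (µm)`, oriented so that
higher = denser, more homogeneous supply.  Whether the source intended
this ratio or its reciprocal is ambiguous; the ratio was chosen so that a
positive treatment effect on supply raises SI.  Col IV within 3 µm of a
vessel (configurable) counts as vessel-associated — an apposition scale
matching basal-membrane contact at this resolution.

## Descriptor registry

The registry is a versioned, explicit list of named, unit-annotated
parameters grouped into families (size, composition, per-population cell
statistics, vessel network, distance field, macrophage, ECM, hypoxia).
The exact published parameter list is not reproduced in the available
text, so the registry fixes its own: the full six-channel panel defines
exactly 71 parameters and the three-cellular-channel core exactly 46 —
these cardinalities are a contract enforced by tests, and any future
reconciliation is a registry version bump.  Families whose channels are
absent are dropped whole and logged; in strict mode they raise.

## VEI calibration

`VEIModel` is a scikit-learn-style regressor for
`VEI = Σ xᵢ·rᵢ^yᵢ` over the ratios (rV, rSI, rSN).  Fitting is the
two-stage procedure: ordinary least squares for the weights with
exponents fixed at 1, then bounded trust-region nonlinear least squares
over all six parameters (weights in [−10, 10], exponents in [0.1, 5],
initialized from stage 1) — deterministic given the data.  Designs
without variation in a ratio column raise a degenerate-design error.
The reference calibration x = (0.6, −0.11, 0.44), y = (0.65, 1.5, 1.5)
ships with the package.

Observer scores use the canonical five-tier scale −1, −0.5, 0, +0.5, +1;
files recorded on a ±2-step scale are divided by 2 on import.  Eq-style
ratios are treated-group means over control-group means.  Compartment
effect indices use b(r) = (r−1)/(r+1): bounded, antisymmetric
(b(1/r) = −b(r)), zero at no change; signs are set so the named effect
(vessel regression, network disruption, compartment expansion) is
positive.

## Synthetic phantoms

The generator emulates what the analysis consumes, not the optics: a
spheroid body (diffuse texture in the tumor and fibroblast channels),
stochastic branching vessel trees (persistent random walks with a
per-step branching probability, radii tapering monotonically root→tip)
rendered as tubes into the CD31 channel, non-overlapping 10 µm cell orbs
(rejection-sampled, capped at 10⁴ attempts), Gaussian PSF blur, Poisson
shot noise, additive Gaussian read noise and a constant background.
Everything is deterministic per seed, and the noiseless masks,
centerlines with radii, and centroids are returned as ground truth.

Not emulated: lumina inside vessels, clearing/refractive-index artifacts,
light-sheet stripe shadows, intensity falloff with depth, or realistic
cell-shape variation.  Passing phantom-recovery tests therefore
demonstrates the correctness of the measurement chain, not robustness to
every real-world artifact.

Ranking datasets draw ratios log-uniformly from [0.25, 4] — spanning the
magnitude of treatment effects the assay is meant to resolve — and set
os = VEI(reference model) + Gaussian noise.  Clipping to the [−1, 1]
observer scale is available but off by default, because strong simulated
effects exceed the scale and clipping would break the exact
os-equals-model identity the generator guarantees.

## Problem sizes

Real VTSs are 300–500 µm across; at native spacing such a stack exceeds
10⁹ voxels.  The package's own experiments use geometrically similar
phantoms at reduced radius: 55 µm in a 256³ stack for end-to-end recovery
and the full-panel registry run, 20–30 µm for unit-level fixtures and the
PCA archetype study (three archetypes differing in size, vessel density
and cell ratios; three replicates each).  Oracle-equivalence checks run
on ≤32³ random instances where brute-force enumeration is exact.

## Known limitations

* Skeleton length slightly over- or under-estimates true centerline
  length (junction geometry, tip retraction ~ one radius); recovery is
  validated to within 10% at the 256³ scale.
* Blob detection assumes roughly spherical, similarly sized cells; it is
  a surrogate for the commercial spot detector, as is the Gaussian
  surface-detail segmentation.
* The S/N aggregation (mean), the SI orientation, and the effect-index
  map b(r) are documented package choices where the source is ambiguous.
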