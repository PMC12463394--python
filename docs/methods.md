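# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Units and conventions

All in-memory lengths are nanometres; ångströms exist only inside MRC
headers (header pixel size = 10 × voxel size). Volumes are indexed
`grid[z, y, x]`, 0-based, with values at voxel centres; on disk the MRC X
axis is fastest-varying, per the format. The pipeline operates on
*density-positive* volumes (membrane = local maximum); cryoET maps with
inverted contrast are flipped at load time (`read_volume(..., invert=True)`).
Coordinate loaders never guess a voxel size — picks can refer to any
binning level, so `units="voxel"` requires an explicit `voxel_size` and
the conversion is applied exactly once. The working scale throughout is
1.194 nm/voxel, the 4×-binned reconstruction pixel used for annotation
and density analysis.

## Molecular crowding profiles

Crowding is measured as 1D intensity line profiles, by default 36 nm wide
and 450 nm long, on **single** tomographic slices. Projecting slices
before profiling smears a slightly tilted membrane into the cytoplasmic
signal, so each slice is profiled independently, its membrane peak is
detected (maximum within ±15 nm of the user anchor), and the profile is
shifted so that peak sits at distance 0 before any averaging. Slices
whose unaligned peak deviates from the median across slices by more than
a tolerance (default 5 voxels) are excluded as tilted in the slice plane.
Width averaging uses `round(width / voxel_size)` interpolated lanes (30
lanes at 1.194 nm/voxel) per sample, trilinear interpolation throughout.

The per-synapse statistic pools the per-slice voxel intensities falling
in the proximal window (default 5–30 nm, the region where a postsynaptic
density would sit) and the distal window (50–200 nm) across included
slices, and applies a two-tailed Welch *t* test. Welch rather than pooled
variance because the windows differ ~8-fold in size; with equal variances
Welch converges to the pooled test, so nothing is lost. Significance is
Bonferroni-corrected by the number of synapses in the analysed panel
(`bonferroni_m`); classification is `higher` / `lower` /
`not_different` by the sign of the mean difference at p < α/m.

## Cleft height

The cleft is the multiset of point-to-point nearest-neighbour distances
PreSM→PoSM and PoSM→PreSM, pooled bidirectionally (the symmetric choice
when no direction is privileged). Distances beyond a 60 nm cutoff — the
empirical upper bound of real cleft measurements, promoted here to the
cleft-zone definition and configurable — are flagged out-of-cleft, never
dropped; a PoSM point is "in the cleft" iff its nearest-PreSM distance is
within the cutoff. Summaries report both the mean of per-synapse means
and the pooled mean, since the two differ when synapses contribute
unequal point counts. The distance distribution is a Gaussian KDE with
Silverman's bandwidth on a grid padded 3 bandwidths beyond the data range
(so the density integrates to 1 within 1e-3); KDE local maxima are
reported as modes, which resolves the two plateaus of bimodal clefts with
closely-apposed and remotely-spaced subregions. Distances are
point-to-point, not point-to-surface; with ~10 nm membrane sampling this
overestimates true separation by well under 1 nm (verified on concentric
shells in the tests).

## Geodesic receptor clustering

Receptor-pair distances are measured along the membrane: the segmented
PoSM cloud is meshed, receptors are projected to their Euclidean-nearest
mesh vertex (lowest index on ties), and distances are shortest paths on
the edge-weighted mesh graph via Dijkstra — edge-graph shortest paths,
not exact polyhedral geodesics, with the discretisation error bounded by
a refinement-convergence test (≤5% change when halving edge length on
sphere fixtures). DBSCAN with eps = 70 nm and min size 4 (standard
core-point semantics, so every cluster has ≥4 members) runs on the
precomputed matrix; +inf entries between disconnected mesh components are
mapped to a large finite sentinel, i.e. never neighbours. Surface rather
than straight-line distance matters because receptor groups on opposite
faces of a folded membrane can be <70 nm apart in space yet hundreds of
nm apart along the membrane; a dedicated test constructs exactly this
fold.

Mesh reconstruction is crust-style in behaviour, not implementation:
sheet-like clouds (smallest principal extent below 0.25× the next) are
triangulated by 2D Delaunay in the principal plane — exact for planar
patches — and 3D-extended convex clouds (spherical shells) use the convex
hull. Strongly folded sheets are not reconstructable from the bare cloud
by this route; for those the parametric `grid_mesh` builder accepts an
explicit (u, v) sampling. Meshes above the face budget (default 10,000
faces, chosen so typical edge lengths stay far below eps) are simplified
by Garland–Heckbert quadric edge collapse; collapses violating the link
condition are rejected, which preserves the Euler characteristic.

Cluster location classes follow a member-based rule: `cleft` if every
member projects to in-cleft membrane (cleft-zone flags transferred from
PoSM points to mesh vertices by nearest-point vote), `perisynaptic` if
none does, `boundary` otherwise.

## CryoCLEM registration and puncta

Fluorescence-to-EM registration fits y = sR·x + t (similarity) by
default — the mapping between two views of a flat grid square is
dominantly a scaled rotation — with full affine behind a flag. Fits with
fewer than 10 fiducials succeed but warn. Puncta segmentation smooths
with a Gaussian (default σ = 2 px), thresholds by Otsu on the smoothed
image, seeds a watershed at local maxima, and filters puncta below
`min_area` on their above-threshold core. Integrated intensity sums the
*raw* pixels over each punctum's full watershed catchment basin, so the
dim tails of a spot count and the per-punctum sums plus background
conserve the image total exactly. Multi-channel bleed-through rejection
is reduced to an optional exclusion mask.

## Dataset reporting

Prevalence treats the mouse as the biological replicate: one percentage
per mouse, summarised as mean ± SEM with the sample (n−1) standard
deviation. Pearson correlations report two-sided p from the t
distribution with n−2 df. Percentages are stored at full precision and
rounded only for display.

## Synthetic scenes

The generator emulates the geometry the analyses assume, with defaults
set to the study conditions: paired membrane sheets at 33 nm separation
(per-scene configurable across the observed 27–37 nm range, or a lateral
two-plateau step for bimodal clefts), a 1.3 μm lateral field, ~12 nm
membrane sampling (within the 4,000–20,000 points-per-membrane regime of
real segmentations), receptor patterns as a Thomas process (uniform
parent centres under a minimum-separation guard, Gaussian σ = 20 nm
offspring, ~10 per cluster — the minimal generative model consistent
with nanodomain-like clustering), and a 14 nm receptor ectodomain height.
Rendered volumes draw each membrane as two Gaussian leaflet ridges 5 nm
apart (width 2 nm), add a configurable cytoplasmic crowding profile as a
function of signed distance from the PoSM, optional receptor blobs,
anisotropic blur and Gaussian noise, at 1.194 nm/voxel.
`make_flat_profiles` fabricates per-slice 1D profiles directly (membrane
ridge σ = 1.5 nm, flat cytoplasm, optional proximal bump) for
statistical tests where volume rendering adds nothing.

Every generator is a pure function of its seed. What the synthetics do
**not** emulate: CTF and missing-wedge artefacts (only a coarse z-blur),
organelles and vesicles, membrane segmentation error correlated along
the membrane, and receptor shape beyond a Gaussian blob. Passing tests
therefore demonstrate correctness of the measurement pipeline on scenes
whose ground truth is known, not robustness to real reconstruction
artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script use scenes of 400–900 nm lateral extent
with 8–15 nm sampling (≈1,000–6,000 points per membrane), 100-seed
replicate sets for stochastic claims, and a 27-synapse crowding panel —
sizes chosen so the full suite runs in well under a minute while keeping
every estimate's sampling error far below the tolerances being asserted.
Degenerate inputs fail loudly: empty point tables, all-excluded profile
sets, sub-minimum fiducial counts and collinear clouds raise typed
errors rather than returning defaults. Ties are broken deterministically
(lowest index) in nearest-neighbour and projection steps, and DBSCAN
labels are deterministic given row order.
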