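# Methods

This note documents the models, numerical conventions and design choices of
the package, and what its synthetic tests do and do not show.

## Volume model

A morphology is treated as the centerline point cloud of its SWC nodes;
radii are carried through I/O and transforms but never enter registration.
Space is divided into cubic voxels of edge length *v* with one voxel
centered at the origin; voxel *i* along an axis covers
[i·v − v/2, i·v + v/2), so a coordinate maps to index floor(x/v + 1/2).
Half-open intervals make boundary assignment unambiguous. Before
voxelization, edges are resampled so consecutive connected points are at
most *v*/4 apart. A spacing of *v*/2 is the minimum that guarantees a
straight segment touches every traversed voxel; the factor-two margin keeps
the same cached point cloud valid when registration candidates stretch it by
scale factors up to 2, and makes the voxel sets used by the searches and by
the trace identical.

## Dissimilarity measures

Pairwise dissimilarity is D = 1 − |A∩B| / |A∪B|. The centric variant
translates the test morphology so the centroid of its *occupied voxel
centers* (not its node centroid) matches the reference's before
re-voxelizing; using voxel-center centroids keeps both operands in the same
discretized space, which matters when the reference is a bare voxel set with
no nodes (group iterations). The centric translation is applied in
continuous space, not snapped to the grid.

The group measure builds the voxel-occupancy histogram, weights each count
by its occupancy, normalizes to unit sum, and takes the 1-D
Earth-Mover-Distance to the point mass at occupancy N with ground distance
|i − j| in raw occupancy units; the closed form is Σₖ pₖ(N−k). A normalized
variant divides by N − 1 so fully disjoint groups score 1 regardless of
group size; raw units are the default and are what the solution selection
uses. Internally all dissimilarities compared by the registration loops are
exact rationals (voxel-count fractions), so "strictly decreased" is never a
floating-point judgement.

## Transform conventions

Transforms apply as x′ = R·(S·(x − c)) + c + t with R = Rz·Ry·Rx (extrinsic
rotations about the world axes, degrees) and strictly positive per-axis
scales — reflections are unrepresentable by construction, matching the
algorithms' stated scope. No rotation convention is canonical here; this one
is fixed, documented and tested, and the searches span the same angle cube
under any such choice. Rotation and scaling pivot at the moving morphology's
current node centroid, recomputed after every applied step. Radii are
multiplied by the cube root of the determinant of the linear part
(cosmetic only). Random test transforms draw every parameter uniformly on
its interval — scales uniform in *linear* scale on [0.5, 2] — whereas the
search grids sample scale log-uniformly; the two uses are distinct (one
defines test conditions, the other a search lattice symmetric about the
identity).

## Pairwise registration

Default voxel-size ladder: 160, 80, 40, 20, 10 μm (geometric halving down to
a 10 μm finest scale, a compromise between feature resolution and noise).
Coarse levels on which the morphologies span only a couple of voxels are
dropped: levels coarser than one eighth of the larger bounding-box diagonal
of the two inputs are removed. At such levels the overlap objective cannot
discriminate a 10° rotation step, the coarse estimate ties toward zero, and
the refinement windows would then permanently exclude the true parameters —
this clip threshold was the single most important robustness choice in the
implementation.

Initial grids at the coarsest kept level: rotation ±30° per axis in 10°
steps; translation ±2v per axis in v/2 steps; scale 7 log-spaced samples per
axis over the allowed bounds. Each finer level searches the previous
estimate ± one previous inter-sample step with 5 samples per parameter (odd,
so the previous estimate stays a candidate); a level's "uncertainty" is thus
its inter-sample interval, which guarantees the coarse optimum stays inside
the refined window. Exhaustive-search ties are broken by the candidate
nearest the identity (Euclidean norm of the parameters; log-scale for
scales), then by candidate order, making the whole search deterministic.

The loop alternates translation and rotation estimation (translation first,
fixed for determinism; the two do not interact) applying a step only if it
strictly decreases the finest-level dissimilarity, then applies at most one
scaling step per outer pass, and stops when a full pass applies nothing, or
after 30 outer passes (a safety cap; the trace-minimum solution rule makes
it harmless). Scale estimation uses the centric measure; each scaling step
searches only the interval still admissible given the scaling already
applied in the call, so one registration's total scaling stays inside the
configured bounds ([0.5, 2] per axis by default). The returned solution is
the earliest trace state with minimal finest-level dissimilarity — the
result can therefore never be worse than the initial centroid alignment.

## Group registration

Iteration 0 centroid-aligns all members to a chosen initial reference and
competes as a candidate solution (so the algorithm is never worse than doing
nothing). The first iteration registers everything to that member's volume;
later iterations use the union of all registered members' voxel sets — the
conservative average that keeps not-yet-overlapping parts represented. No
centroid alignment happens inside group iterations (the pairwise call runs
with its initial alignment disabled). Acceptance compares the dissimilarity
vectors (coarsest → finest) before and after each pairwise registration
lexicographically and requires strict improvement at the first differing
level; rejected members pass through unchanged. Cumulative per-axis scaling
is tracked per member and the interval [0.5, 2] / cumulative (clamped to
contain 1) is handed to the next pairwise call. The run stops when an
iteration rejects everything or after 20 iterations. The iteration with
minimal occupancy-based group dissimilarity at the smallest voxel size wins,
and all members are mapped by the inverse of the initial reference's
accumulated transform, which returns that member exactly to its input frame.

## Synthetic data

The generator grows a seeded branching walk: persistent-direction steps of
Gaussian length, random branching, reflection at the walls of a bounding
box. The defaults — 300 nodes, extent 300×300×40 μm, steps 10±2 μm, branch
probability 0.15, direction jitter 0.6 — produce a dense, *nearly planar*
arbor of ~3 mm cable. They emulate the flattened tangential-cell dendrites
that volume-overlap registration targets: density and approximate planarity
are what make the overlap objective informative at a 10 μm voxel size.
Sparse isotropic 3-D trees of the same node count make the finest-level
overlap landscape essentially flat and registration of large combined
transforms unreliable — a genuine property of the method, not of the
implementation.

Test suites apply random affine transforms (translation U[−20, 20] μm,
rotation U[−30, 30]° per axis, scale U[0.5, 2] per axis, pivoted at the
perturbed morphology's centroid, which keeps cases inside the search ranges)
to noisy copies (per-coordinate Gaussian noise) while preserving node ids,
so ground-truth correspondences are available. Suites can be stratified by
the anisotropy of the planted scaling (MAS). Desk-scale defaults (tens of
cases) keep full-suite runs in minutes; the full randomized protocol
(1000 noiseless + 100 per noise level) is one configuration of the same
generator. What passing these tests shows: the estimator removes affine
differences between *identical* underlying geometries under moderate noise.
What they cannot show: behavior under non-affine inter-specimen variability,
reconstruction artifacts, or real arbor geometry.

## Evaluation

Distances between corresponding points (by id for synthetic tests, nearest
neighbor among test points for each reference point otherwise, ties to the
lowest id) are tested against the smallest voxel size with the exact
binomial sign test, one-sided, ties counted as failures (conservative), at a
1% level. The exact sign test is the primary statistic; a Wilcoxon
signed-rank variant is available behind a flag for sensitivity analysis,
since the two names are often conflated and the rank version uses more of
the data under symmetry assumptions. Suite distance tables are summarized
per test (across points) and per reference point (across tests).

The PCA baseline assumes the sorted principal axes of the two morphologies
correspond and that they are similarly oriented. The returned transform
reports the rotation mapping the test's principal frame onto the
reference's (axis signs chosen for a proper rotation of maximal trace, i.e.
the smallest such rotation) and the per-axis *scaling differences*
σ_test/σ_ref along corresponding axes; `pca_registration_matrix` assembles
the exact registering map, which applies the reciprocal scales in the
principal frame. Reporting differences rather than correction factors keeps
the scale values directly comparable with planted scalings and MAS. With
two nearly equal variances (consecutive σ ratios within 1%) the axis
correspondence is ill-defined; the rotation is skipped with a warning
rather than guessing an axis pairing.

## Density profiles

Each member is resampled to ≤ 0.1 μm spacing, binarized on a shared
0.25 μm grid (origin-centered convention shared with the registration
voxelization), smoothed with a discrete Gaussian kernel truncated at 3σ and
renormalized to exact unit sum, and averaged. The grid is padded by 3σ so
no kernel mass leaves it; values are occupancy fractions in [0, 1] and the
σ → 0 limit is exactly the fraction of members crossing each voxel. The
kernel σ is a required per-group choice (it sets the visual smoothing
scale and has no universal default).

## Known limitations

- Affine transforms only: no shear parameter, no reflections, no non-rigid
  deformation.
- Centerline volume model: radii and frustum geometry are ignored.
- Heavily anisotropic scaling differences (MAS ≳ 0.37) are a known failure
  mode of the pairwise search; the solution-selection rule only guarantees
  the result is no worse than centroid alignment.
- Exhaustive grids are deterministic but their densities are heuristics;
  grid-incompatible true parameters are recovered only to the finest step.
- The voxel-index packing supports coordinates up to ±2²⁰ voxels per axis.
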