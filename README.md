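# regmaxs

Spatial co-registration of neuron morphologies by maximizing voxel-volume
overlap: pairwise registration (Reg-MaxS) and groupwise registration by
iterative averaging (Reg-MaxS-N), for SWC reconstructions.

Morphologies of the same neuron type reconstructed from different specimens
share a stereotypical gross structure but arrive in different coordinate
frames, sizes and orientations, and differ in their fine branching. To study
that stereotypy — or to build density maps of a neuron type — the
reconstructions must first be brought into a common frame without relying on
a standard-brain atlas or on point-to-point correspondences, which fine-scale
biological variability makes meaningless. This package registers
morphologies using only their coarse volume overlap.

## The measures and algorithms

A morphology is discretized into the set of cubic voxels (edge length *v*,
one voxel centered at the origin) containing at least one of its points.
For two voxel sets the spatial dissimilarity is

    D(setA, setB) = 1 − n(setA ∩ setB) / n(setA ∪ setB)

(one minus the Jaccard overlap). The *non-centric* form uses the sets as
they lie (for translation/rotation estimation); the *centric* form first
aligns the occupied-voxel centroids (for scale estimation). For a group of
*N* morphologies, the occupancy of a voxel is the number of members touching
it; the group dissimilarity is the 1-D Earth-Mover-Distance between the
occupancy-weighted, normalized histogram and the perfect-overlap histogram
(all mass at occupancy *N*), which has the closed form Σₖ pₖ·(N−k).

**Reg-MaxS** registers a test morphology to a reference volume by estimating
translation, rotation and per-axis scale differences with exhaustive grid
searches refined over a descending ladder of voxel sizes (default
160…10 μm, clipped to the morphology's size), alternating
translation/rotation passes with single scaling steps until no transform
strictly reduces the dissimilarity at the smallest voxel size. Reflections
are not handled. **Reg-MaxS-N** co-registers a group by iterative averaging:
each iteration registers every member to the current reference volume, takes
the union of the registered voxel sets as the next reference, accepts each
pairwise result only if its dissimilarity profile improves lexicographically
from the coarsest voxel size down, and restricts each member's cumulative
scaling to [0.5, 2]. The iteration with minimal occupancy-based group
dissimilarity is the solution, mapped back into the initial reference's
frame.

Also included: anisotropy of a scaling triple (MAS = 1 − mean of sorted
pairwise scale ratios), synthetic test-data generation with known ground
truth, corresponding-point distance statistics with the exact sign test, a
PCA registration baseline, and dendritic density profiles with maximal
projections.

## Worked example

`examples/pairwise_registration.py` generates a 300-node quasi-planar
synthetic arbor, transforms a copy by a random affine transform from the
standard test ranges (translation U[−20, 20] μm, rotation U[−30, 30]°,
per-axis scale U[0.5, 2]), registers the copy back, and prints:

```
planted transform: angles [-7.2 28.7  5.4] deg, scales [1.41 1.46 1.51] , translation [ -7.1 -14.   12.7] um

trace (9 states, D at voxel sizes (40.0, 20.0, 10.0) um):
   0 initial      [0.702, 0.800, 0.901]
   ...
   6 scale        [0.447, 0.452, 0.741]
   7 translation  [0.471, 0.395, 0.580]
   8 rotation     [0.238, 0.133, 0.186] <- solution

residual distances: median 1.17 um over 300 corresponding points
sign test vs the smallest voxel size (10.0 um): p = 4.91e-91, significant at 1%: True
```

The trace shows the dissimilarity at each voxel size after every applied
transform; the solution is the state with minimal finest-level
dissimilarity. A median corresponding-point distance of ~1 μm against a
smallest voxel size of 10 μm means the planted transform was removed. The
other example scripts demonstrate the dissimilarity measures, group
registration and density profiles the same way.

A thin CLI wraps the same pipelines:

```sh
regmaxs simulate --seed 1 --n-nodes 300 --n-transforms 5 --noise-stds 0,5 --out-dir suite/
regmaxs register-pair --test suite/case000_transformed.swc --ref suite/base.swc --out reg.swc
regmaxs register-group --swc-dir group/ --ref-index 0 --out-dir registered/
regmaxs evaluate --ref suite/base.swc --test-dir registered/ --mode nearest --threshold 10 --out metrics.csv
regmaxs density --swc-dir registered/ --kernel-std 1.25 --out density.npy
```

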