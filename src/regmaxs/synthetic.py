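"""Synthetic tree morphologies and randomized registration test suites.

The generator grows seeded stochastic branching walks that stand in for real
dendritic arbors: connected trees with persistent-direction segments, random
branching and a bounded spatial extent. Test suites perturb a base tree with
per-node Gaussian positional noise and random affine transforms drawn from
the standard test ranges (translation uniform on [-20, 20] um per axis,
rotation uniform on [-30, 30] degrees per axis, per-axis scale uniform on
[0.5, 2.0]), keeping node ids fixed so that ground-truth point
correspondences are known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import Morphology, apply_transform, centroid
from .transforms import AffineTransform, TransformRanges, mas, random_transform

__all__ = [
    "TreeGenParams",
    "TestCase",
    "generate_tree",
    "add_noise",
    "make_suite",
]


@dataclass(frozen=True)
class TreeGenParams:
    """Parameters of the stochastic tree growth.

    ``spatial_extent`` is the full width of the allowed box per axis (um),
    centered at the origin. ``branch_probability`` is the per-step chance of
    opening a new branch at a random existing node. Steps have Gaussian
    length (mean/std in um) and a persistent direction with Gaussian jitter.
    The defaults grow a dense, nearly planar arbor (300 x 300 x 40 um),
    emulating the flattened tangential-cell dendrites that voxel-overlap
    registration is designed for; sparse isotropic trees make the overlap
    objective uninformative at fine voxel sizes.
    """

    n_nodes: int = 300
    spatial_extent: tuple[float, float, float] = (300.0, 300.0, 40.0)
    branch_probability: float = 0.15
    step_length_mean: float = 10.0
    step_length_std: float = 2.0
    direction_jitter: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if any(e <= 0 for e in self.spatial_extent):
            raise ValueError("spatial_extent must be positive")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")
        if self.step_length_mean <= 0 or self.step_length_std < 0:
            raise ValueError("invalid step length parameters")


@dataclass(frozen=True)
class TestCase:
    """One randomized registration test.

    ``transformed`` is ``true_transform`` applied to ``noisy`` (which equals
    ``base`` for noiseless cases); node ids are identical across the three
    morphologies, so correspondences are known by id.
    """

    base: Morphology
    noisy: Morphology
    transformed: Morphology
    true_transform: AffineTransform
    noise_std: float

    @property
    def mas(self) -> float:
        """Anisotropy of the planted scaling."""
        return mas(self.true_transform.scales)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def generate_tree(params: TreeGenParams) -> Morphology:
    """Grow a connected tree with exactly ``params.n_nodes`` nodes.

    Deterministic for a fixed seed. The root sits at the origin; all
    coordinates stay within half the spatial extent of the origin per axis
    (walkers reflect off the box walls).
    """
    rng = np.random.default_rng(params.seed)
    half = np.asarray(params.spatial_extent, dtype=float) / 2.0
    xyz = [np.zeros(3)]
    parents = [-1]
    tips = [[0, _unit(rng.normal(size=3))]]
    while len(xyz) < params.n_nodes:
        tip = tips[rng.integers(len(tips))]
        node, direction = tip
        step = max(rng.normal(params.step_length_mean, params.step_length_std),
                   0.25 * params.step_length_mean)
        direction = _unit(direction +
                          params.direction_jitter * rng.normal(size=3))
        p = xyz[node] + step * direction
        for ax in range(3):  # reflect at the box walls
            if abs(p[ax]) > half[ax]:
                p[ax] = np.clip(p[ax], -half[ax], half[ax])
                direction[ax] *= -1.0
        xyz.append(p)
        parents.append(node)
        tip[0], tip[1] = len(xyz) - 1, direction
        if (rng.random() < params.branch_probability
                and len(xyz) < params.n_nodes):
            tips.append([int(rng.integers(len(xyz))),
                         _unit(rng.normal(size=3))])
    n = len(xyz)
    ids = np.arange(1, n + 1)
    types = np.full(n, 3)
    types[0] = 1
    parent_ids = np.array([ids[p] if p >= 0 else -1 for p in parents])
    return Morphology(ids, types, np.asarray(xyz), np.ones(n), parent_ids)


def add_noise(m: Morphology, std: float,
              rng: np.random.Generator) -> Morphology:
    """Independent zero-mean Gaussian perturbation of every coordinate.

    Topology, ids and radii are unchanged; ``std`` in um, 0 allowed.
    """
    if std < 0:
        raise ValueError("noise std must be non-negative")
    out = m.copy()
    if std > 0:
        out.xyz = out.xyz + rng.normal(0.0, std, size=out.xyz.shape)
    return out


def make_suite(base: Morphology, n_transforms: int,
               noise_stds, rng: np.random.Generator,
               ranges: TransformRanges | None = None,
               max_mas: float | None = None) -> list[TestCase]:
    """Build randomized test cases: one per (transform, noise std) pair.

    Each of the ``n_transforms`` random transforms is applied to the noisy
    version of ``base`` for every noise std (std 0 reproduces the noiseless
    protocol). Transforms pivot at the noisy morphology's centroid so the
    transformed copy stays within the search ranges. With ``max_mas`` set,
    transforms are redrawn until their scaling anisotropy is below the cut,
    stratifying the suite by MAS.
    """
    if n_transforms < 1:
        raise ValueError("n_transforms must be >= 1")
    ranges = ranges or TransformRanges()
    draws = []
    for _ in range(n_transforms):
        t = random_transform(rng, ranges)
        while max_mas is not None and mas(t.scales) >= max_mas:
            t = random_transform(rng, ranges)
        draws.append(t)
    cases = []
    for t in draws:
        for std in noise_stds:
            noisy = add_noise(base, float(std), rng)
            centered = AffineTransform(rotation_angles=t.rotation_angles,
                                       scales=t.scales,
                                       translation=t.translation,
                                       center=centroid(noisy))
            cases.append(TestCase(base=base, noisy=noisy,
                                  transformed=apply_transform(noisy, centered),
                                  true_transform=centered,
                                  noise_std=float(std)))
    return cases
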