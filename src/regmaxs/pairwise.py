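"""Pairwise registration by maximizing voxel-volume overlap (Reg-MaxS).

The algorithm registers a *test* morphology to a *reference* volume by
repeatedly estimating and removing translation, rotation and scaling
differences. Each difference is estimated by exhaustive search over a
discrete parameter grid, refined over a descending sequence of voxel sizes
(multi-resolution matching): the search at the coarsest voxel size scans a
wide grid, and each finer level scans a window of one coarse inter-sample
interval around the previous estimate. The overlap objectives have many
local minima at small voxel sizes, which rules out gradient-based
optimization.

Translation and rotation do not interact, but both interact with scaling, so
the loop structure is: alternate translation/rotation passes until neither
strictly decreases the dissimilarity at the smallest voxel size, then apply
one scaling step, and repeat until a full outer pass changes nothing. The
trace state with the smallest finest-level dissimilarity (earliest on ties)
is returned as the solution, so the result is never worse than the initial
centroid alignment. Reflections are not handled and must be removed
beforehand. The search is fully deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .morphology import Morphology, apply_transform, centroid, resample_points
from .voxels import (VoxelSet, dissimilarity_fraction, keys_to_indices,
                     points_to_keys, voxelize)

__all__ = [
    "SearchSchedule",
    "RegMaxSConfig",
    "RegMaxSResult",
    "TraceEntry",
    "ReferenceVolume",
    "exhaustive_search",
    "multiscale_estimate",
    "reg_maxs",
]


@dataclass(frozen=True)
class SearchSchedule:
    """Voxel-size ladder and grid densities for the multi-scale searches.

    ``voxel_sizes`` must be strictly descending; the default halves from
    160 um down to 10 um. Initial grids at the coarsest level: rotation
    +-``rotation_half_range`` deg per axis in steps of ``rotation_step``;
    translation +-``translation_span_voxels`` * v per axis in steps of
    ``translation_step_voxels`` * v (v = coarsest voxel size); scale
    ``n_scale_samples`` log-spaced samples per axis over the allowed bounds.
    Each refinement level scans estimate +- one previous inter-sample step
    with ``n_refine_samples`` samples per parameter (odd, so the previous
    estimate is always a candidate).
    """

    voxel_sizes: tuple[float, ...] = (160.0, 80.0, 40.0, 20.0, 10.0)
    rotation_half_range: float = 30.0
    rotation_step: float = 10.0
    translation_span_voxels: float = 2.0
    translation_step_voxels: float = 0.5
    n_scale_samples: int = 7
    n_refine_samples: int = 5

    def __post_init__(self):
        vs = tuple(float(v) for v in self.voxel_sizes)
        object.__setattr__(self, "voxel_sizes", vs)
        if len(vs) < 1 or any(v <= 0 for v in vs):
            raise ValueError("need at least one positive voxel size")
        if any(a <= b for a, b in zip(vs, vs[1:])):
            raise ValueError("voxel sizes must be strictly descending")
        if self.n_refine_samples < 3 or self.n_refine_samples % 2 == 0:
            raise ValueError("n_refine_samples must be odd and >= 3")
        if self.n_scale_samples < 3 or self.n_scale_samples % 2 == 0:
            raise ValueError("n_scale_samples must be odd and >= 3")

    @property
    def smallest(self) -> float:
        return self.voxel_sizes[-1]

    def clipped(self, max_voxel: float) -> "SearchSchedule":
        """Drop levels coarser than ``max_voxel``, keeping at least one."""
        keep = tuple(v for v in self.voxel_sizes if v <= max_voxel)
        if not keep:
            keep = (self.voxel_sizes[-1],)
        return replace(self, voxel_sizes=keep)


@dataclass
class RegMaxSConfig:
    """Tunables of a single pairwise registration.

    ``scale_bounds`` is one (lo, hi) interval applied per axis, or a 3-tuple
    of per-axis intervals; it bounds the *total* scaling applied over the
    whole call. ``align_centroids`` controls the initial centroid match
    (disabled inside group iterations after the first).
    """

    scale_bounds: tuple = (0.5, 2.0)
    max_outer: int = 30
    align_centroids: bool = True

    def per_axis_bounds(self) -> tuple[tuple[float, float], ...]:
        b = self.scale_bounds
        if len(b) == 2 and np.isscalar(b[0]):
            b = (tuple(b),) * 3
        b = tuple((float(lo), float(hi)) for lo, hi in b)
        for lo, hi in b:
            if not 0 < lo <= hi:
                raise ValueError(f"invalid scale bounds ({lo}, {hi})")
        return b


class ReferenceVolume:
    """Voxel-set provider over voxel sizes for one or more morphologies.

    The volume at a given voxel size is the union of the members'
    voxelizations (for a single member, simply its voxel set). Caches per
    voxel size, since the reference is fixed during a registration.
    """

    def __init__(self, members):
        if isinstance(members, Morphology):
            members = [members]
        self.members: list[Morphology] = list(members)
        if not self.members:
            raise ValueError("reference volume needs at least one morphology")
        self._keys: dict[float, np.ndarray] = {}
        self._vox_centroid: dict[float, np.ndarray] = {}

    def keys(self, voxel_size: float) -> np.ndarray:
        if voxel_size not in self._keys:
            parts = [voxelize(m, voxel_size).keys for m in self.members]
            self._keys[voxel_size] = parts[0] if len(parts) == 1 \
                else np.unique(np.concatenate(parts))
        return self._keys[voxel_size]

    def voxel_set(self, voxel_size: float) -> VoxelSet:
        return VoxelSet(voxel_size, self.keys(voxel_size))

    def voxel_centroid(self, voxel_size: float) -> np.ndarray:
        if voxel_size not in self._vox_centroid:
            idx = keys_to_indices(self.keys(voxel_size))
            self._vox_centroid[voxel_size] = idx.mean(axis=0) * voxel_size
        return self._vox_centroid[voxel_size]

    def node_centroid(self) -> np.ndarray:
        return np.vstack([m.xyz for m in self.members]).mean(axis=0)


def exhaustive_search(candidates: Sequence, objective: Callable,
                      norm: Callable | None = None):
    """Scan all candidates; return ``(best_candidate, best_value)``.

    Ties on the objective are broken by the smaller ``norm`` (distance of the
    candidate from the identity, by default zero), then by candidate order,
    so the search is deterministic.
    """
    best_cand = None
    best_key = None
    best_val = None
    n_seen = 0
    for cand in candidates:
        n_seen += 1
        val = objective(cand)
        key = (val, norm(cand) if norm is not None else 0.0)
        if best_key is None or key < best_key:
            best_key, best_cand, best_val = key, cand, val
    if n_seen == 0:
        raise ValueError("no candidates to search")
    return best_cand, best_val


def _rotation_matrix(angles_deg) -> np.ndarray:
    return Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()


def _step_matrix(kind: str, params, center) -> np.ndarray:
    """4x4 matrix of one estimated step, pivoted at ``center``."""
    M = np.eye(4)
    if kind == "translation":
        M[:3, 3] = params
    elif kind == "rotation":
        R = _rotation_matrix(params)
        M[:3, :3] = R
        M[:3, 3] = center - R @ center
    elif kind == "scale":
        S = np.diag(np.asarray(params, dtype=float))
        M[:3, :3] = S
        M[:3, 3] = center - S @ center
    else:  # pragma: no cover
        raise ValueError(f"unknown step kind {kind!r}")
    return M


def _restrict_axis(cum: float, global_bounds: tuple[float, float],
                   default_bounds: tuple[float, float]) -> tuple[float, float]:
    """Allowed further scaling on one axis given the cumulative scale."""
    gmin, gmax = global_bounds
    if cum < gmin or cum > gmax:
        return (1.0, 1.0)
    lo = max(gmin / cum, default_bounds[0])
    hi = min(gmax / cum, default_bounds[1])
    # the identity must always remain admissible
    return (min(lo, 1.0), max(hi, 1.0))


def _candidate_grid(axes: list[np.ndarray]) -> list[tuple]:
    axes = [np.unique(a) for a in axes]
    return list(itertools.product(*(a.tolist() for a in axes)))


def _multiscale(kind: str, xyz: np.ndarray, child: np.ndarray,
                parent: np.ndarray, center: np.ndarray,
                reference: ReferenceVolume, schedule: SearchSchedule,
                scale_bounds: tuple[tuple[float, float], ...] | None
                ) -> np.ndarray:
    """Run the coarse-to-fine exhaustive searches for one parameter kind."""
    est = np.ones(3) if kind == "scale" else np.zeros(3)
    steps = None  # per-axis inter-sample interval (log units for scale)
    nref = schedule.n_refine_samples
    for level, v in enumerate(schedule.voxel_sizes):
        # spacing v/4 keeps the <= v/2 point-spacing contract valid even for
        # candidates scaled up to the 2.0 bound
        pts = resample_points(xyz, child, parent, v / 4.0)
        ref_keys = reference.keys(v)

        if level == 0:
            if kind == "translation":
                step = schedule.translation_step_voxels * v
                span = schedule.translation_span_voxels * v
                n = int(round(2 * span / step)) + 1
                axes = [np.linspace(-span, span, n)] * 3
                steps = np.full(3, step)
            elif kind == "rotation":
                h, s = schedule.rotation_half_range, schedule.rotation_step
                n = int(round(2 * h / s)) + 1
                axes = [np.linspace(-h, h, n)] * 3
                steps = np.full(3, s)
            else:
                axes, steps = [], np.empty(3)
                for a, (lo, hi) in enumerate(scale_bounds):
                    axes.append(np.geomspace(lo, hi, schedule.n_scale_samples))
                    steps[a] = (np.log(hi) - np.log(lo)) / \
                        (schedule.n_scale_samples - 1)
        else:
            axes = []
            for a in range(3):
                if kind == "scale":
                    lo, hi = scale_bounds[a]
                    window = np.exp(np.linspace(np.log(est[a]) - steps[a],
                                                np.log(est[a]) + steps[a],
                                                nref))
                    axes.append(np.clip(window, lo, hi))
                else:
                    axes.append(np.linspace(est[a] - steps[a],
                                            est[a] + steps[a], nref))
            steps = 2 * steps / (nref - 1)

        if kind == "translation":
            def objective(t, _pts=pts, _ref=ref_keys, _v=v):
                return dissimilarity_fraction(
                    points_to_keys(_pts + np.asarray(t), _v), _ref)

            def norm(t):
                return float(np.linalg.norm(t))
        elif kind == "rotation":
            def objective(a, _pts=pts, _ref=ref_keys, _v=v):
                R = _rotation_matrix(a)
                moved = (_pts - center) @ R.T + center
                return dissimilarity_fraction(points_to_keys(moved, _v), _ref)

            def norm(a):
                return float(np.linalg.norm(a))
        else:
            ref_cent = reference.voxel_centroid(v)

            def objective(s, _pts=pts, _ref=ref_keys, _v=v, _rc=ref_cent):
                moved = (_pts - center) * np.asarray(s) + center
                test_keys = points_to_keys(moved, _v)
                shift = _rc - keys_to_indices(test_keys).mean(axis=0) * _v
                return dissimilarity_fraction(
                    points_to_keys(moved + shift, _v), _ref)

            def norm(s):
                return float(np.linalg.norm(np.log(s)))

        best, _ = exhaustive_search(_candidate_grid(axes), objective, norm)
        est = np.asarray(best, dtype=float)
    return est


def multiscale_estimate(kind: str, test: Morphology, reference,
                        schedule: SearchSchedule | None = None,
                        scale_bounds=((0.5, 2.0),) * 3) -> np.ndarray:
    """Estimate one transform difference between ``test`` and ``reference``.

    ``kind`` is ``"translation"``, ``"rotation"`` or ``"scale"``. Translation
    and rotation are scored with the non-centric dissimilarity, scale with
    the centric one. Rotation and scaling pivot at the test's node centroid.
    """
    if kind not in ("translation", "rotation", "scale"):
        raise ValueError(f"unknown kind {kind!r}")
    schedule = schedule or SearchSchedule()
    if not isinstance(reference, ReferenceVolume):
        reference = ReferenceVolume(reference)
    child, parent = test.edges()
    bounds = tuple((float(lo), float(hi)) for lo, hi in scale_bounds) \
        if kind == "scale" else None
    return _multiscale(kind, test.xyz, child, parent, centroid(test),
                       reference, schedule, bounds)


@dataclass(frozen=True)
class TraceEntry:
    """One recorded state of the registration loop."""

    kind: str                       # "initial", "centroid", "translation", ...
    params: tuple | None            # the applied step's parameters
    dissimilarities: tuple          # Fractions, ordered largest->smallest voxel
    matrix: np.ndarray              # cumulative 4x4 up to and incl. this step
    cumulative_scales: np.ndarray   # per-axis total scaling so far

    @property
    def dissimilarity_floats(self) -> tuple[float, ...]:
        return tuple(float(d) for d in self.dissimilarities)


@dataclass
class RegMaxSResult:
    """Outcome of one pairwise registration."""

    total_transform: np.ndarray
    trace: list[TraceEntry]
    solution_index: int
    registered: Morphology
    voxel_sizes: tuple[float, ...]
    cumulative_scales: np.ndarray

    @property
    def dissimilarity(self) -> float:
        """Finest-level dissimilarity of the chosen solution."""
        return float(self.trace[self.solution_index].dissimilarities[-1])


def reg_maxs(test: Morphology, reference,
             schedule: SearchSchedule | None = None,
             config: RegMaxSConfig | None = None) -> RegMaxSResult:
    """Register ``test`` to ``reference`` (a morphology, a sequence of
    morphologies, or a :class:`ReferenceVolume`).

    Returns the trace state with minimal dissimilarity at the smallest voxel
    size (earliest on ties); its cumulative transform, applied to the input
    test morphology, yields ``registered``.
    """
    if len(test) == 0:
        raise ValueError("empty test morphology")
    if not isinstance(reference, ReferenceVolume):
        reference = ReferenceVolume(reference)
    config = config or RegMaxSConfig()
    bounds = config.per_axis_bounds()
    schedule = schedule or SearchSchedule()
    # drop coarse levels on which the morphologies span only a couple of
    # voxels: there the overlap objective cannot discriminate rotations, the
    # coarse estimate pins to zero and the refinement windows then exclude
    # the true parameters
    diags = []
    for m in [test] + reference.members:
        lo, hi = m.bounding_box()
        diags.append(float(np.linalg.norm(hi - lo)))
    schedule = schedule.clipped(max(diags) / 8.0)

    child, parent = test.edges()
    cur = test.copy()
    M_total = np.eye(4)
    cum_scale = np.ones(3)
    trace: list[TraceEntry] = []

    def record(kind: str, params):
        fracs = tuple(
            dissimilarity_fraction(voxelize(cur, v).keys, reference.keys(v))
            for v in schedule.voxel_sizes)
        trace.append(TraceEntry(kind, params, fracs, M_total.copy(),
                                cum_scale.copy()))

    def finest() -> Fraction:
        return trace[-1].dissimilarities[-1]

    record("initial", None)
    if config.align_centroids:
        t = reference.node_centroid() - centroid(cur)
        M = _step_matrix("translation", t, np.zeros(3))
        cur.xyz = cur.xyz + t
        M_total = M @ M_total
        record("centroid", tuple(t))

    def try_apply(kind: str, params, center) -> bool:
        nonlocal cur, M_total, cum_scale
        M = _step_matrix(kind, params, center)
        moved = cur.copy()
        moved.xyz = cur.xyz @ M[:3, :3].T + M[:3, 3]
        new_D = dissimilarity_fraction(
            voxelize(moved, schedule.smallest).keys,
            reference.keys(schedule.smallest))
        if new_D < finest():
            cur = moved
            M_total = M @ M_total
            if kind == "scale":
                cum_scale = cum_scale * np.asarray(params)
            record(kind, tuple(params))
            return True
        return False

    for _ in range(config.max_outer):
        applied_any = False
        while True:  # translation/rotation passes
            applied_inner = False
            for kind in ("translation", "rotation"):
                c = centroid(cur)
                params = _multiscale(kind, cur.xyz, child, parent, c,
                                     reference, schedule, None)
                if try_apply(kind, params, c):
                    applied_inner = applied_any = True
            if not applied_inner:
                break
        # one scaling step, bounded so the call's total scaling stays in range
        step_bounds = tuple(
            _restrict_axis(cum_scale[a], bounds[a], bounds[a])
            for a in range(3))
        c = centroid(cur)
        params = _multiscale("scale", cur.xyz, child, parent, c,
                             reference, schedule, step_bounds)
        if try_apply("scale", params, c):
            applied_any = True
        if not applied_any:
            break

    finals = [e.dissimilarities[-1] for e in trace]
    solution = finals.index(min(finals))  # exact Fractions; earliest on ties
    entry = trace[solution]
    registered = apply_transform(test, entry.matrix)
    return RegMaxSResult(total_transform=entry.matrix, trace=trace,
                         solution_index=solution, registered=registered,
                         voxel_sizes=schedule.voxel_sizes,
                         cumulative_scales=entry.cumulative_scales)
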