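"""Group co-registration by iterative averaging (Reg-MaxS-N).

A group of morphologies is co-registered without a pre-existing atlas. Each
iteration registers every member to the current reference volume with the
pairwise algorithm; the union of the registered members' voxel sets (a
conservative "average volume" that keeps every member fully represented)
becomes the reference of the next iteration. The reference of the first
iteration is the volume of one designated member, after an initial
approximate registration that matches all centroids to it.

Three safeguards come with the iteration:

* **Acceptance.** A pairwise registration to an average is accepted only if
  the dissimilarity profile improves lexicographically from the *largest*
  voxel size down — sacrificing coarse overlap for fine overlap against a
  union volume would randomly match non-corresponding parts. Rejected
  members stay unchanged for that iteration.
* **Scaling restriction.** The total per-axis scaling applied to a member
  across all iterations is confined to global bounds; the interval offered
  to each pairwise call shrinks as scaling accumulates, so members cannot
  grow without limit to inflate overlap.
* **Normalization.** The iteration whose occupancy-based group dissimilarity
  is minimal (including the initial centroid-aligned state) is the solution;
  all its morphologies are finally mapped by the inverse of the initial
  reference's accumulated transform, returning the initial reference to its
  input coordinates.

The iteration stops when every pairwise registration of an iteration is
rejected, or after ``max_iters``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import Morphology, apply_transform, centroid
from .pairwise import (RegMaxSConfig, ReferenceVolume, SearchSchedule,
                       _restrict_axis, _step_matrix, reg_maxs)
from .transforms import invert
from .voxels import (VoxelSet, group_dissimilarity, occupancy_histogram,
                     voxelize)

__all__ = [
    "GroupConfig",
    "GroupRegistrationResult",
    "average_volume",
    "accept_registration",
    "restrict_scaling",
    "normalize_finals",
    "reg_maxs_n",
]


@dataclass
class GroupConfig:
    """Tunables of a group registration run."""

    global_scale_bounds: tuple[float, float] = (0.5, 2.0)
    max_iters: int = 20
    pairwise: RegMaxSConfig = field(default_factory=RegMaxSConfig)


def average_volume(members, voxel_size: float) -> VoxelSet:
    """Union of the members' voxel sets at the given voxel size."""
    members = list(members)
    if not members:
        raise ValueError("empty group")
    out = voxelize(members[0], voxel_size)
    for m in members[1:]:
        out = out.union(voxelize(m, voxel_size))
    return out


def accept_registration(before, after) -> bool:
    """Lexicographic acceptance of a pairwise registration to an average.

    ``before`` and ``after`` are dissimilarity vectors ordered from the
    largest to the smallest voxel size. Accept iff the first differing entry
    decreased; reject if all entries are equal.
    """
    before, after = list(before), list(after)
    if len(before) != len(after) or not before:
        raise ValueError("dissimilarity vectors must have equal length >= 1")
    for b, a in zip(before, after):
        if a < b:
            return True
        if a > b:
            return False
    return False


def restrict_scaling(cumulative_scales, global_bounds=(0.5, 2.0),
                     default_bounds=None) -> tuple[tuple[float, float], ...]:
    """Per-axis scale interval still admissible given accumulated scaling.

    The interval on each axis is ``[global_min/cum, global_max/cum]``
    intersected with ``default_bounds`` (the per-call search bounds,
    defaulting to the global bounds) and always contains 1.0. If the
    cumulative scale has left the global bounds, the interval clamps to
    ``(1.0, 1.0)`` — no further scaling in any direction on that axis.
    """
    cum = np.asarray(cumulative_scales, dtype=float)
    if cum.shape != (3,) or np.any(cum <= 0):
        raise ValueError("cumulative_scales must be three positive factors")
    default_bounds = default_bounds or tuple(global_bounds)
    return tuple(_restrict_axis(float(c), tuple(global_bounds),
                                tuple(default_bounds)) for c in cum)


def normalize_finals(morphologies, reference_total) -> list[Morphology]:
    """Map all morphologies by the inverse of the reference's total transform."""
    inv = invert(reference_total)
    return [apply_transform(m, inv) for m in morphologies]


@dataclass
class GroupRegistrationResult:
    """Outcome of a group registration run.

    ``group_dissimilarities[i]`` is the occupancy-based dissimilarity (at the
    smallest voxel size) after iteration ``i``; index 0 is the initial
    centroid-aligned state. ``acceptance_flags[i]`` holds the per-member
    acceptance of iteration ``i`` (iterations >= 1).
    """

    group_dissimilarities: list[float]
    acceptance_flags: list[list[bool]]
    total_transforms: list[np.ndarray]
    cumulative_scales: list[np.ndarray]
    solution_iteration: int
    normalization_transform: np.ndarray
    final_morphologies: list[Morphology]


def reg_maxs_n(group, initial_ref_index: int = 0,
               schedule: SearchSchedule | None = None,
               config: GroupConfig | None = None) -> GroupRegistrationResult:
    """Co-register a group of >= 2 morphologies by iterative averaging."""
    group = list(group)
    if len(group) < 2:
        raise ValueError("group registration needs at least two morphologies")
    if not 0 <= initial_ref_index < len(group):
        raise ValueError("initial_ref_index out of range")
    schedule = schedule or SearchSchedule()
    config = config or GroupConfig()
    n = len(group)
    smallest = schedule.voxel_sizes[-1]

    # iteration 0: centroid-align everything to the initial reference
    ref_c = centroid(group[initial_ref_index])
    current: list[Morphology] = []
    totals: list[np.ndarray] = []
    cum_scales = [np.ones(3) for _ in range(n)]
    for m in group:
        t = ref_c - centroid(m)
        M = _step_matrix("translation", t, np.zeros(3))
        current.append(apply_transform(m, M))
        totals.append(M)

    def group_D(members) -> float:
        sets = [voxelize(m, smallest) for m in members]
        return group_dissimilarity(occupancy_histogram(sets))

    history_D = [group_D(current)]
    history_totals = [[M.copy() for M in totals]]
    history_scales = [[s.copy() for s in cum_scales]]
    flags_history: list[list[bool]] = []

    reference = ReferenceVolume(current[initial_ref_index])
    pw = config.pairwise
    for _ in range(config.max_iters):
        flags: list[bool] = []
        registered: list[Morphology] = []
        for i in range(n):
            bounds_i = restrict_scaling(cum_scales[i],
                                        config.global_scale_bounds,
                                        pw.per_axis_bounds()[0])
            cfg = RegMaxSConfig(scale_bounds=bounds_i,
                                max_outer=pw.max_outer,
                                align_centroids=False)
            res = reg_maxs(current[i], reference, schedule, cfg)
            before = res.trace[0].dissimilarities
            after = res.trace[res.solution_index].dissimilarities
            ok = accept_registration(before, after)
            flags.append(ok)
            if ok:
                registered.append(res.registered)
                totals[i] = res.total_transform @ totals[i]
                cum_scales[i] = cum_scales[i] * res.cumulative_scales
            else:
                registered.append(current[i])
        current = registered
        flags_history.append(flags)
        history_D.append(group_D(current))
        history_totals.append([M.copy() for M in totals])
        history_scales.append([s.copy() for s in cum_scales])
        if not any(flags):
            break
        reference = ReferenceVolume(current)

    solution = int(np.argmin(history_D))
    sol_totals = history_totals[solution]
    norm_M = invert(sol_totals[initial_ref_index])
    finals = [apply_transform(group[i], norm_M @ sol_totals[i])
              for i in range(n)]
    return GroupRegistrationResult(
        group_dissimilarities=history_D,
        acceptance_flags=flags_history,
        total_transforms=sol_totals,
        cumulative_scales=history_scales[solution],
        solution_iteration=solution,
        normalization_transform=norm_M,
        final_morphologies=finals,
    )
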