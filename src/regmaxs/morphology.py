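"""SWC neuron morphologies: reading, writing, resampling, transforming.

A morphology is a forest of nodes, each with an integer id, a structure type,
a 3-D position in micrometres, a radius and a parent id (-1 for roots). The
registration algorithms treat a morphology as the point cloud of its nodes
(optionally densified along edges); radii never enter the volume model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import AffineTransform, _as_matrix

__all__ = [
    "Morphology",
    "SWCParseError",
    "read_swc",
    "write_swc",
    "centroid",
    "resample",
    "apply_transform",
]


class SWCParseError(ValueError):
    """Raised for malformed SWC content; the message names the line."""


@dataclass
class Morphology:
    """Node table of an SWC morphology.

    Parallel arrays over nodes: ``ids`` (unique integers), ``types``
    (structure type, passed through untouched), ``xyz`` (N x 3, um),
    ``radii`` (um, >= 0), ``parents`` (id of parent, -1 for roots).
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    parents: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        if self.validate:
            self._check()

    def _check(self):
        n = len(self.ids)
        if n == 0:
            raise ValueError("a morphology must contain at least one node")
        if not (len(self.types) == len(self.radii) == len(self.parents) == n
                and self.xyz.shape == (n, 3)):
            raise ValueError("node arrays have inconsistent lengths")
        if len(np.unique(self.ids)) != n:
            raise ValueError("node ids must be unique")
        if not np.all(np.isfinite(self.xyz)) or not np.all(np.isfinite(self.radii)):
            raise ValueError("coordinates and radii must be finite")
        if np.any(self.radii < 0):
            raise ValueError("radii must be non-negative")
        id_index = {int(i): k for k, i in enumerate(self.ids)}
        for k, p in enumerate(self.parents):
            if p == -1:
                continue
            if int(p) not in id_index:
                raise ValueError(
                    f"node {int(self.ids[k])} has dangling parent {int(p)}")
        # acyclicity: chase parent chains with memoized roots
        state = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 in-progress, 2 done
        for start in range(n):
            k, chain = start, []
            while k != -1 and state[k] == 0:
                state[k] = 1
                chain.append(k)
                p = int(self.parents[k])
                k = id_index[p] if p != -1 else -1
            if k != -1 and state[k] == 1:
                raise ValueError("parent links form a cycle")
            for c in chain:
                state[c] = 2

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(child_index, parent_index) positional arrays over non-root nodes."""
        id_index = {int(i): k for k, i in enumerate(self.ids)}
        child = np.flatnonzero(self.parents != -1)
        parent = np.array([id_index[int(p)] for p in self.parents[child]],
                          dtype=np.int64)
        return child, parent

    def cable_length(self) -> float:
        child, parent = self.edges()
        if len(child) == 0:
            return 0.0
        return float(np.linalg.norm(self.xyz[child] - self.xyz[parent],
                                    axis=1).sum())

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.xyz.min(axis=0), self.xyz.max(axis=0)

    def copy(self) -> "Morphology":
        return Morphology(self.ids.copy(), self.types.copy(), self.xyz.copy(),
                          self.radii.copy(), self.parents.copy(),
                          validate=False)


def read_swc(path) -> Morphology:
    """Read an SWC file.

    Accepts any whitespace separation, blank lines and ``#`` comments;
    multiple roots (a forest) are allowed. Raises :class:`SWCParseError`
    naming the offending line on malformed rows, duplicate ids or dangling
    parents.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                ids.append(int(cols[0]))
                types.append(int(cols[1]))
                xyz.append([float(c) for c in cols[2:5]])
                radii.append(float(cols[5]))
                parents.append(int(cols[6]))
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from exc
    if not ids:
        raise SWCParseError(f"{path}: no data lines")
    try:
        return Morphology(ids, types, xyz, radii, parents)
    except ValueError as exc:
        raise SWCParseError(f"{path}: {exc}") from exc


def write_swc(morphology: Morphology, path) -> None:
    """Write a morphology as 7-column SWC with full float precision."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(len(morphology)):
            x, y, z = morphology.xyz[i]
            fh.write(f"{int(morphology.ids[i])} {int(morphology.types[i])} "
                     f"{x:.9g} {y:.9g} {z:.9g} "
                     f"{morphology.radii[i]:.9g} "
                     f"{int(morphology.parents[i])}\n")


def centroid(morphology: Morphology) -> np.ndarray:
    """Unweighted arithmetic mean of the node coordinates (um)."""
    return morphology.xyz.mean(axis=0)


def resample(morphology: Morphology, max_spacing: float) -> Morphology:
    """Subdivide edges so every parent-child distance is <= ``max_spacing``.

    Inserted nodes lie on the original segments, evenly spaced, with linearly
    interpolated radii and the child's structure type; they receive fresh ids
    appended after the existing maximum so original ids keep their meaning.
    Zero-length edges are left untouched.
    """
    if max_spacing <= 0:
        raise ValueError("max_spacing must be positive")
    child, parent = morphology.edges()
    if len(child) == 0:
        return morphology.copy()
    seg = morphology.xyz[child] - morphology.xyz[parent]
    length = np.linalg.norm(seg, axis=1)
    n_sub = np.maximum(np.ceil(length / max_spacing - 1e-12).astype(int), 1)

    ids = list(morphology.ids)
    types = list(morphology.types)
    xyz = list(morphology.xyz)
    radii = list(morphology.radii)
    parents = list(morphology.parents)
    next_id = int(morphology.ids.max()) + 1

    for e in np.flatnonzero(n_sub > 1):
        c, p, k = child[e], parent[e], int(n_sub[e])
        fracs = np.arange(1, k) / k
        prev_id = int(morphology.ids[p])
        for f in fracs:
            xyz.append(morphology.xyz[p] + f * seg[e])
            radii.append((1 - f) * morphology.radii[p] + f * morphology.radii[c])
            types.append(morphology.types[c])
            ids.append(next_id)
            parents.append(prev_id)
            prev_id = next_id
            next_id += 1
        parents[c] = prev_id  # reparent the original child onto the chain
    return Morphology(ids, types, xyz, radii, parents, validate=False)


def resample_points(xyz: np.ndarray, child: np.ndarray, parent: np.ndarray,
                    max_spacing: float) -> np.ndarray:
    """Point cloud of nodes plus evenly spaced interior edge points.

    Fast path used by voxelization and the registration searches; returns
    only coordinates, no ids or topology.
    """
    if len(child) == 0:
        return xyz
    seg = xyz[child] - xyz[parent]
    length = np.linalg.norm(seg, axis=1)
    n_sub = np.maximum(np.ceil(length / max_spacing - 1e-12).astype(int), 1)
    extra = []
    for e in np.flatnonzero(n_sub > 1):
        fracs = np.arange(1, n_sub[e]) / n_sub[e]
        extra.append(xyz[parent[e]] + fracs[:, None] * seg[e])
    if not extra:
        return xyz
    return np.vstack([xyz] + extra)


def apply_transform(morphology: Morphology, transform) -> Morphology:
    """Map node coordinates through an :class:`AffineTransform` or 4x4 matrix.

    Ids, topology and structure types are preserved. Radii are multiplied by
    the cube root of the linear part's determinant (the geometric mean of the
    per-axis scale factors), a cosmetic convention: radii play no role in
    registration.
    """
    M = _as_matrix(transform)
    out = morphology.copy()
    out.xyz = morphology.xyz @ M[:3, :3].T + M[:3, 3]
    out.radii = morphology.radii * abs(np.linalg.det(M[:3, :3])) ** (1.0 / 3.0)
    return out
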