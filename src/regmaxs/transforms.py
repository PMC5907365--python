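"""Affine transforms for morphology registration.

A transform is parameterized by per-axis rotation angles (degrees), strictly
positive per-axis scale factors, a translation and a fixed center, applied as

    x' = R @ (S @ (x - center)) + center + translation

with ``R = Rz @ Ry @ Rx`` (extrinsic rotations about the world x, then y, then
z axis).  Positive scales mean the linear part always has positive determinant:
reflections cannot be represented, matching the registration algorithms, which
do not handle them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AffineTransform",
    "TransformRanges",
    "compose",
    "invert",
    "apply_matrix",
    "random_transform",
    "mas",
]


def _as_vec3(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class AffineTransform:
    """Rotation / per-axis scale / translation about a fixed center.

    Parameters
    ----------
    rotation_angles : 3-vector, degrees, rotations about x, y, z.
    scales : 3-vector, strictly positive per-axis scale factors.
    translation : 3-vector, micrometres.
    center : 3-vector, micrometres; rotation and scaling pivot.
    """

    rotation_angles: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scales: np.ndarray = field(default_factory=lambda: np.ones(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation_angles",
                           _as_vec3(self.rotation_angles, "rotation_angles"))
        object.__setattr__(self, "scales", _as_vec3(self.scales, "scales"))
        object.__setattr__(self, "translation",
                           _as_vec3(self.translation, "translation"))
        object.__setattr__(self, "center", _as_vec3(self.center, "center"))
        if np.any(self.scales <= 0):
            raise ValueError("scales must be strictly positive (no reflections)")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    def rotation_matrix(self) -> np.ndarray:
        # extrinsic x-y-z: R = Rz @ Ry @ Rx
        return Rotation.from_euler("xyz", self.rotation_angles,
                                   degrees=True).as_matrix()

    def matrix(self) -> np.ndarray:
        """4x4 row-major homogeneous matrix implementing the stated order."""
        R = self.rotation_matrix()
        A = R @ np.diag(self.scales)
        M = np.eye(4)
        M[:3, :3] = A
        M[:3, 3] = -A @ self.center + self.center + self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of points."""
        return apply_matrix(self.matrix(), points)

    def to_json(self) -> str:
        return json.dumps({
            "angles_deg": self.rotation_angles.tolist(),
            "scales": self.scales.tolist(),
            "translation_um": self.translation.tolist(),
            "center_um": self.center.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform":
        d = json.loads(text)
        return cls(rotation_angles=d["angles_deg"], scales=d["scales"],
                   translation=d["translation_um"], center=d["center_um"])


@dataclass(frozen=True)
class TransformRanges:
    """Per-axis sampling intervals for random test transforms.

    Defaults are the randomized-test protocol: translations uniform on
    [-20, 20] um, rotations uniform on [-30, 30] degrees and scales uniform
    (in linear scale) on [0.5, 2.0] per axis.
    """

    translation_range: tuple[float, float] = (-20.0, 20.0)
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    scale_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self):
        for name in ("translation_range", "rotation_range", "scale_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if self.scale_range[0] <= 0:
            raise ValueError("scale_range must be within (0, inf)")


def _as_matrix(t) -> np.ndarray:
    if isinstance(t, AffineTransform):
        return t.matrix()
    M = np.asarray(t, dtype=float)
    if M.shape != (4, 4):
        raise ValueError(f"expected AffineTransform or 4x4 matrix, got {M.shape}")
    return M


def compose(outer, inner) -> np.ndarray:
    """4x4 matrix of ``inner`` followed by ``outer``."""
    return _as_matrix(outer) @ _as_matrix(inner)


def invert(t) -> np.ndarray:
    """Inverse 4x4 matrix; always exists for positive-scale transforms."""
    M = _as_matrix(t)
    if abs(np.linalg.det(M[:3, :3])) < 1e-300:
        raise np.linalg.LinAlgError("singular transform")
    return np.linalg.inv(M)


def apply_matrix(M, points: np.ndarray) -> np.ndarray:
    """Map an (N, 3) (or (3,)) array of points through a 4x4 matrix."""
    M = _as_matrix(M)
    pts = np.asarray(points, dtype=float)
    return pts @ M[:3, :3].T + M[:3, 3]


def random_transform(rng: np.random.Generator,
                     ranges: TransformRanges | None = None,
                     center=(0.0, 0.0, 0.0)) -> AffineTransform:
    """Draw a transform with each parameter independent and uniform.

    Scales are uniform in linear scale over their interval. Reproducible for a
    fixed generator state.
    """
    if ranges is None:
        ranges = TransformRanges()
    t = rng.uniform(*ranges.translation_range, size=3)
    a = rng.uniform(*ranges.rotation_range, size=3)
    s = rng.uniform(*ranges.scale_range, size=3)
    return AffineTransform(rotation_angles=a, scales=s, translation=t,
                           center=np.asarray(center, dtype=float))


def mas(scales) -> float:
    """Measure of Anisotropic Scaling of three per-axis scale factors.

    With the factors sorted ascending as s1 <= s2 <= s3,

        MAS = 1 - (1/3) * (s1/s2 + s1/s3 + s2/s3)

    MAS is 0 exactly when all three factors are equal and grows toward 1 as
    they diverge. It is invariant to permutation and to a common positive
    multiplier.
    """
    s = np.sort(np.asarray(scales, dtype=float))
    if s.shape != (3,):
        raise ValueError("mas expects exactly three scale factors")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("scale factors must be positive and finite")
    s1, s2, s3 = s
    return float(1.0 - (s1 / s2 + s1 / s3 + s2 / s3) / 3.0)
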