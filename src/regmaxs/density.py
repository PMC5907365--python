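"""Dendritic density profiles from groups of co-registered morphologies.

Each morphology is resampled to a fine point spacing, binarized on a shared
voxel grid (1 where the morphology passes through a voxel, 0 elsewhere),
optionally smoothed with a unity-sum discrete Gaussian kernel, and the
per-morphology volumes are averaged. The resulting values are occupancy
fractions in [0, 1]: with no smoothing, the value of a voxel is exactly the
fraction of morphologies passing through it. The grid follows the
voxel-centered-at-origin convention of the volume representations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .morphology import Morphology, resample_points

__all__ = ["DensityProfile", "density_profile", "max_projection"]


@dataclass
class DensityProfile:
    """Dense 3-D occupancy-fraction volume.

    ``origin`` is the world coordinate (um) of the center of voxel
    ``values[0, 0, 0]``; the grid advances by ``voxel_size`` per index.
    """

    origin: np.ndarray
    voxel_size: float
    values: np.ndarray
    kernel_std: float


def density_profile(morphologies, voxel_size: float = 0.25,
                    resample_spacing: float = 0.1,
                    kernel_std: float = 0.0) -> DensityProfile:
    """Average smoothed binary occupancy volume of a group.

    Parameters
    ----------
    voxel_size : grid edge length in um (0.25 by default).
    resample_spacing : maximum distance between consecutive connected points
        after resampling (0.1 um by default).
    kernel_std : standard deviation of the Gaussian smoothing kernel in um;
        0 disables smoothing. The kernel is truncated at 3 sigma and
        normalized to unit sum, so each morphology's total mass is conserved
        away from the grid boundary; the grid is padded by 3 sigma so no
        mass is lost.
    """
    morphologies = list(morphologies)
    if not morphologies:
        raise ValueError("empty group")
    if voxel_size <= 0 or resample_spacing <= 0 or kernel_std < 0:
        raise ValueError("voxel_size and resample_spacing must be positive, "
                         "kernel_std non-negative")
    index_sets = []
    for m in morphologies:
        child, parent = m.edges()
        pts = resample_points(m.xyz, child, parent, resample_spacing)
        index_sets.append(np.floor(pts / voxel_size + 0.5).astype(np.int64))
    lo = np.min([idx.min(axis=0) for idx in index_sets], axis=0)
    hi = np.max([idx.max(axis=0) for idx in index_sets], axis=0)
    pad = int(np.ceil(3.0 * kernel_std / voxel_size)) if kernel_std > 0 else 0
    lo, hi = lo - pad, hi + pad
    shape = tuple(hi - lo + 1)

    sigma_vox = kernel_std / voxel_size
    acc = np.zeros(shape)
    for idx in index_sets:
        vol = np.zeros(shape)
        off = idx - lo
        vol[off[:, 0], off[:, 1], off[:, 2]] = 1.0
        if kernel_std > 0:
            vol = gaussian_filter(vol, sigma_vox, truncate=3.0,
                                  mode="constant")
        acc += vol
    acc /= len(morphologies)
    return DensityProfile(origin=lo.astype(float) * voxel_size,
                          voxel_size=voxel_size, values=acc,
                          kernel_std=kernel_std)


def max_projection(profile: DensityProfile, axis: int) -> np.ndarray:
    """Maximal projection of the profile along axis 1, 2 or 3 (x, y or z)."""
    if axis not in (1, 2, 3):
        raise ValueError("axis must be 1, 2 or 3")
    return profile.values.max(axis=axis - 1)
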