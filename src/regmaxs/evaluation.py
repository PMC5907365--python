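"""Registration performance measures and the PCA baseline.

Registration quality is quantified from Euclidean distances between
corresponding points of a reference morphology P and a result morphology Q:

    d_i = || p_i - q_{p_i} ||,   i = 1..m

Correspondences come either from shared node ids (synthetic tests, where the
test is a transformed copy of the reference) or from nearest neighbors among
the test points for every reference point (real morphologies without a
ground-truth pairing). Because the registration is finalized at the smallest
voxel size, distances below that voxel size indicate success; significance is
assessed with the exact one-sided sign test on the count of distances below
the threshold, at a 1% level. Distances from a suite of n tests over m
reference points can be regrouped per test (across points) or per reference
point (across tests), yielding two complementary success percentages.

The PCA baseline registers two morphologies by assuming their sorted
principal axes correspond: it matches centroids, rotates the test's
principal frame onto the reference's, and reads per-axis scaling differences
off the standard deviations along corresponding axes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import binom, wilcoxon

from .morphology import Morphology, centroid
from .transforms import AffineTransform

__all__ = [
    "correspondences",
    "correspondence_distances",
    "sign_test",
    "performance_summary",
    "pca_register",
    "pca_registration_matrix",
]


def correspondences(reference: Morphology, test: Morphology,
                    mode: str = "known") -> tuple[np.ndarray, np.ndarray]:
    """Paired point arrays ``(ref_points, test_points)``, one row per
    reference node.

    ``mode="known"`` pairs by node id (requires identical id sets);
    ``mode="nearest"`` pairs each reference node with its Euclidean-nearest
    test node, ties broken toward the lowest test node id.
    """
    if len(reference) == 0 or len(test) == 0:
        raise ValueError("empty morphology")
    if mode == "known":
        order = {int(i): k for k, i in enumerate(test.ids)}
        if set(order) != {int(i) for i in reference.ids}:
            raise ValueError("known-correspondence mode requires matching ids")
        idx = np.array([order[int(i)] for i in reference.ids])
        return reference.xyz.copy(), test.xyz[idx]
    if mode == "nearest":
        # sort test nodes by id so that KDTree ties resolve to the lowest id
        by_id = np.argsort(test.ids, kind="stable")
        pts = test.xyz[by_id]
        dist, idx = cKDTree(pts).query(reference.xyz)
        # cKDTree tie-breaking is unspecified; enforce lowest-id explicitly
        for k in range(len(reference)):
            tied = np.flatnonzero(
                np.abs(np.linalg.norm(pts - reference.xyz[k], axis=1)
                       - dist[k]) <= 1e-12 * max(1.0, dist[k]))
            if len(tied) > 1:
                idx[k] = tied[0]
        return reference.xyz.copy(), pts[idx]
    raise ValueError(f"unknown mode {mode!r}")


def correspondence_distances(reference: Morphology, test: Morphology,
                             mode: str = "known") -> np.ndarray:
    """Euclidean distances d_i of the corresponding point pairs (um)."""
    p, q = correspondences(reference, test, mode)
    return np.linalg.norm(p - q, axis=1)


def sign_test(distances, threshold: float, alpha: float = 0.01,
              method: str = "sign") -> tuple[float, bool]:
    """Exact one-sided sign test that distances fall below ``threshold``.

    With k = #{d < threshold} out of n (ties at the threshold count as
    failures, a conservative choice), the p-value is
    P(Binomial(n, 1/2) >= k). ``method="wilcoxon"`` instead runs the
    one-sided Wilcoxon signed-rank test of ``d - threshold < 0`` for
    sensitivity analysis. Returns ``(p_value, p_value < alpha)``.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance set")
    if method == "sign":
        k = int(np.sum(d < threshold))
        p = float(binom.sf(k - 1, d.size, 0.5))
    elif method == "wilcoxon":
        shifted = d - threshold
        if np.all(shifted == 0):
            p = 1.0
        else:
            p = float(wilcoxon(shifted[shifted != 0],
                               alternative="less").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, p < alpha


def performance_summary(suite_distances, threshold: float,
                        alpha: float = 0.01) -> tuple[float, float]:
    """Success percentages of a distance table of shape (n_tests, m_points).

    Row ``j`` holds the distances of test j across all reference points.
    Returns ``(percent of tests significant, percent of points
    significant)``: the sign test applied along each row (per test, across
    points) and along each column (per reference point, across tests).
    """
    table = np.asarray(suite_distances, dtype=float)
    if table.ndim != 2 or table.size == 0:
        raise ValueError("expected a non-empty 2-D distance table")
    tests_ok = [sign_test(row, threshold, alpha)[1] for row in table]
    points_ok = [sign_test(col, threshold, alpha)[1] for col in table.T]
    return (100.0 * np.mean(tests_ok), 100.0 * np.mean(points_ok))


def _principal_axes(m: Morphology) -> tuple[np.ndarray, np.ndarray]:
    """(eigenvalues desc, eigenvector columns) of the node covariance."""
    x = m.xyz - centroid(m)
    cov = x.T @ x / len(m)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pca_registration_matrix(test: Morphology,
                            reference: Morphology) -> np.ndarray:
    """Exact 4x4 map registering ``test`` onto ``reference`` via PCA.

    Applies, in the test's principal frame, the reciprocal of the per-axis
    scaling differences, then rotates the frame onto the reference's and
    matches centroids.
    """
    t = pca_register(test, reference)
    _, E_r = _principal_axes(reference)
    R = Rotation.from_euler("xyz", t.rotation_angles, degrees=True).as_matrix()
    # rotate the test frame onto the reference's, then undo the scaling
    # differences along the reference principal axes
    A = E_r @ np.diag(1.0 / t.scales) @ E_r.T
    lin = A @ R
    M = np.eye(4)
    M[:3, :3] = lin
    M[:3, 3] = centroid(reference) - lin @ centroid(test)
    return M


def pca_register(test: Morphology, reference: Morphology) -> AffineTransform:
    """Estimate transform differences between two morphologies via PCA.

    Assumes the sorted principal axes of the two morphologies correspond and
    that the morphologies are oriented similarly in space. The returned
    transform holds the rotation taking the test's principal axes onto the
    reference's (axis signs chosen for a proper rotation of maximal trace),
    per-axis scaling differences of the test relative to the reference
    (sigma_test / sigma_reference along corresponding axes) and the
    centroid-matching translation. If either morphology has two nearly equal
    principal variances (consecutive standard-deviation ratios within 1%),
    the axis correspondence is ill-defined: a warning is issued and the axes
    are left unrotated.
    """
    for name, m in (("test", test), ("reference", reference)):
        if len(m) < 4:
            raise ValueError(f"{name} needs at least 4 nodes for PCA")
        if np.linalg.matrix_rank(m.xyz - centroid(m), tol=1e-9) < 2:
            raise ValueError(f"{name} nodes are collinear")
    vals_t, E_t = _principal_axes(test)
    vals_r, E_r = _principal_axes(reference)
    sig_t = np.sqrt(np.maximum(vals_t, 0.0))
    sig_r = np.sqrt(np.maximum(vals_r, 0.0))

    degenerate = False
    for sig in (sig_t, sig_r):
        for a in range(2):
            if sig[a] > 0 and sig[a + 1] / sig[a] > 0.99:
                degenerate = True
    if degenerate:
        warnings.warn("near-degenerate principal variances; axes left "
                      "unrotated", stacklevel=2)
        R = np.eye(3)
    else:
        best_trace, R = -np.inf, np.eye(3)
        for sx in (1.0, -1.0):
            for sy in (1.0, -1.0):
                for sz in (1.0, -1.0):
                    cand = E_r @ np.diag([sx, sy, sz]) @ E_t.T
                    if np.linalg.det(cand) < 0:
                        continue
                    tr = np.trace(cand)
                    if tr > best_trace:
                        best_trace, R = tr, cand
    with np.errstate(divide="ignore", invalid="ignore"):
        scales = np.where(sig_r > 0, sig_t / sig_r, 1.0)
    angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
    return AffineTransform(rotation_angles=angles, scales=scales,
                           translation=centroid(reference) - centroid(test),
                           center=centroid(test))
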