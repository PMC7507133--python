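"""Fast Point Feature Histograms (FPFH): pose-invariant 33-D local descriptors.

For a pair of oriented points, three angular features (alpha, phi, theta) are
measured in a Darboux frame anchored at the point whose normal makes the
smaller angle with the connecting line. Each point's SPFH is the
concatenation of three 11-bin histograms of these features over its radius
neighborhood; the FPFH adds the distance-weighted mean of the neighbors'
SPFHs. Matching uses plain nearest neighbors in 33-D Euclidean space, so no
per-histogram normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ContractError
from .surface import ColoredPointCloud

N_BINS = 11
DIM = 3 * N_BINS
#: Descriptor support radius as a multiple of the voxel size.
RADIUS_FACTOR = 5.0
#: Cap on neighbors contributing to one SPFH.
MAX_NEIGHBORS = 100


@dataclass
class FPFHSet:
    """n x 33 non-negative descriptor matrix for a reduced cloud."""

    descriptors: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        if self.descriptors.ndim != 2 or self.descriptors.shape[1] != DIM:
            raise ContractError(f"descriptors must have {DIM} columns")

    def __len__(self) -> int:
        return len(self.descriptors)


def _pair_features_arrays(p_s, n_s, p_t, n_t):
    """Vectorized (alpha, phi, theta) with the smaller-angle frame-origin rule."""
    p_s, n_s = np.atleast_2d(p_s), np.atleast_2d(n_s)
    p_t, n_t = np.atleast_2d(p_t), np.atleast_2d(n_t)
    d = p_t - p_s
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist <= 0):
        raise ContractError("pair features undefined for coincident points")
    dhat = d / dist[:, None]

    # angle(n_s, d) vs angle(n_t, -d): swap roles where the target's normal
    # is better aligned with the connecting line. Regular lattice clouds hit
    # exact ties constantly (equal projections up to sign); break them by the
    # sign of the resulting phi, which is pose invariant, instead of letting
    # rounding noise decide.
    cos_s = np.einsum("ij,ij->i", n_s, dhat)
    cos_t = np.einsum("ij,ij->i", n_t, -dhat)
    abs_s, abs_t = np.abs(cos_s), np.abs(cos_t)
    tie = np.abs(abs_s - abs_t) < 1e-9
    swap = np.where(tie, cos_t > cos_s + 1e-9, abs_s < abs_t)

    u = np.where(swap[:, None], n_t, n_s)
    other = np.where(swap[:, None], n_s, n_t)
    dvec = np.where(swap[:, None], -dhat, dhat)

    v = np.cross(u, dvec)
    vnorm = np.linalg.norm(v, axis=1)
    # u parallel to d: Darboux frame degenerate; use any perpendicular of u.
    bad = vnorm < 1e-12
    if np.any(bad):
        fallback = np.cross(u[bad], np.where(np.abs(u[bad, :1]) < 0.9, [1.0, 0, 0], [0, 1.0, 0]))
        v[bad] = fallback
        vnorm[bad] = np.linalg.norm(fallback, axis=1)
    v = v / vnorm[:, None]
    w = np.cross(u, v)

    alpha = np.einsum("ij,ij->i", v, other)
    phi = np.einsum("ij,ij->i", u, dvec)
    sin_t = np.einsum("ij,ij->i", w, other)
    cos_t = np.einsum("ij,ij->i", u, other)
    theta = np.arctan2(sin_t, cos_t)
    # Degenerate-but-common case: the other normal lies in the (u, d) plane
    # (e.g. two points on one atomic sphere), so sin_t is exactly 0 and the
    # sign of theta = +/-pi would be decided by rounding noise. Pin it to +pi
    # so the feature is pose invariant.
    theta = np.where((np.abs(sin_t) < 1e-9) & (cos_t < 0), np.pi, theta)
    return alpha, phi, theta, dist


def pair_features(p_s, n_s, p_t, n_t) -> tuple[float, float, float]:
    """Angular features (alpha, phi, theta) of one oriented point pair."""
    a, f, t, _ = _pair_features_arrays(p_s, n_s, p_t, n_t)
    return float(a[0]), float(f[0]), float(t[0])


def _bin_index(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    idx = np.floor((values - lo) / (hi - lo) * N_BINS).astype(np.int64)
    return np.clip(idx, 0, N_BINS - 1)


def compute_fpfh(cloud: ColoredPointCloud, radius: float) -> FPFHSet:
    """FPFH descriptors of every point of a reduced cloud.

    Neighborhoods are radius-limited (capped at the 100 nearest); points with
    an empty neighborhood get an all-zero descriptor.
    """
    if radius <= 0:
        raise ContractError("radius must be positive")
    pos, nrm = cloud.positions, cloud.normal
    n = len(cloud)
    tree = cKDTree(pos)
    k = min(n, MAX_NEIGHBORS + 1)
    dist, idx = tree.query(pos, k=k, distance_upper_bound=radius)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    # drop self matches and misses
    valid = np.isfinite(dist) & (idx != np.arange(n)[:, None]) & (dist > 0)

    src = np.repeat(np.arange(n), valid.sum(axis=1))
    tgt = idx[valid]
    pair_d = dist[valid]

    spfh = np.zeros((n, DIM))
    if len(src):
        alpha, phi, theta, _ = _pair_features_arrays(pos[src], nrm[src], pos[tgt], nrm[tgt])
        ia = _bin_index(alpha, -1.0, 1.0)
        ip = _bin_index(phi, -1.0, 1.0) + N_BINS
        it = _bin_index(theta, -np.pi, np.pi) + 2 * N_BINS
        for cols in (ia, ip, it):
            np.add.at(spfh, (src, cols), 1.0)

    fpfh = spfh.copy()
    if len(src):
        w = 1.0 / pair_d
        contrib = np.zeros((n, DIM))
        np.add.at(contrib, src, w[:, None] * spfh[tgt])
        counts = np.bincount(src, minlength=n).astype(float)
        nonzero = counts > 0
        fpfh[nonzero] += contrib[nonzero] / counts[nonzero, None]
    return FPFHSet(descriptors=fpfh, radius=radius)
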