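"""Generic colored point-cloud operations.

Voxel downsampling keeps, per occupied voxel, the member point closest to the
centroid of that voxel's points (ties broken by lowest point index). The grid
is anchored at the axis-aligned bounding-box minimum, which makes the
reduction deterministic for a given cloud and voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ContractError
from .surface import ColoredPointCloud

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid-body transform (rotation + translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ContractError("transform matrix must be 4x4")
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m[3], (0.0, 0.0, 0.0, 1.0), atol=_ORTHO_TOL):
            raise ContractError("last row must be (0, 0, 0, 1)")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ContractError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ContractError("reflections are not rigid transforms")

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(R, dtype=float)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 10.0) -> "RigidTransform":
        """Uniform random rotation and a uniform translation in a cube."""
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls.from_rotation_translation(R, t)

    # -- accessors --------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra ----------------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = self.rotation.T
        m[:3, 3] = -self.rotation.T @ self.translation
        return RigidTransform(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def apply_normals(self, normals: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(normals, dtype=float)) @ self.rotation.T

    # -- text serialization (row-major 4x4) --------------------------------
    def to_text(self) -> str:
        return "\n".join(" ".join(f"{v:.12g}" for v in row) for row in self.matrix)

    @classmethod
    def from_text(cls, text: str) -> "RigidTransform":
        vals = np.array(text.split(), dtype=float)
        if vals.size != 16:
            raise ContractError("expected 16 whitespace-separated numbers")
        return cls(vals.reshape(4, 4))


def reorthonormalize(R: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) via SVD."""
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def voxel_downsample(cloud: ColoredPointCloud, vs: float) -> ColoredPointCloud:
    """Reduce to one representative point per occupied voxel of edge ``vs``."""
    if vs <= 0:
        raise ContractError("voxel size must be positive")
    if len(cloud) == 0:
        raise ContractError("cannot downsample an empty cloud")
    pos = cloud.positions
    keys = np.floor((pos - pos.min(axis=0)) / vs).astype(np.int64)
    _, voxel_id = np.unique(keys, axis=0, return_inverse=True)

    order = np.argsort(voxel_id, kind="stable")
    vid = voxel_id[order]
    starts = np.flatnonzero(np.r_[True, vid[1:] != vid[:-1]])
    sums = np.add.reduceat(pos[order], starts, axis=0)
    counts = np.diff(np.r_[starts, len(vid)])
    centroids = sums / counts[:, None]

    dist = np.linalg.norm(pos[order] - centroids[vid], axis=1)
    # per voxel: argmin distance, ties -> lowest original point index
    pick = np.lexsort((order, dist, vid))
    winners = order[pick[starts]]
    return cloud.select(np.sort(winners))


def apply_transform(cloud: ColoredPointCloud, T: RigidTransform) -> ColoredPointCloud:
    """Rigidly move a cloud: positions rotated+translated, normals rotated."""
    if not isinstance(T, RigidTransform):
        raise ContractError("T must be a RigidTransform")
    out = cloud.copy()
    out.positions = T.apply(cloud.positions)
    out.normal = T.apply_normals(cloud.normal)
    return out


def nn_query(target, query_points: np.ndarray, max_dist: float | None = None):
    """Exact nearest neighbor of each query point in the target cloud.

    Returns ``(index, distance)`` arrays; ``index`` is -1 (and distance inf)
    where the nearest neighbor is farther than ``max_dist``.
    """
    tgt = target.positions if isinstance(target, ColoredPointCloud) else np.asarray(target)
    if len(tgt) == 0:
        raise ContractError("target cloud is empty")
    tree = cKDTree(tgt)
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    if max_dist is None:
        dist, idx = tree.query(q)
    else:
        dist, idx = tree.query(q, distance_upper_bound=max_dist)
        idx = np.where(np.isinf(dist), -1, idx)
    return idx.astype(np.int64), dist
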