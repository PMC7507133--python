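"""Two-stage rigid registration of colored point clouds.

Stage 1 ("global"): RANSAC over FPFH correspondences. Each iteration samples
N source points, pairs each with its nearest target point in 33-D descriptor
space, and keeps the Kabsch transform only if (1) every transformed sample
lies within ``vs * 1.5`` of its correspondent and (2) all sampled edge
lengths agree within 10%. Validated hypotheses are ranked by the RMSE of the
whole reduced source against the target (correspondences within
``vs * 1.5``); the search stops after 400000 sampled hypotheses or 1000
validations, whichever comes first.

Stage 2 ("color"): Gauss-Newton colored ICP minimizing
``E(T) = delta * Eg(T) + (1 - delta) * Ec(T)`` with ``delta = 0.8``, where
Eg is the point-to-plane objective and Ec compares each source point's
scalar color with the target color field extrapolated (via a precomputed
tangent-plane gradient) to the source point's projection. Iterations stop at
100 or when the relative RMSE change drops below 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cloud import RigidTransform, reorthonormalize
from .errors import ContractError, DegenerateGeometryError
from .features import FPFHSet
from .surface import ColoredPointCloud

_RANSAC_BATCH = 4096


@dataclass
class GlobalParams:
    """RANSAC stage parameters (voxel size ``vs`` sets every length scale)."""

    vs: float
    ransac_n: int = 4
    max_iterations: int = 400_000
    max_validations: int = 1000
    dist_check_factor: float = 1.5
    edge_tolerance: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ransac_n < 3:
            raise ContractError("ransac_n must be >= 3")
        if self.vs <= 0 or self.dist_check_factor <= 0 or self.edge_tolerance <= 0:
            raise ContractError("tolerances must be positive")

    @property
    def max_corr_dist(self) -> float:
        return self.vs * self.dist_check_factor


@dataclass
class ColorICPParams:
    """Colored-ICP parameters; ``delta`` balances geometry vs color."""

    max_corr_dist: float
    gradient_radius: float
    delta: float = 0.8
    max_iterations: int = 100
    rel_rmse_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ContractError("delta must be in [0, 1]")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rmse: float
    n_corr: int
    stage: str
    success: bool = True
    n_iterations: int = 0
    n_validations: int = 0
    extras: dict = field(default_factory=dict)


def kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit T minimizing ||T(P) - Q||^2 (no reflection)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ContractError("kabsch needs matching point sets with >= 3 points")
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise DegenerateGeometryError("collinear points: rotation underdetermined")
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return RigidTransform.from_rotation_translation(R, t)


def _kabsch_batch(P: np.ndarray, Q: np.ndarray):
    """Rigid fits for stacked point sets P, Q of shape (B, m, 3).

    Returns (R, t) with shapes (B, 3, 3), (B, 3). Degenerate members get an
    identity fit and are expected to fail the subsequent proximity check.
    """
    Pm, Qm = P.mean(axis=1, keepdims=True), Q.mean(axis=1, keepdims=True)
    H = np.einsum("bmi,bmj->bij", P - Pm, Q - Qm)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("bij,bjk->bik", Vt.transpose(0, 2, 1), U.transpose(0, 2, 1)))
    D = np.repeat(np.eye(3)[None], len(P), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("bij,bjk,bkl->bil", Vt.transpose(0, 2, 1), D, U.transpose(0, 2, 1))
    bad = S[:, 1] < 1e-10 * np.maximum(S[:, 0], 1e-30)
    if bad.any():
        R[bad] = np.eye(3)
    t = Qm[:, 0] - np.einsum("bij,bj->bi", R, Pm[:, 0])
    return R, t


def global_registration(
    src_reduced: ColoredPointCloud,
    tgt_reduced: ColoredPointCloud,
    fpfh_src: FPFHSet,
    fpfh_tgt: FPFHSet,
    params: GlobalParams,
) -> RegistrationResult:
    """Seeded RANSAC global registration (bit-reproducible for a fixed seed)."""
    n_src, n_tgt = len(src_reduced), len(tgt_reduced)
    if n_src < params.ransac_n or n_tgt < params.ransac_n:
        raise ContractError("reduced clouds smaller than ransac_n")
    if len(fpfh_src) != n_src or len(fpfh_tgt) != n_tgt:
        raise ContractError("descriptor sets do not match the clouds")

    # correspondence map: per source point, 1-NN target in descriptor space
    corr = cKDTree(fpfh_tgt.descriptors).query(fpfh_src.descriptors)[1]

    src_pos, tgt_pos = src_reduced.positions, tgt_reduced.positions
    tgt_tree = cKDTree(tgt_pos)
    thr = params.max_corr_dist
    N = params.ransac_n
    iu, ju = np.triu_indices(N, k=1)

    rng = np.random.default_rng(params.seed)
    best_rmse, best_T, best_ncorr = np.inf, None, 0
    iters = validations = 0
    while iters < params.max_iterations and validations < params.max_validations:
        b = min(_RANSAC_BATCH, params.max_iterations - iters)
        iters += b
        samples = rng.integers(0, n_src, size=(b, N))
        ok = np.array([len(set(row)) == N for row in samples])

        P = src_pos[samples]                 # (b, N, 3)
        Q = tgt_pos[corr[samples]]
        # check 2 first (transform-independent): edge lengths within 10%
        es = np.linalg.norm(P[:, iu] - P[:, ju], axis=2)
        et = np.linalg.norm(Q[:, iu] - Q[:, ju], axis=2)
        emax = np.maximum(es, et)
        ok &= np.all((np.abs(es - et) <= params.edge_tolerance * emax) & (emax > 0), axis=1)
        if ok.any():
            R, t = _kabsch_batch(P[ok], Q[ok])
            moved = np.einsum("bij,bmj->bmi", R, P[ok]) + t[:, None, :]
            # check 1: transformed samples near their correspondents
            near = np.all(np.linalg.norm(moved - Q[ok], axis=2) <= thr, axis=1)
            for R1, t1 in zip(R[near], t[near]):
                if validations >= params.max_validations:
                    break
                moved_all = src_pos @ R1.T + t1
                d, _ = tgt_tree.query(moved_all, distance_upper_bound=thr)
                paired = np.isfinite(d)
                if not paired.any():
                    continue  # no usable correspondence: hypothesis discarded
                validations += 1
                rmse = float(np.sqrt(np.mean(d[paired] ** 2)))
                if rmse < best_rmse:
                    best_rmse, best_ncorr = rmse, int(paired.sum())
                    best_T = RigidTransform.from_rotation_translation(
                        reorthonormalize(R1), t1
                    )

    if best_T is None:
        return RegistrationResult(
            RigidTransform.identity(), np.inf, 0, "global", success=False,
            n_iterations=iters, n_validations=0,
        )
    return RegistrationResult(
        best_T, best_rmse, best_ncorr, "global",
        n_iterations=iters, n_validations=validations,
    )


def color_gradient(tgt_reduced: ColoredPointCloud, radius: float) -> np.ndarray:
    """Per-point tangent-plane gradient of the scalar color field.

    Least-squares fit of ``g . (p' - p) ~ c' - c`` over the radius
    neighborhood with neighbor offsets projected onto the tangent plane and a
    constraint row enforcing ``g . n = 0``. Uniform neighborhoods (or points
    with fewer than 3 neighbors) get a zero gradient.
    """
    pos, nrm, col = tgt_reduced.positions, tgt_reduced.normal, tgt_reduced.color
    n = len(tgt_reduced)
    tree = cKDTree(pos)
    grads = np.zeros((n, 3))
    neighborhoods = tree.query_ball_point(pos, radius)
    for i in range(n):
        nb = [j for j in neighborhoods[i] if j != i]
        if len(nb) < 3:
            continue
        dc = col[nb] - col[i]
        if np.all(dc == 0.0):
            continue
        off = pos[nb] - pos[i]
        off = off - np.outer(off @ nrm[i], nrm[i])  # project to tangent plane
        A = np.vstack([off, nrm[i] * len(nb)])
        b = np.r_[dc, 0.0]
        g, *_ = np.linalg.lstsq(A, b, rcond=None)
        grads[i] = g - (g @ nrm[i]) * nrm[i]
    return grads


def icp_cost(
    src: ColoredPointCloud,
    tgt: ColoredPointCloud,
    T: RigidTransform,
    params: ColorICPParams,
    gradients: np.ndarray | None = None,
) -> float:
    """Evaluate E(T) = delta * Eg + (1 - delta) * Ec by direct summation."""
    if gradients is None:
        gradients = color_gradient(tgt, params.gradient_radius)
    tree = cKDTree(tgt.positions)
    q = T.apply(src.positions)
    d, j = tree.query(q, distance_upper_bound=params.max_corr_dist)
    m = np.isfinite(d)
    if not m.any():
        return np.inf
    j = j[m]
    diff = q[m] - tgt.positions[j]
    r_g = np.einsum("ij,ij->i", tgt.normal[j], diff)
    proj = diff - tgt.normal[j] * r_g[:, None]
    c_proj = tgt.color[j] + np.einsum("ij,ij->i", gradients[j], proj)
    r_c = c_proj - src.color[m]
    return float(params.delta * np.sum(r_g**2) + (1 - params.delta) * np.sum(r_c**2))


def colored_icp(
    src_reduced: ColoredPointCloud,
    tgt_reduced: ColoredPointCloud,
    init: RigidTransform,
    params: ColorICPParams,
) -> RegistrationResult:
    """Colored-ICP refinement starting from the global alignment."""
    if not isinstance(init, RigidTransform):
        raise ContractError("init must be a RigidTransform")
    tgt_pos, tgt_nrm, tgt_col = (
        tgt_reduced.positions, tgt_reduced.normal, tgt_reduced.color,
    )
    src_pos, src_col = src_reduced.positions, src_reduced.color
    grads = color_gradient(tgt_reduced, params.gradient_radius)
    tree = cKDTree(tgt_pos)
    sqrt_g, sqrt_c = np.sqrt(params.delta), np.sqrt(1.0 - params.delta)

    T = init.matrix.copy()
    prev_rmse = None
    rmse, n_corr = np.inf, 0
    for it in range(1, params.max_iterations + 1):
        q = src_pos @ T[:3, :3].T + T[:3, 3]
        d, j = tree.query(q, distance_upper_bound=params.max_corr_dist)
        m = np.isfinite(d)
        if not m.any():
            if it == 1:
                return RegistrationResult(
                    init, np.inf, 0, "color", success=False, n_iterations=0
                )
            break
        j = j[m]
        p = q[m]
        nt, ct, gt = tgt_nrm[j], tgt_col[j], grads[j]
        diff = p - tgt_pos[j]
        rmse = float(np.sqrt(np.mean(d[m] ** 2)))
        n_corr = int(m.sum())

        r_g = np.einsum("ij,ij->i", nt, diff)
        proj = diff - nt * r_g[:, None]
        r_c = (ct + np.einsum("ij,ij->i", gt, proj)) - src_col[m]

        # Jacobians wrt the twist (omega, t) at the current estimate
        J_g = np.hstack([np.cross(p, nt), nt]) * sqrt_g
        J_c = np.hstack([np.cross(p, gt), gt]) * sqrt_c
        J = np.vstack([J_g, J_c])
        r = np.r_[r_g * sqrt_g, r_c * sqrt_c]
        JtJ = J.T @ J
        Jtr = J.T @ r
        try:
            xi = np.linalg.solve(JtJ + 1e-12 * np.eye(6), -Jtr)
        except np.linalg.LinAlgError:
            break
        dR = Rotation.from_rotvec(xi[:3]).as_matrix()
        Tn = np.eye(4)
        Tn[:3, :3] = reorthonormalize(dR @ T[:3, :3])
        Tn[:3, 3] = dR @ T[:3, 3] + xi[3:]
        T = Tn

        if rmse < 1e-12:  # numerically exact; relative change is noise here
            break
        if prev_rmse is not None:
            if abs(prev_rmse - rmse) / prev_rmse < params.rel_rmse_tol:
                break
        prev_rmse = rmse

    # final bookkeeping at the converged pose
    q = src_pos @ T[:3, :3].T + T[:3, 3]
    d, _ = tree.query(q, distance_upper_bound=params.max_corr_dist)
    m = np.isfinite(d)
    if m.any():
        rmse, n_corr = float(np.sqrt(np.mean(d[m] ** 2))), int(m.sum())
    return RegistrationResult(
        RigidTransform(T), rmse, n_corr, "color", n_iterations=it
    )
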