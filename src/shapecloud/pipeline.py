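"""End-to-end alignment workflow.

``align_pair`` builds both full-resolution surfaces once, then for each voxel
size of the sweep (0.2-1.2 A by default) downsamples, computes FPFH
descriptors, runs the RANSAC global stage and the colored-ICP refinement,
and scores the result on the *full* clouds. The alignment with the largest
``gfit + hfit`` wins (ties: lower final RMSE, then smaller voxel size).

Randomized protocols (``random_pose``, ``repeat_align``) derive every
per-run / per-voxel seed deterministically from the base seed, so whole
experiments are reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import chemio
from .chemio import Molecule
from .cloud import RigidTransform, apply_transform, voxel_downsample
from .constants import DEFAULT_DOTS_PER_ATOM, DEFAULT_VS_SWEEP, PAIR_THRESHOLD
from .errors import AlignmentFailureError, ContractError
from .features import RADIUS_FACTOR, compute_fpfh
from .registration import (
    ColorICPParams,
    GlobalParams,
    colored_icp,
    global_registration,
)
from .scoring import FitnessScores, fitness
from .surface import ColoredPointCloud, build_surface_cloud

log = logging.getLogger("shapecloud")


@dataclass
class AlignmentResult:
    """Outcome of one (voxel size, seed) alignment run."""

    transform: RigidTransform
    scores: FitnessScores | None
    vs: float
    seed: int
    rmse_global: float
    rmse_final: float
    run_id: int = 0
    success: bool = True
    extras: dict = field(default_factory=dict)

    @property
    def key(self) -> float:
        """Selection key: gfit + hfit."""
        if self.scores is None:
            return -np.inf
        return self.scores.gfit + self.scores.hfit

    def to_dict(self) -> dict:
        d = {
            "vs": self.vs,
            "seed": self.seed,
            "run_id": self.run_id,
            "success": self.success,
            "rmse_global": self.rmse_global,
            "rmse_final": self.rmse_final,
        }
        if self.scores is not None:
            d.update(self.scores.to_dict())
        return d


def derive_seed(base_seed: int, vs: float, run_id: int = 0) -> int:
    """Deterministic, platform-independent sub-seed below 2**31."""
    token = f"{base_seed}:{run_id}:{vs:.3f}".encode()
    return zlib.crc32(token) % (2**31)


def _prepared(mol: Molecule) -> Molecule:
    if np.any(mol.radii <= 0) or np.any(mol.classes < 1):
        return chemio.prepare(mol.copy())
    return mol


def align_clouds(
    s1: ColoredPointCloud,
    s2: ColoredPointCloud,
    vs: float,
    seed: int,
    run_id: int = 0,
    threshold: float = PAIR_THRESHOLD,
) -> AlignmentResult:
    """One full global+color alignment of source cloud s1 onto target s2."""
    r1, r2 = voxel_downsample(s1, vs), voxel_downsample(s2, vs)
    gp = GlobalParams(vs=vs, seed=seed)
    if len(r1) < gp.ransac_n or len(r2) < gp.ransac_n:
        return AlignmentResult(
            RigidTransform.identity(), None, vs, seed, np.inf, np.inf, run_id, False
        )
    radius = RADIUS_FACTOR * vs
    f1, f2 = compute_fpfh(r1, radius), compute_fpfh(r2, radius)
    g = global_registration(r1, r2, f1, f2, gp)
    if not g.success:
        return AlignmentResult(
            RigidTransform.identity(), None, vs, seed, np.inf, np.inf, run_id, False
        )
    icp_params = ColorICPParams(max_corr_dist=gp.max_corr_dist, gradient_radius=2.0 * vs)
    c = colored_icp(r1, r2, g.transform, icp_params)
    final_T = c.transform if c.success else g.transform

    scores = fitness(apply_transform(s1, final_T), s2, threshold)
    scores.global_gfit = fitness(apply_transform(s1, g.transform), s2, threshold).gfit
    scores.rmse = c.rmse if c.success else g.rmse
    scores.extras.update(n_source=len(s1), n_target=len(s2), vs=vs, seed=seed)
    return AlignmentResult(
        transform=final_T,
        scores=scores,
        vs=vs,
        seed=seed,
        rmse_global=g.rmse,
        rmse_final=c.rmse if c.success else g.rmse,
        run_id=run_id,
        success=True,
        extras={"n_reduced_source": len(r1), "n_reduced_target": len(r2)},
    )


def align_pair(
    source: Molecule,
    target: Molecule,
    vs_list=DEFAULT_VS_SWEEP,
    seed: int = 0,
    dots_per_atom: int = DEFAULT_DOTS_PER_ATOM,
    run_id: int = 0,
    threshold: float = PAIR_THRESHOLD,
) -> tuple[AlignmentResult, list[AlignmentResult]]:
    """Voxel-size sweep alignment; returns (best result, all results)."""
    source, target = _prepared(source), _prepared(target)
    s1 = build_surface_cloud(source, dots_per_atom)
    s2 = build_surface_cloud(target, dots_per_atom)
    results = []
    for vs in vs_list:
        res = align_clouds(
            s1, s2, vs, derive_seed(seed, vs, run_id), run_id, threshold
        )
        log.info(
            "vs=%.1f success=%s gfit=%s hfit=%s",
            vs,
            res.success,
            None if res.scores is None else round(res.scores.gfit, 3),
            None if res.scores is None else round(res.scores.hfit, 3),
        )
        results.append(res)
    usable = [r for r in results if r.success]
    if not usable:
        raise AlignmentFailureError("every voxel size of the sweep failed")
    best = min(usable, key=lambda r: (-r.key, r.rmse_final, r.vs))
    return best, results


def random_pose(mol: Molecule, seed: int | np.random.Generator) -> Molecule:
    """Apply a seeded uniform random rotation plus a uniform [-10, 10]^3 A
    translation to a copy of the molecule."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = RigidTransform.random(rng, max_translation=10.0)
    out = mol.copy()
    moved = T.apply(out.positions)
    for a, p in zip(out.atoms, moved):
        a.position = p
    return out


def _heavy_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def cluster_poses(
    poses: list[np.ndarray], rmsd_cutoff: float = 1.0
) -> list[list[int]]:
    """Greedy leader clustering of poses by pairwise coordinate RMSD."""
    clusters: list[list[int]] = []
    for i, p in enumerate(poses):
        for members in clusters:
            if _heavy_rmsd(p, poses[members[0]]) < rmsd_cutoff:
                members.append(i)
                break
        else:
            clusters.append([i])
    return sorted(clusters, key=len, reverse=True)


def repeat_align(
    source: Molecule,
    target: Molecule,
    n_runs: int,
    base_seed: int = 0,
    vs_list=DEFAULT_VS_SWEEP,
    dots_per_atom: int = DEFAULT_DOTS_PER_ATOM,
    rmsd_cutoff: float = 1.0,
):
    """Repeat the sweep from fresh random source poses and cluster the final
    poses by heavy-atom RMSD.

    Returns ``(results, summary)`` where summary rows carry each cluster's
    frequency (percent of runs) and best ``gfit + hfit``.
    """
    if n_runs < 1:
        raise ContractError("n_runs must be >= 1")
    source = _prepared(source)
    heavy = [k for k, el in enumerate(source.elements) if el != "H"] or list(
        range(len(source))
    )
    results, poses = [], []
    for r in range(n_runs):
        posed = random_pose(source, derive_seed(base_seed, -1.0, r))
        best, _ = align_pair(
            posed, target, vs_list, seed=base_seed, run_id=r, dots_per_atom=dots_per_atom
        )
        results.append(best)
        poses.append(best.transform.apply(posed.positions)[heavy])
    clusters = cluster_poses(poses, rmsd_cutoff)
    summary = [
        {
            "members": members,
            "frequency": 100.0 * len(members) / n_runs,
            "best_score": max(results[i].key for i in members),
        }
        for members in clusters
    ]
    return results, summary


def rank_conformers(
    conformers: list[Molecule],
    target: Molecule,
    seed: int = 0,
    vs_list=DEFAULT_VS_SWEEP,
    dots_per_atom: int = DEFAULT_DOTS_PER_ATOM,
) -> list[AlignmentResult]:
    """Align every conformer to the target; sort by gfit + hfit (stable)."""
    if not conformers:
        raise ContractError("need at least one conformer")
    results = []
    for k, conf in enumerate(conformers):
        best, _ = align_pair(
            conf, target, vs_list, seed=seed, run_id=k, dots_per_atom=dots_per_atom
        )
        best.extras["conformer_index"] = k
        results.append(best)
    return sorted(results, key=lambda r: -r.key)
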