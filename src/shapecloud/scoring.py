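"""Tversky-style fitness scores on full-resolution clouds.

A transformed source point is *paired* when its nearest target point lies
strictly within the threshold (0.3 A by default, the mean adjacent-point
spacing of the full-resolution surfaces); it is *class-paired* when that
nearest point additionally carries the same pharmacophore class. Pairing is
many-to-one: several source points may share one target point.

gfit  = paired / total                       (all source points)
cfit  = sum_k class-paired_k / sum_k size_k  (k over all 4 classes)
hfit  = same ratio over classes 2..4 only   (polar + skeleton + other)

These are asymmetric (Tversky-like): the smaller cloud of a pair always
scores at least as high as the larger one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import PAIR_THRESHOLD
from .errors import ContractError
from .surface import ColoredPointCloud


@dataclass
class FitnessScores:
    gfit: float
    cfit: float
    hfit: float
    pair_threshold: float = PAIR_THRESHOLD
    global_gfit: float | None = None
    per_class_matches: tuple[int, int, int, int] = (0, 0, 0, 0)
    per_class_sizes: tuple[int, int, int, int] = (0, 0, 0, 0)
    rmse: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in (self.gfit, self.cfit, self.hfit):
            if not 0.0 <= s <= 1.0:
                raise ContractError(f"score {s} outside [0, 1]")
        if any(m > s for m, s in zip(self.per_class_matches, self.per_class_sizes)):
            raise ContractError("class matches exceed class sizes")

    def to_dict(self) -> dict:
        d = {
            "gfit": self.gfit,
            "cfit": self.cfit,
            "hfit": self.hfit,
            "global_gfit": self.global_gfit,
            "pair_threshold": self.pair_threshold,
            "rmse": self.rmse,
        }
        d.update(self.extras)
        return d


def pair_points(
    src_aligned: ColoredPointCloud,
    tgt: ColoredPointCloud,
    threshold: float = PAIR_THRESHOLD,
):
    """Per-source (paired, class-paired) flags against the target cloud."""
    if len(src_aligned) == 0 or len(tgt) == 0:
        raise ContractError("pairing needs non-empty clouds")
    dist, idx = cKDTree(tgt.positions).query(src_aligned.positions)
    matched = dist < threshold
    class_matched = matched & (tgt.cls[idx] == src_aligned.cls)
    return matched, class_matched


def fitness(
    src_aligned: ColoredPointCloud,
    tgt: ColoredPointCloud,
    threshold: float = PAIR_THRESHOLD,
) -> FitnessScores:
    """gfit/cfit/hfit of an aligned source cloud against a target cloud."""
    if len(src_aligned) == 0:
        raise ContractError("empty source cloud")
    matched, class_matched = pair_points(src_aligned, tgt, threshold)
    sizes = tuple(int(np.sum(src_aligned.cls == k)) for k in range(1, 5))
    hits = tuple(
        int(np.sum(class_matched & (src_aligned.cls == k))) for k in range(1, 5)
    )
    gfit = float(np.mean(matched))
    cfit = sum(hits) / sum(sizes)
    n_h = sum(sizes[1:])
    hfit = (sum(hits[1:]) / n_h) if n_h else 0.0
    return FitnessScores(
        gfit=gfit,
        cfit=cfit,
        hfit=hfit,
        pair_threshold=threshold,
        per_class_matches=hits,
        per_class_sizes=sizes,
    )
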