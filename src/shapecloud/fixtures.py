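"""Embedded test molecules and synthetic generators.

Coordinates were generated once (ETKDG embedding, seed 2024, MMFF refine)
and frozen as SDF text in the package data; they are parsed, not rebuilt, at
run time. Atom/bond counts per fixture:

================  =====  =====
name              atoms  bonds
================  =====  =====
methane               5      4
benzene              12     12
toluene              15     15
sorbic_acid          16     15
acetic_acid           8      7
methyl_tetrazole     10     10
druglike             56     58   (two aryl rings + piperazine benzamide)
================  =====  =====
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import chemio
from .chemio import Atom, Molecule
from .cloud import RigidTransform
from .constants import CLASS_COLOR_VALUE, XH_BOND_DEFAULT, XH_BOND_LENGTH
from .errors import ContractError
from .surface import ColoredPointCloud

FIXTURE_NAMES = (
    "methane",
    "benzene",
    "toluene",
    "sorbic_acid",
    "acetic_acid",
    "methyl_tetrazole",
    "druglike",
)


def list_fixtures() -> tuple[str, ...]:
    return FIXTURE_NAMES


def load_fixture(name: str, prepared: bool = True) -> Molecule:
    """Load an embedded fixture; ``prepared`` assigns radii and classes."""
    if name not in FIXTURE_NAMES:
        raise ContractError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("shapecloud").joinpath(f"data/{name}.sdf")
    with resources.as_file(ref) as path:
        mol = chemio.read_molecule(path, fmt="sdf")
    return chemio.prepare(mol) if prepared else mol


def carve_fragment(mol: Molecule, atom_subset) -> Molecule:
    """Cut a connected sub-molecule, capping dangling bonds with hydrogens.

    Each severed bond (i in subset, j outside) is replaced by an H placed
    along the former i->j direction at a standard X-H length. Coordinates of
    kept atoms are untouched.
    """
    subset = sorted(set(int(i) for i in atom_subset))
    n = len(mol)
    if not subset or any(i < 0 or i >= n for i in subset):
        raise ContractError("atom subset out of range")
    inset = np.zeros(n, dtype=bool)
    inset[subset] = True

    inner = [(i, j) for i, j in mol.bonds if inset[i] and inset[j]]
    if len(subset) > 1:
        rows = [subset.index(i) for i, j in inner] + [subset.index(j) for i, j in inner]
        cols = [subset.index(j) for i, j in inner] + [subset.index(i) for i, j in inner]
        adj = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(subset), len(subset))
        )
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ContractError("atom subset is not connected in the bond graph")

    remap = {old: new for new, old in enumerate(subset)}
    atoms = [
        Atom(mol.atoms[i].element, mol.atoms[i].position.copy(), mol.atoms[i].radius,
             mol.atoms[i].cls)
        for i in subset
    ]
    orders = mol.bond_orders or [1] * len(mol.bonds)
    bonds = [(remap[i], remap[j]) for i, j in inner]
    new_orders = [o for (i, j), o in zip(mol.bonds, orders) if inset[i] and inset[j]]

    for (i, j), _o in zip(mol.bonds, orders):
        for keep, lose in ((i, j), (j, i)):
            if inset[keep] and not inset[lose]:
                anchor = mol.atoms[keep]
                vec = mol.atoms[lose].position - anchor.position
                vec = vec / np.linalg.norm(vec)
                length = XH_BOND_LENGTH.get(anchor.element, XH_BOND_DEFAULT)
                cap = Atom("H", anchor.position + length * vec)
                atoms.append(cap)
                bonds.append((remap[keep], len(atoms) - 1))
                new_orders.append(1)

    frag = Molecule(f"{mol.name}_fragment", atoms, bonds, new_orders)
    return chemio.prepare(frag)


@dataclass
class ColorSymmetryToy:
    """A geometry with an exact 2-fold symmetry broken only by point colors.

    ``source`` placed at ``true_transform`` coincides with ``target``; placed
    at ``flipped_transform`` (the extra 180-degree rotation about the
    symmetry axis) it coincides geometrically but mismatches every color.
    """

    source: ColoredPointCloud
    target: ColoredPointCloud
    true_transform: RigidTransform
    flipped_transform: RigidTransform


def symmetric_color_toy(separation: float = 0.25, seed: int = 0) -> ColorSymmetryToy:
    """Build congruent clouds on a parabolic sheet z = 0.1 x^2.

    The grid is symmetric under a 180-degree rotation about the z axis; the
    class labels (apolar on x < 0, polar on x >= 0) break that symmetry. The
    target is the sheet moved by a seeded random rigid transform, which is
    returned as the ground truth.
    """
    if separation <= 0:
        raise ContractError("separation must be positive")
    half = 8
    xs = (np.arange(-half, half + 1)) * separation
    ys = (np.arange(-half, half + 1)) * separation
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    curv = 0.1
    Z = curv * X**2
    pos = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    # analytic normals of z - 0.1 x^2 = 0
    nrm = np.column_stack(
        [-2 * curv * pos[:, 0], np.zeros(len(pos)), np.ones(len(pos))]
    )
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    cls = np.where(pos[:, 0] < 0, 1, 2)
    color = np.array([CLASS_COLOR_VALUE[int(c)] for c in cls])
    parent = np.full(len(pos), -1)
    source = ColoredPointCloud(pos, cls, color, nrm.copy(), parent.copy())

    rng = np.random.default_rng(seed)
    true_T = RigidTransform.random(rng, max_translation=3.0)
    target = ColoredPointCloud(
        true_T.apply(pos),
        cls.copy(),
        color.copy(),
        true_T.apply_normals(nrm),
        parent.copy(),
    )
    flip = RigidTransform.from_rotation_translation(
        np.diag([-1.0, -1.0, 1.0]), np.zeros(3)
    )
    return ColorSymmetryToy(
        source=source,
        target=target,
        true_transform=true_T,
        flipped_transform=true_T @ flip,
    )
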