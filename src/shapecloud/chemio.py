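"""Molecular structure I/O, van der Waals radii and pharmacophore classes.

Molecules are lightweight containers: element symbols, Cartesian coordinates
in Angstrom, a bond list, and (once assigned) per-atom vdW radii and
pharmacophore classes. Parsing and SDF writing are delegated to RDKit;
indices are 0-based internally and converted at the file boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    APOLAR_HALOGENS,
    BONDI_RADII,
    POLAR_ELEMENTS,
    POLAR_H_CUTOFF,
    SKELETON_ELEMENTS,
)
from .errors import ContractError, MoleculeParseError, UnknownElementError


@dataclass
class Atom:
    """One atom: element symbol, position (Angstrom), vdW radius, class."""

    element: str
    position: np.ndarray
    radius: float = 0.0
    cls: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ContractError(f"atom position must be a finite 3-vector, got {self.position!r}")


@dataclass
class Molecule:
    """An ordered list of atoms plus a bond list of 0-based (i, j) pairs, i < j.

    ``bond_orders`` is optional bookkeeping (aligned with ``bonds``) so that
    SDF round-trips preserve the bond block; it plays no role in alignment.
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    bond_orders: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ContractError("a molecule needs at least one atom")
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm = []
        for i, j in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ContractError(f"bond ({i},{j}) out of range for {n} atoms")
            ij = (min(i, j), max(i, j))
            if ij in seen:
                raise ContractError(f"duplicate bond {ij}")
            seen.add(ij)
            norm.append(ij)
        self.bonds = norm

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def classes(self) -> np.ndarray:
        return np.array([a.cls for a in self.atoms], dtype=int)

    def neighbors(self, i: int) -> list[int]:
        return [j if k == i else k for k, j in self.bonds if i in (k, j)]

    def copy(self) -> "Molecule":
        return Molecule(
            self.name,
            [Atom(a.element, a.position.copy(), a.radius, a.cls) for a in self.atoms],
            list(self.bonds),
            None if self.bond_orders is None else list(self.bond_orders),
        )


def _normalize_element(sym: str) -> str:
    return sym.strip().capitalize() if len(sym.strip()) > 1 else sym.strip().upper()


def _from_rdkit(rdmol, name: str) -> Molecule:
    if rdmol.GetNumConformers() == 0:
        raise MoleculeParseError(f"{name}: no 3D coordinates")
    conf = rdmol.GetConformer()
    pos = conf.GetPositions()
    atoms = [
        Atom(_normalize_element(a.GetSymbol()), pos[a.GetIdx()]) for a in rdmol.GetAtoms()
    ]
    bonds, orders = [], []
    for b in rdmol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j)))
        orders.append(max(1, int(b.GetBondTypeAsDouble())))
    return Molecule(name, atoms, bonds, orders)


def read_molecule(path: str | os.PathLike, fmt: str | None = None) -> Molecule:
    """Read a single molecule from SDF/MOL (V2000), PDB or XYZ.

    Radii and classes are *not* assigned; call :func:`assign_radii` and
    :func:`classify_atoms` before building a surface. Bond lists may be empty
    for XYZ and for PDB files without CONECT records.
    """
    from rdkit import Chem

    path = os.fspath(path)
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower() or "sdf"
    fmt = fmt.lower()
    if not os.path.exists(path):
        raise MoleculeParseError(f"no such file: {path}")
    name = os.path.splitext(os.path.basename(path))[0]

    if fmt in ("sdf", "mol"):
        rdmol = Chem.MolFromMolFile(path, sanitize=False, removeHs=False)
    elif fmt == "pdb":
        rdmol = Chem.MolFromPDBFile(
            path, sanitize=False, removeHs=False, proximityBonding=False
        )
    elif fmt == "xyz":
        from rdkit.Chem import rdmolfiles

        rdmol = rdmolfiles.MolFromXYZFile(path)
    else:
        raise MoleculeParseError(f"unsupported format: {fmt}")
    if rdmol is None:
        raise MoleculeParseError(f"could not parse {path} as {fmt}")
    mol = _from_rdkit(rdmol, name)
    if rdmol.HasProp("_Name") and rdmol.GetProp("_Name").strip():
        mol.name = rdmol.GetProp("_Name").strip()
    return mol


def read_molecules(path: str | os.PathLike) -> list[Molecule]:
    """Read every record of a multi-molecule SDF (e.g. a conformer library)."""
    from rdkit import Chem

    path = os.fspath(path)
    if not os.path.exists(path):
        raise MoleculeParseError(f"no such file: {path}")
    out = []
    supplier = Chem.SDMolSupplier(path, sanitize=False, removeHs=False)
    for k, rdmol in enumerate(supplier):
        if rdmol is None:
            raise MoleculeParseError(f"{path}: record {k + 1} unparseable")
        name = rdmol.GetProp("_Name").strip() if rdmol.HasProp("_Name") else ""
        out.append(_from_rdkit(rdmol, name or f"record{k + 1}"))
    if not out:
        raise MoleculeParseError(f"{path}: no records")
    return out


def assign_radii(mol: Molecule, table: dict[str, float] | None = None) -> Molecule:
    """Attach tabulated vdW radii (defaults to the bundled Bondi values)."""
    table = BONDI_RADII if table is None else table
    missing = sorted({a.element for a in mol.atoms} - set(table))
    if missing:
        raise UnknownElementError(
            f"no vdW radius for element(s): {', '.join(missing)}"
        )
    for a in mol.atoms:
        a.radius = float(table[a.element])
    return mol


def classify_atoms(mol: Molecule) -> Molecule:
    """Assign the four pharmacophore classes (total and idempotent).

    H bonded to N or O is polar (class 2), otherwise apolar (class 1). When
    the molecule carries no bond table (XYZ, bare PDB), an H counts as polar
    if its nearest N/O lies within 1.3 A.
    """
    pos = mol.positions
    have_bonds = bool(mol.bonds)
    no_idx = [k for k, a in enumerate(mol.atoms) if a.element in ("N", "O")]
    for i, a in enumerate(mol.atoms):
        el = a.element
        if el == "H":
            if have_bonds:
                polar = any(mol.atoms[j].element in ("N", "O") for j in mol.neighbors(i))
            else:
                polar = bool(no_idx) and (
                    np.min(np.linalg.norm(pos[no_idx] - pos[i], axis=1)) < POLAR_H_CUTOFF
                )
            a.cls = 2 if polar else 1
        elif el in APOLAR_HALOGENS:
            a.cls = 1
        elif el in POLAR_ELEMENTS:
            a.cls = 2
        elif el in SKELETON_ELEMENTS:
            a.cls = 3
        else:
            a.cls = 4
    return mol


def prepare(mol: Molecule) -> Molecule:
    """Convenience: assign default radii and classes in place."""
    return classify_atoms(assign_radii(mol))


def to_rdkit(mol: Molecule):
    """Build an (unsanitized) RDKit molecule with one conformer."""
    from rdkit import Chem
    from rdkit.Chem import rdchem

    order_map = {
        1: Chem.BondType.SINGLE,
        2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
    }
    rw = Chem.RWMol()
    for a in mol.atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    orders = mol.bond_orders or [1] * len(mol.bonds)
    for (i, j), o in zip(mol.bonds, orders):
        rw.AddBond(i, j, order_map.get(o, Chem.BondType.SINGLE))
    conf = rdchem.Conformer(len(mol))
    for k, a in enumerate(mol.atoms):
        conf.SetAtomPosition(k, a.position.tolist())
    m = rw.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", mol.name)
    return m


def write_molecule(
    mol: Molecule, path: str | os.PathLike, transform=None
) -> None:
    """Write an SDF record, optionally applying a rigid transform first.

    The element and bond blocks are written unchanged; only coordinates move.
    """
    from rdkit import Chem

    out = mol.copy()
    if transform is not None:
        moved = transform.apply(out.positions)
        for a, p in zip(out.atoms, moved):
            a.position = p
    block = Chem.MolToMolBlock(to_rdkit(out), kekulize=False)
    try:
        with open(path, "w") as fh:
            fh.write(block)
            fh.write("$$$$\n")
    except OSError as exc:
        raise ShapecloudIOError(str(exc)) from exc


class ShapecloudIOError(MoleculeParseError):
    """Unwritable or unreadable path."""
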