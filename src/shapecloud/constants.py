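"""Shared physical constants and default parameters.

Radii are the Bondi (1964) van der Waals radii, in Angstrom. Pharmacophore
classes partition atoms into four groups that drive surface coloring and the
color term of the refinement stage:

1. apolar envelope  -- nonpolar H and the heavy halogens Cl, Br, I
2. polar            -- N, O, S, F and H bonded to N or O (H-bond capable)
3. skeleton         -- C, P, B (e.g. aromatic carbon patches)
4. other            -- everything else (rare in organic drug-like molecules)
"""

from __future__ import annotations

#: Bondi (1964) van der Waals radii, Angstrom.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "P": 1.80,
    "B": 1.92,
}

#: Heavy halogens counted in the apolar class (fluorine is polar instead).
APOLAR_HALOGENS = frozenset({"Cl", "Br", "I"})
#: Elements that are polar regardless of bonding.
POLAR_ELEMENTS = frozenset({"N", "O", "S", "F"})
#: Skeleton elements.
SKELETON_ELEMENTS = frozenset({"C", "P", "B"})

#: Display colors per class (white / red / green / blue), used in PLY output.
CLASS_RGB: dict[int, tuple[int, int, int]] = {
    1: (255, 255, 255),
    2: (255, 0, 0),
    3: (0, 255, 0),
    4: (0, 0, 255),
}

#: Scalar color embedding of the categorical classes used by the colored-ICP
#: color term. Values are deliberately well separated so that cross-class
#: correspondences are penalized; a naive RGB->gray intensity would collapse
#: red/green/blue onto one value.
CLASS_COLOR_VALUE: dict[int, float] = {1: 1.0, 2: 0.0, 3: 0.5, 4: 0.25}

#: Nominal dot budget per atomic sphere.
DEFAULT_DOTS_PER_ATOM = 600

#: Reference sphere radius (Angstrom) converting the nominal per-sphere dot
#: budget into a uniform surface density: density = dots / (4*pi*R_REF^2).
#: 2.40 A makes the 600-dot default reproduce the ~0.3 A mean adjacent-point
#: spacing the method's 0.3 A pairing threshold is built on.
REF_SPHERE_RADIUS = 2.40

#: Burial tolerance: a dot survives if it is no deeper than EPS inside any
#: foreign sphere, so tangent contacts survive.
BURIAL_EPS = 1e-6

#: Pairing threshold (Angstrom) for the fitness scores.
PAIR_THRESHOLD = 0.3

#: Default voxel-size sweep (Angstrom).
DEFAULT_VS_SWEEP = tuple(round(0.2 + 0.1 * i, 1) for i in range(11))

#: Bond-free polar-H fallback: an H is polar if its nearest N/O is closer
#: than this (covalent H-N/H-O bonds are <=1.1 A; next contacts are >1.8 A).
POLAR_H_CUTOFF = 1.3

#: Default X-H bond lengths (Angstrom) used when capping carved fragments.
XH_BOND_LENGTH: dict[str, float] = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}
XH_BOND_DEFAULT = 1.09
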