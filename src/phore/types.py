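"""Core molecular containers shared by every stage of the pipeline.

Coordinates are Cartesian and in angstroms (Å) throughout; residue numbers
follow the author numbering of the source structure verbatim (e.g. the
VEGFR-2 kinase-domain residues Glu885, Glu917, Cys919, Asp1046).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Atom",
    "Molecule3D",
    "ProteinLigandComplex",
    "PocketDefinition",
    "ResidueId",
    "VEGFR2_FRONT",
    "VEGFR2_BACK",
    "residue_in_set",
]

#: (chain_id, residue_number, residue_name); chain "" acts as a wildcard
#: when a set of residue ids is used for membership tests.
ResidueId = tuple[str, int, str]

#: Front (hinge / ATP-site) residues of the VEGFR-2 kinase domain.
VEGFR2_FRONT: frozenset[ResidueId] = frozenset({("", 917, "GLU"), ("", 919, "CYS")})
#: Back (allosteric, DFG-out) pocket residues of the VEGFR-2 kinase domain.
VEGFR2_BACK: frozenset[ResidueId] = frozenset({("", 885, "GLU"), ("", 1046, "ASP")})

_HETERO = {"N", "O", "S", "P", "F", "CL", "BR", "I"}


def residue_in_set(res: ResidueId, pool: Iterable[ResidueId]) -> bool:
    """Membership test where an entry with chain "" matches any chain."""
    chain, num, name = res
    for pc, pn, pname in pool:
        if pn == num and pname.upper() == name.upper() and (pc == "" or pc == chain):
            return True
    return False


@dataclass
class Atom:
    """A single atom with optional residue annotation (receptor side)."""

    serial: int
    element: str
    position: np.ndarray
    formal_charge: int = 0
    is_aromatic: bool = False
    residue_name: str = ""
    residue_number: int = 0
    chain_id: str = ""
    name: str = ""  # PDB-style atom name, e.g. "OE2", "HN"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        self.element = self.element.strip()
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.residue_number, self.residue_name)

    def label(self) -> str:
        """Human-readable label in the Glu885:OE2 style."""
        res = f"{self.residue_name.capitalize()}{self.residue_number}" if self.residue_name else ""
        atom = self.name or self.element
        return f"{res}:{atom}" if res else atom


@dataclass
class Molecule3D:
    """A molecule (or multi-fragment assembly) with explicit 3D coordinates.

    ``bonds`` entries are (i, j, order) with 0-based atom indices and order in
    {1, 2, 3, "ar"}.
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, object]] = field(default_factory=list)
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.name!r}: at least one atom required")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError(f"molecule {self.name!r}: duplicate atom serials")
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.name!r}: bond ({i},{j}) out of range")
            if i == j:
                raise ValueError(f"molecule {self.name!r}: self-bond on atom {i}")
            if order not in (1, 2, 3, "ar"):
                raise ValueError(f"molecule {self.name!r}: bad bond order {order!r}")

    # -- geometry -----------------------------------------------------------
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        """Rigid-body copy: x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_atoms = [
            replace(a, position=rotation @ a.position + translation) for a in self.atoms
        ]
        return Molecule3D(self.name, new_atoms, list(self.bonds), dict(self.properties))

    # -- connectivity -------------------------------------------------------
    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def bond_orders(self) -> dict[frozenset, object]:
        return {frozenset((i, j)): order for i, j, order in self.bonds}

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element.upper() != "H"]

    def is_sp3_carbon(self, i: int, adj: Optional[list[list[int]]] = None) -> bool:
        a = self.atoms[i]
        if a.element.upper() != "C" or a.is_aromatic:
            return False
        orders = self.bond_orders()
        nbrs = (adj or self.neighbors())[i]
        return all(orders[frozenset((i, j))] == 1 for j in nbrs)

    def is_alkyl_carbon(self, i: int, adj: Optional[list[list[int]]] = None) -> bool:
        """sp3 carbon with no hetero-atom neighbour (pure C/H environment)."""
        adj = adj or self.neighbors()
        if not self.is_sp3_carbon(i, adj):
            return False
        return all(self.atoms[j].element.upper() not in _HETERO for j in adj[i])


@dataclass
class ProteinLigandComplex:
    """A receptor and a ligand sharing one Å coordinate frame."""

    receptor: Molecule3D
    ligand: Molecule3D

    def __post_init__(self) -> None:
        for a in self.receptor.atoms:
            if not a.residue_name or a.residue_number == 0:
                raise ValueError(
                    "receptor atoms must carry residue_name and residue_number "
                    f"(atom serial {a.serial} does not)"
                )


@dataclass
class PocketDefinition:
    """A binding site: residues within ``radius`` Å of the ligand, plus the
    optional front/back partition used by the type-II classifier."""

    radius: float
    residues: frozenset = frozenset()
    front_residues: Optional[frozenset] = None
    back_residues: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("pocket radius must be >= 0")
        self.residues = frozenset(self.residues)
        if self.front_residues is not None:
            self.front_residues = frozenset(self.front_residues)
        if self.back_residues is not None:
            self.back_residues = frozenset(self.back_residues)
        if self.residues:
            for sub, label in ((self.front_residues, "front"), (self.back_residues, "back")):
                if sub:
                    for res in sub:
                        if not residue_in_set((res[0], res[1], res[2]), self.residues) and not any(
                            residue_in_set(r, [res]) for r in self.residues
                        ):
                            raise ValueError(f"{label} residue {res} not in pocket residues")


def default_vegfr2_pocket(radius: float = 10.0, residues: Iterable[ResidueId] = ()) -> PocketDefinition:
    """The VEGFR-2 front/back pocket convention: front = Glu917 + Cys919
    (hinge), back = Glu885 + Asp1046 (allosteric pocket)."""
    return PocketDefinition(
        radius=radius,
        residues=frozenset(residues),
        front_residues=VEGFR2_FRONT,
        back_residues=VEGFR2_BACK,
    )
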