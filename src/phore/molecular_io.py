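"""Readers and writers for molecular structures and pharmacophore models.

Conventions fixed here and used everywhere else:

* coordinates are Å; residue numbers are the author numbering of the source
  PDB file, preserved verbatim (Glu885 stays 885);
* residue identity is (chain, number, 3-letter name); insertion codes are
  rejected loudly;
* pharmacophore models round-trip through a small documented JSON dialect.

PDB parsing is delegated to gemmi, SDF/MOL2/SMILES handling to RDKit; both
are converted into the package's light-weight :class:`Molecule3D` container.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import gemmi
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from scipy.spatial import cKDTree

from .pharmacophore import FEATURE_KINDS, PharmacophoreFeature, PharmacophoreModel
from .types import (
    Atom,
    Molecule3D,
    PocketDefinition,
    ProteinLigandComplex,
    VEGFR2_BACK,
    VEGFR2_FRONT,
    residue_in_set,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ParseError",
    "MissingCoordinatesError",
    "read_structure",
    "write_pdb",
    "write_sdf",
    "read_pharmacophore",
    "write_pharmacophore",
    "extract_binding_site",
    "mol_from_rdkit",
    "mol_to_rdkit",
    "mol_from_smiles",
]


class ParseError(ValueError):
    """A file failed to parse under its named standard."""


class MissingCoordinatesError(ValueError):
    """A SMILES input has no 3D coordinates and no embedding was requested."""


_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3"}

# covalent radii (Å) for distance-based bond inference on PDB input
_COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
}

# aromatic side-chain ring atoms of the standard residues (for PDB input,
# where aromaticity is not encoded in the file)
_AROMATIC_SIDECHAIN = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

_BOND_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}
_BOND_ORDER_TO_RDKIT = {v: k for k, v in _BOND_ORDER_FROM_RDKIT.items()}


# ---------------------------------------------------------------------------
# RDKit bridge
# ---------------------------------------------------------------------------

def mol_from_rdkit(rdmol: Chem.Mol, name: str = "") -> Molecule3D:
    """Convert an RDKit molecule (any conformer, explicit H kept) to
    :class:`Molecule3D`.  Without a conformer all positions are zero —
    acceptable only for topology-driven uses such as Ro5 profiling."""
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        pos = np.array(conf.GetAtomPosition(i)) if conf is not None else np.zeros(3)
        atoms.append(
            Atom(
                serial=i + 1,
                element=a.GetSymbol(),
                position=pos,
                formal_charge=a.GetFormalCharge(),
                is_aromatic=a.GetIsAromatic(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER_FROM_RDKIT.get(b.GetBondType(), 1))
        for b in rdmol.GetBonds()
    ]
    label = name or (rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "mol")
    props = {k: rdmol.GetProp(k) for k in rdmol.GetPropNames()}
    return Molecule3D(label or "mol", atoms, bonds, props)


def mol_to_rdkit(mol: Molecule3D, sanitize: bool = True) -> Chem.Mol:
    """Convert to an RDKit molecule with an explicit conformer."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element.capitalize())
        ra.SetFormalCharge(a.formal_charge)
        ra.SetIsAromatic(a.is_aromatic)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for i, j, order in mol.bonds:
        rw.AddBond(i, j, _BOND_ORDER_TO_RDKIT[order])
        if order == "ar":
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    conf = Chem.Conformer(len(mol.atoms))
    for i, a in enumerate(mol.atoms):
        conf.SetAtomPosition(i, [float(x) for x in a.position])
    m = rw.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", mol.name)
    if sanitize:
        Chem.SanitizeMol(m)
    return m


def mol_from_smiles(
    smiles: str, name: str = "", embed: bool = False, seed: int = 1
) -> Molecule3D:
    """Parse a SMILES; optionally embed a 3D conformer (ETKDG, seeded)."""
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    rdmol = Chem.AddHs(rdmol)
    if embed:
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) % (2**31 - 1)
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            raise ParseError(f"3D embedding failed for SMILES {smiles!r}")
    elif rdmol.GetNumConformers() == 0:
        raise MissingCoordinatesError(
            f"SMILES {smiles!r} carries no coordinates; pass embed=True to generate them"
        )
    return mol_from_rdkit(rdmol, name=name or smiles)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _infer_bonds(atoms: list[Atom]) -> list[tuple[int, int, object]]:
    """Distance-based covalent bond inference (r_i + r_j + 0.4 Å cutoff)."""
    xyz = np.array([a.position for a in atoms])
    tree = cKDTree(xyz)
    bonds = []
    for i, j in sorted(tree.query_pairs(r=2.6)):
        ri = _COVALENT_RADIUS.get(atoms[i].element.upper(), 0.77)
        rj = _COVALENT_RADIUS.get(atoms[j].element.upper(), 0.77)
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if d <= ri + rj + 0.4 and d > 0.4:
            order = (
                "ar"
                if atoms[i].is_aromatic
                and atoms[j].is_aromatic
                and atoms[i].residue_id == atoms[j].residue_id
                else 1
            )
            bonds.append((i, j, order))
    return bonds


def _flag_planar_rings(mol: Molecule3D) -> None:
    """PDB carries no aromaticity: flag planar 5-7 rings of C/N as aromatic
    (RMS out-of-plane <= 0.1 Å).  Saturated rings (chairs, cyclopropane)
    fail the size or planarity test and stay aliphatic."""
    import networkx as nx

    g = nx.Graph((i, j) for i, j, _ in mol.bonds)
    for cycle in nx.cycle_basis(g):
        if not (5 <= len(cycle) <= 7):
            continue
        if any(mol.atoms[i].element.upper() not in ("C", "N") for i in cycle):
            continue
        pts = np.array([mol.atoms[i].position for i in cycle])
        centred = pts - pts.mean(axis=0)
        _, s, _ = np.linalg.svd(centred, full_matrices=False)
        if s[-1] / np.sqrt(len(cycle)) > 0.1:
            continue
        for i in cycle:
            mol.atoms[i].is_aromatic = True
        ring = set(cycle)
        for k, (i, j, _) in enumerate(mol.bonds):
            if i in ring and j in ring:
                mol.bonds[k] = (i, j, "ar")


def _read_pdb(
    path: Path, strip_waters: bool = True, chain: Optional[str] = None
) -> Union[Molecule3D, ProteinLigandComplex]:
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi raises with line info
        raise ParseError(f"{path}: {exc}") from exc
    if not st or len(st) == 0:
        raise ParseError(f"{path}: no model records found")
    model = st[0]
    rec_atoms: list[Atom] = []
    lig_atoms: list[Atom] = []
    serial = 0
    chains = [c for c in model if chain is None or c.name == chain]
    if chain is not None and not chains:
        raise ParseError(f"{path}: chain {chain!r} not present")
    for ch in chains:
        for res in ch:
            if res.seqid.icode not in (" ", "", "\x00"):
                raise ParseError(
                    f"{path}: insertion code {res.seqid.icode!r} on residue "
                    f"{res.name} {res.seqid.num} is unsupported"
                )
            resname = res.name.strip().upper()
            if strip_waters and resname in _WATER_NAMES:
                continue
            is_het = res.het_flag == "H"
            for at in res:
                serial += 1
                aname = at.name.strip().upper()
                aromatic = (not is_het) and aname in _AROMATIC_SIDECHAIN.get(resname, ())
                atom = Atom(
                    serial=serial,
                    element=at.element.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    formal_charge=int(at.charge),
                    is_aromatic=aromatic,
                    residue_name=resname,
                    residue_number=res.seqid.num,
                    chain_id=ch.name,
                    name=at.name.strip(),
                )
                (lig_atoms if is_het else rec_atoms).append(atom)
    if not rec_atoms and not lig_atoms:
        raise ParseError(f"{path}: no atoms parsed")
    if not lig_atoms or not rec_atoms:
        mol = Molecule3D(path.stem, rec_atoms or lig_atoms)
        mol.bonds = _infer_bonds(mol.atoms)
        _flag_planar_rings(mol)
        return mol
    # re-index serials per molecule
    for idx, a in enumerate(rec_atoms):
        a.serial = idx + 1
    for idx, a in enumerate(lig_atoms):
        a.serial = idx + 1
    receptor = Molecule3D(path.stem + "_receptor", rec_atoms)
    receptor.bonds = _infer_bonds(rec_atoms)
    _flag_planar_rings(receptor)
    ligand = Molecule3D(path.stem + "_ligand", lig_atoms)
    ligand.bonds = _infer_bonds(lig_atoms)
    _flag_planar_rings(ligand)
    return ProteinLigandComplex(receptor=receptor, ligand=ligand)


def _pdb_atom_line(record: str, serial: int, a: Atom) -> str:
    name = (a.name or a.element)[:4]
    # standard PDB name justification: 1-char elements start in column 14
    name_field = f" {name:<3s}" if len(a.element) == 1 and len(name) < 4 else f"{name:<4s}"
    res = (a.residue_name or "LIG")[:3]
    chain = (a.chain_id or "A")[:1]
    num = a.residue_number or 1
    x, y, z = a.position
    el = a.element.upper().rjust(2)
    return (
        f"{record:<6s}{serial:>5d} {name_field} {res:<3s} {chain}{num:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el}"
    )


def write_pdb(obj: Union[Molecule3D, ProteinLigandComplex], path) -> None:
    """Write a molecule or complex as fixed-column PDB (receptor as ATOM,
    ligand as HETATM with residue name LIG unless already annotated)."""
    lines = []
    serial = 0
    if isinstance(obj, ProteinLigandComplex):
        for a in obj.receptor.atoms:
            serial += 1
            lines.append(_pdb_atom_line("ATOM", serial, a))
        lines.append("TER")
        for a in obj.ligand.atoms:
            serial += 1
            lines.append(_pdb_atom_line("HETATM", serial, a))
    else:
        for a in obj.atoms:
            serial += 1
            record = "ATOM" if a.residue_name and a.residue_name != "LIG" else "HETATM"
            lines.append(_pdb_atom_line(record, serial, a))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SDF / MOL2
# ---------------------------------------------------------------------------

def _read_sdf(path: Path) -> list[Molecule3D]:
    text = path.read_text()
    if "M  END" not in text:
        raise ParseError(
            f"{path}: truncated SDF record (no 'M  END' in {len(text.splitlines())} lines)"
        )
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols = []
    for k, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ParseError(f"{path}: record {k + 1} failed to parse")
        mols.append(mol_from_rdkit(rdmol))
    if not mols:
        raise ParseError(f"{path}: no records")
    return mols


def write_sdf(mols: Union[Molecule3D, list[Molecule3D]], path) -> None:
    if isinstance(mols, Molecule3D):
        mols = [mols]
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for m in mols:
        rd = mol_to_rdkit(m)
        for k, v in m.properties.items():
            rd.SetProp(str(k), str(v))
        writer.write(rd)
    writer.close()


def _read_mol2(path: Path) -> Molecule3D:
    rdmol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=True)
    if rdmol is None:
        raise ParseError(f"{path}: MOL2 record failed to parse")
    return mol_from_rdkit(rdmol, name=path.stem)


def read_structure(
    path,
    format: str,
    strip_waters: bool = True,
    chain: Optional[str] = None,
    embed: bool = False,
    seed: int = 1,
) -> Union[Molecule3D, ProteinLigandComplex, list[Molecule3D]]:
    """Read a structure file.

    ``format`` is one of {"pdb", "sdf", "mol2", "smiles3d"}.  PDB files with
    both polymer and HETATM ligand records return a
    :class:`ProteinLigandComplex`; SDF returns a list of molecules (a single
    molecule for one-record files would still be ``[mol]``); ``smiles3d``
    reads the first whitespace-separated token per line and requires
    ``embed=True`` to generate coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "pdb":
        return _read_pdb(path, strip_waters=strip_waters, chain=chain)
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "mol2":
        return _read_mol2(path)
    if fmt == "smiles3d":
        mols = []
        for k, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"{path.stem}_{k + 1}"
            mols.append(mol_from_smiles(parts[0], name=name, embed=embed, seed=seed + k))
        if not mols:
            raise ParseError(f"{path}: no SMILES records")
        return mols
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# binding-site extraction
# ---------------------------------------------------------------------------

def extract_binding_site(
    complex_: ProteinLigandComplex,
    radius: float = 10.0,
    front=VEGFR2_FRONT,
    back=VEGFR2_BACK,
) -> PocketDefinition:
    """Residues with any atom within ``radius`` Å (inclusive) of any ligand
    atom.  The front/back partitions keep only members actually present."""
    if not complex_.ligand.atoms:
        raise ValueError("complex has no ligand atoms")
    lig_xyz = complex_.ligand.coords()
    residues = set()
    for a in complex_.receptor.atoms:
        d = np.linalg.norm(lig_xyz - a.position, axis=1)
        if d.min() <= radius:
            residues.add(a.residue_id)
    front_present = frozenset(r for r in (front or ()) if residue_in_set_any(r, residues))
    back_present = frozenset(r for r in (back or ()) if residue_in_set_any(r, residues))
    return PocketDefinition(
        radius=radius,
        residues=frozenset(residues),
        front_residues=front_present or None,
        back_residues=back_present or None,
    )


def residue_in_set_any(pattern, residues) -> bool:
    """True when some concrete residue matches a possibly chain-wildcard id."""
    return any(residue_in_set(r, [pattern]) for r in residues)


# ---------------------------------------------------------------------------
# pharmacophore JSON dialect
# ---------------------------------------------------------------------------

PHARMACOPHORE_FORMAT = "phore-pharmacophore-json"
PHARMACOPHORE_VERSION = 1


def write_pharmacophore(model: PharmacophoreModel, path) -> None:
    if not model.features:
        raise ValueError("cannot serialize a model with no features")
    doc = {
        "format": PHARMACOPHORE_FORMAT,
        "version": PHARMACOPHORE_VERSION,
        "provenance": model.provenance,
        "selectivity": model.selectivity,
        "features": [
            {
                "kind": f.kind,
                "centroid": [float(x) for x in f.centroid],
                "tolerance": float(f.tolerance),
                "projection": None
                if f.projection is None
                else [float(x) for x in f.projection],
            }
            for f in model.features
        ],
        "distance_matrix": [[float(x) for x in row] for row in model.distance_matrix],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_pharmacophore(path) -> PharmacophoreModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if doc.get("format") != PHARMACOPHORE_FORMAT:
        raise ParseError(f"{path}: not a {PHARMACOPHORE_FORMAT} file")
    feats = []
    for k, fd in enumerate(doc.get("features", [])):
        if fd.get("kind") not in FEATURE_KINDS:
            raise ParseError(
                f"{path}: feature {k + 1} has unknown kind {fd.get('kind')!r} "
                f"(expected one of {FEATURE_KINDS})"
            )
        proj = fd.get("projection")
        feats.append(
            PharmacophoreFeature(
                fd["kind"],
                np.array(fd["centroid"], dtype=float),
                float(fd["tolerance"]),
                None if proj is None else np.array(proj, dtype=float),
            )
        )
    return PharmacophoreModel(
        feats,
        distance_matrix=np.array(doc["distance_matrix"], dtype=float),
        selectivity=float(doc.get("selectivity", 0.0)),
        provenance=doc.get("provenance", ""),
    )
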