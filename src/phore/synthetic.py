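"""Deterministic, seeded generators for every input the pipeline needs.

Three families:

* **ligands** — valence-correct fragment assemblies whose perceived features
  sit exactly on a pharmacophore model's centroids (matchers) or violate it
  by construction (decoys).  Each feature kind maps to a dedicated chemical
  group that expresses *only* that kind under the perception rules:
  methanethiol (S-H donor; sulfur is not a Lipinski-style acceptor) for HBD,
  formaldehyde (carbonyl O, no H) for HBA, and a carbocycle for HyP.  Using
  disconnected fragments keeps every planted feature chemically independent,
  which is what makes the matcher/decoy guarantees exact.
* **libraries** — labeled active/decoy sets planted to reproduce requested
  confusion counts (D, A, Ht, Ha) exactly when screened.
* **complexes** — mini receptor pockets of amino-acid fragment mimics with
  contacts planted at specified distances/angles, exact to float precision.

All randomness flows through a counter-based Philox generator keyed by the
caller's seed, so output is byte-identical across platforms and runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .pharmacophore import (
    FeatureSet,
    PharmacophoreModel,
    enumerate_models,
    perceive_complementary_features,
)
from .molecular_io import extract_binding_site
from .screening import LibraryRecord, ScreeningLibrary
from .types import Atom, Molecule3D, ProteinLigandComplex, ResidueId

__all__ = [
    "LibrarySpec",
    "PlantedContact",
    "ComplexSpec",
    "make_matching_ligand",
    "make_decoy_ligand",
    "make_library",
    "make_toy_complex",
    "make_reference_complex",
    "reference_model",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=int(seed) % (2**63)))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


# ---------------------------------------------------------------------------
# fragment templates (local coordinates; the feature-bearing point at origin)
# ---------------------------------------------------------------------------

_TET = math.acos(-1.0 / 3.0)  # tetrahedral angle, 109.47 deg


def _tetrahedral_dirs(u: np.ndarray) -> list[np.ndarray]:
    """Three unit directions at the tetrahedral angle from bond direction u."""
    u = _unit(u)
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = _unit(np.cross(u, ref))
    q = np.cross(u, p)
    out = []
    for phi in (0.0, 2 * math.pi / 3, 4 * math.pi / 3):
        out.append(
            math.cos(_TET) * u + math.sin(_TET) * (math.cos(phi) * p + math.sin(phi) * q)
        )
    return out


def _methyl(center: np.ndarray, toward: np.ndarray, atoms, bonds, parent_idx):
    """Append a CH3 whose C sits at ``center`` bonded toward ``parent_idx``."""
    c_idx = len(atoms)
    atoms.append(("C", center, 0, False))
    bonds.append((parent_idx, c_idx, 1))
    for d in _tetrahedral_dirs(toward):
        h_idx = len(atoms)
        atoms.append(("H", center + 1.09 * d, 0, False))
        bonds.append((c_idx, h_idx, 1))
    return c_idx


def _frag_thiol() -> tuple[list, list]:
    """Methanethiol; S (the HBD anchor) at the origin."""
    atoms = [("S", np.zeros(3), 0, False)]
    bonds: list = []
    c = np.array([1.81, 0.0, 0.0])
    _methyl(c, np.array([1.0, 0.0, 0.0]), atoms, bonds, 0)
    hs = 1.34 * np.array([math.cos(math.radians(96)), math.sin(math.radians(96)), 0.0])
    atoms.append(("H", hs, 0, False))
    bonds.append((0, len(atoms) - 1, 1))
    return atoms, bonds


def _frag_formaldehyde() -> tuple[list, list]:
    """Formaldehyde; carbonyl O (the HBA anchor) at the origin."""
    atoms = [("O", np.zeros(3), 0, False), ("C", np.array([1.21, 0.0, 0.0]), 0, False)]
    bonds = [(0, 1, 2)]
    for sgn in (1.0, -1.0):
        d = np.array([math.cos(math.radians(59)), sgn * math.sin(math.radians(59)), 0.0])
        atoms.append(("H", atoms[1][1] + 1.09 * d, 0, False))
        bonds.append((1, len(atoms) - 1, 1))
    return atoms, bonds


def _frag_benzene() -> tuple[list, list]:
    """Benzene; ring centroid (the HyP anchor) at the origin."""
    atoms = []
    bonds = []
    for k in range(6):
        t = math.radians(60 * k)
        atoms.append(("C", 1.39 * np.array([math.cos(t), math.sin(t), 0.0]), 0, True))
    for k in range(6):
        bonds.append((k, (k + 1) % 6, "ar"))
    for k in range(6):
        t = math.radians(60 * k)
        atoms.append(("H", 2.48 * np.array([math.cos(t), math.sin(t), 0.0]), 0, False))
        bonds.append((k, 6 + k, 1))
    return atoms, bonds


def _frag_cyclopropane() -> tuple[list, list]:
    """Cyclopropane; 3-carbon aliphatic cluster centroid at the origin."""
    atoms = []
    bonds = []
    r = 1.51 / (2 * math.sin(math.pi / 3))
    for k in range(3):
        t = math.radians(120 * k + 90)
        atoms.append(("C", r * np.array([math.cos(t), math.sin(t), 0.0]), 0, False))
    for k in range(3):
        bonds.append((k, (k + 1) % 3, 1))
    for k in range(3):
        t = math.radians(120 * k + 90)
        radial = np.array([math.cos(t), math.sin(t), 0.0])
        for z in (1.0, -1.0):
            d = _unit(0.8 * radial + z * np.array([0.0, 0.0, 1.0]))
            atoms.append(("H", atoms[k][1] + 1.09 * d, 0, False))
            bonds.append((k, len(atoms) - 1, 1))
    return atoms, bonds


def _frag_methane() -> tuple[list, list]:
    """Methane; chemically inert under every perception rule (no cluster)."""
    atoms = [("C", np.zeros(3), 0, False)]
    bonds = []
    for d in np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3):
        atoms.append(("H", 1.09 * d, 0, False))
        bonds.append((0, len(atoms) - 1, 1))
    return atoms, bonds


_KIND_FRAGMENT = {
    "HBD": _frag_thiol,
    "HBA": _frag_formaldehyde,
    "HyP": _frag_cyclopropane,
}


def _assemble(groups: list[tuple[list, list, np.ndarray, np.ndarray]], name: str) -> Molecule3D:
    """Combine (atoms, bonds, rotation, translation) groups into one molecule."""
    all_atoms: list[Atom] = []
    all_bonds: list[tuple[int, int, object]] = []
    for atoms, bonds, rot, trans in groups:
        offset = len(all_atoms)
        for el, pos, charge, aromatic in atoms:
            all_atoms.append(
                Atom(
                    serial=len(all_atoms) + 1,
                    element=el,
                    position=rot @ np.asarray(pos, float) + trans,
                    formal_charge=charge,
                    is_aromatic=aromatic,
                )
            )
        for i, j, order in bonds:
            all_bonds.append((i + offset, j + offset, order))
    return Molecule3D(name, all_atoms, all_bonds)


# ---------------------------------------------------------------------------
# matcher / decoy ligands
# ---------------------------------------------------------------------------

def make_matching_ligand(
    model: PharmacophoreModel, seed: int, jitter: float = 0.0
) -> Molecule3D:
    """A fragment assembly whose perceived features sit on the model's
    centroids, each displaced rigidly by a seeded vector of length
    ``jitter`` Å.  At jitter 0 the ligand matches with RMSD 0."""
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if len(model.features) > 7:
        raise ValueError("models with more than 7 features are unsupported")
    rng = _rng(seed)
    groups = []
    for f in model.features:
        atoms, bonds = _KIND_FRAGMENT[f.kind]()
        rot = _random_rotation(rng)
        shift = jitter * _random_unit(rng)
        groups.append((atoms, bonds, rot, f.centroid + shift))
    return _assemble(groups, f"match_s{seed}")


def make_decoy_ligand(
    model: PharmacophoreModel, seed: int, violation: str = "distance"
) -> Molecule3D:
    """A guaranteed non-matcher.

    ``violation="distance"`` displaces one feature group far enough that
    every pairwise constraint through it breaks by more than 3 Å beyond the
    combined tolerances; ``violation="kind"`` omits every group of one
    required kind (replaced by inert methane), so no kind-complete
    assignment exists.
    """
    rng = _rng(seed)
    n = len(model.features)
    if violation == "distance":
        diam = float(model.distance_matrix.max())
        max_tol = max(f.tolerance for f in model.features)
        shift_len = 2.0 * diam + 2.0 * max_tol + 3.1
        victim = int(rng.integers(n))
        shift_dir = _random_unit(rng)
        groups = []
        for k, f in enumerate(model.features):
            atoms, bonds = _KIND_FRAGMENT[f.kind]()
            rot = _random_rotation(rng)
            trans = f.centroid + (shift_len * shift_dir if k == victim else 0.0)
            groups.append((atoms, bonds, rot, trans))
        return _assemble(groups, f"decoy_d_s{seed}")
    if violation == "kind":
        present = [k for k in ("HBA", "HBD", "HyP") if k in model.kinds]
        omitted = present[0]
        groups = []
        for f in model.features:
            frag = _frag_methane if f.kind == omitted else _KIND_FRAGMENT[f.kind]
            atoms, bonds = frag()
            groups.append((atoms, bonds, _random_rotation(rng), f.centroid.copy()))
        return _assemble(groups, f"decoy_k_s{seed}")
    raise ValueError(f"unknown violation {violation!r}")


# ---------------------------------------------------------------------------
# labeled libraries with planted confusion counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibrarySpec:
    """Planted decoy-set composition: D molecules, A actives, of which
    planted_Ha actives and (planted_Ht - planted_Ha) inactives match."""

    D: int
    A: int
    planted_Ht: int
    planted_Ha: int
    seed: int
    jitter_max: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.A <= self.D):
            raise ValueError("need 0 <= A <= D")
        if not (0 <= self.planted_Ha <= min(self.planted_Ht, self.A)):
            raise ValueError("need 0 <= planted_Ha <= min(planted_Ht, A)")
        if self.planted_Ht > self.D:
            raise ValueError("planted_Ht cannot exceed D")
        if self.planted_Ht - self.planted_Ha > self.D - self.A:
            raise ValueError("more inactive matchers requested than inactives available")


def make_library(model: PharmacophoreModel, spec: LibrarySpec) -> ScreeningLibrary:
    """A labeled library that screens to exactly the planted counts under the
    default matcher tolerances."""
    rng = _rng(spec.seed)
    roles: list[tuple[bool, bool]] = []  # (active, matcher)
    roles += [(True, True)] * spec.planted_Ha
    roles += [(False, True)] * (spec.planted_Ht - spec.planted_Ha)
    roles += [(True, False)] * (spec.A - spec.planted_Ha)
    roles += [(False, False)] * (spec.D - spec.A - (spec.planted_Ht - spec.planted_Ha))
    order = rng.permutation(len(roles))
    records = []
    for pos, idx in enumerate(order):
        active, matcher = roles[idx]
        child_seed = int(rng.integers(2**31 - 1))
        if matcher:
            jitter = float(rng.uniform(0.02, spec.jitter_max))
            mol = make_matching_ligand(model, child_seed, jitter=jitter)
        else:
            violation = "distance" if pos % 2 == 0 else "kind"
            mol = make_decoy_ligand(model, child_seed, violation=violation)
        mol.name = f"mol_{pos + 1:05d}"
        mol.properties["planted_matcher"] = matcher
        records.append(LibraryRecord(molecule=mol, active=active))
    return ScreeningLibrary(records)


# ---------------------------------------------------------------------------
# toy complexes with planted contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedContact:
    """One contact to realize exactly.

    ``distance`` is the category's defining distance (heavy-atom D...A for
    hydrogen bonds unless ``measure="hydrogen"``, centroid-based for the pi
    classes, closest heavy pair otherwise).  ``angle`` is the D-H...A angle
    for hydrogen bonds (degrees, default 180)."""

    category: str
    residue: ResidueId
    distance: float
    angle: Optional[float] = None
    measure: str = "heavy"  # or "hydrogen" (H...acceptor) for hydrogen bonds
    donor_side: str = "receptor"  # hydrogen bonds only

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("planted distance must be > 0")
        if self.measure not in ("heavy", "hydrogen"):
            raise ValueError("measure must be 'heavy' or 'hydrogen'")


@dataclass(frozen=True)
class ComplexSpec:
    contacts: tuple[PlantedContact, ...]
    seed: int = 0
    ligand_scaffold: str = "fragments"
    ring_radius: Optional[float] = None  # override for the placement circle

    def __post_init__(self) -> None:
        object.__setattr__(self, "contacts", tuple(self.contacts))


def _res_atom(el, pos, name, residue: ResidueId, charge=0, aromatic=False) -> Atom:
    return Atom(
        serial=0,
        element=el,
        position=np.asarray(pos, float),
        formal_charge=charge,
        is_aromatic=aromatic,
        residue_name=residue[2],
        residue_number=residue[1],
        chain_id=residue[0] or "A",
        name=name,
    )


def _hbond_geometry(d: float, theta_deg: float, measure: str, bond_len: float = 1.01):
    """Local 1D geometry: acceptor at 0, donor along +x.

    Returns (x_donor, (x_H, y_H)) realizing the D-H...A angle theta and the
    requested distance (heavy D...A or hydrogen H...A)."""
    theta = math.radians(theta_deg)
    b = bond_len
    if measure == "hydrogen":
        ha = d
        xd_sq = b * b + ha * ha - 2 * b * ha * math.cos(theta)
        dheavy = math.sqrt(xd_sq)
    else:
        dheavy = d
        disc = b * b * math.cos(theta) ** 2 - b * b + dheavy * dheavy
        if disc < 0:
            raise ValueError(
                f"hydrogen bond with heavy distance {d} and angle {theta_deg} is infeasible"
            )
        ha = b * math.cos(theta) + math.sqrt(disc)
        if ha <= 0:
            raise ValueError("degenerate hydrogen-bond geometry")
    # H at (ha, 0); donor D placed so that angle(D, H, A) = theta
    hx, hy = ha, 0.0
    dx = hx - b * math.cos(theta)
    dy = b * math.sin(theta)
    # re-express with D on record: |D - A| must equal dheavy (holds by construction)
    return (dx, dy), (hx, hy), dheavy


def make_toy_complex(spec: ComplexSpec) -> ProteinLigandComplex:
    """A mini pocket of residue fragment mimics realizing every planted
    contact exactly; ligand groups carry the complementary chemistry.

    Contact assemblies are spaced on a circle wide enough that no unplanted
    cross-contact falls inside any detection window; a spec that forces
    assemblies closer than 2 Å raises a geometric-infeasibility error.
    """
    n = max(len(spec.contacts), 1)
    radius = spec.ring_radius
    if radius is None:
        radius = max(10.0, 8.0 / (2 * math.sin(math.pi / n)) if n > 1 else 10.0)
    rec_parts: list[list[Atom]] = []
    lig_groups: list[tuple[list, list, np.ndarray, np.ndarray]] = []

    for k, contact in enumerate(spec.contacts):
        theta = 2 * math.pi * k / n
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        v = np.array([-math.sin(theta), math.cos(theta), 0.0])
        w = np.array([0.0, 0.0, 1.0])
        anchor = radius * u
        res = contact.residue
        cat = contact.category
        d = contact.distance
        frame = np.column_stack([u, v, w])  # local x -> u etc.

        if cat == "hydrogen_bond":
            angle = 180.0 if contact.angle is None else contact.angle
            bond_len = 1.01
            (dx, dy), (hx, hy), _ = _hbond_geometry(d, angle, contact.measure, bond_len)
            if contact.donor_side == "receptor":
                # ligand acceptor (formaldehyde O) at anchor; receptor N-H beyond
                a_pos = anchor
                d_pos = anchor + dx * u + dy * v
                h_pos = anchor + hx * u + hy * v
                cap = d_pos + 1.47 * _unit(-0.5 * _unit(h_pos - d_pos) + 0.866 * w)
                part = [
                    _res_atom("N", d_pos, "N", res),
                    _res_atom("H", h_pos, "HN", res),
                    _res_atom("C", cap, "CA", res),
                ]
                for t in _tetrahedral_dirs(cap - d_pos):
                    part.append(_res_atom("H", cap + 1.09 * t, "HA", res))
                rec_parts.append(part)
                fa, fb = _frag_formaldehyde()
                rot = np.column_stack([-u, -v, w])  # C points inward, away from N
                lig_groups.append((fa, fb, rot, a_pos))
            else:
                # ligand O-H at the anchor donates outward to a receptor
                # carbonyl O; local geometry has the acceptor at the origin
                # and the donor at (dx, dy), mapped so the donor sits at the
                # anchor and the acceptor along +u.
                (dx, dy), (hx, hy), dheavy = _hbond_geometry(
                    d, angle, contact.measure, 0.96
                )
                a_pos = anchor + dx * u - dy * v
                h_pos = anchor + (dx - hx) * u - dy * v
                c_pos = a_pos + 1.21 * u
                part = [
                    _res_atom("O", a_pos, "O", res),
                    _res_atom("C", c_pos, "C", res),
                ]
                for sgn in (1.0, -1.0):
                    hdir = _unit(0.515 * u + sgn * 0.857 * v)
                    part.append(_res_atom("H", c_pos + 1.09 * hdir, "HC", res))
                rec_parts.append(part)
                # ligand methanol: O at anchor, H toward the acceptor
                hdir_l = _unit(h_pos - anchor)
                cdir = _unit(-0.326 * hdir_l + 0.946 * w)
                c_pos_l = anchor + 1.41 * cdir
                atoms = [
                    ("O", anchor, 0, False),
                    ("H", h_pos, 0, False),
                    ("C", c_pos_l, 0, False),
                ]
                bonds = [(0, 1, 1), (0, 2, 1)]
                for t in _tetrahedral_dirs(-cdir):
                    atoms.append(("H", c_pos_l + 1.09 * t, 0, False))
                    bonds.append((2, len(atoms) - 1, 1))
                lig_groups.append((atoms, bonds, np.eye(3), np.zeros(3)))

        elif cat in ("pi_pi_stacked", "pi_pi_T", "pi_cation", "pi_sigma", "pi_alkyl"):
            # ligand benzene at the anchor, ring plane spanned by (v, w)
            fa, fb = _frag_benzene()
            ring_frame = np.column_stack([v, w, u])  # ring normal = u
            lig_groups.append((fa, fb, ring_frame, anchor))
            if cat == "pi_pi_stacked":
                c2 = anchor + d * u
                part = _residue_ring(c2, v, w, res)
                rec_parts.append(part)
            elif cat == "pi_pi_T":
                c2 = anchor + d * u
                part = _residue_ring(c2, u, w, res)  # normal = v, perpendicular
                rec_parts.append(part)
            elif cat == "pi_cation":
                npos = anchor + d * u
                part = [_res_atom("N", npos, "NZ", res, charge=1)]
                for t in _tetrahedral_dirs(-u):
                    part.append(_res_atom("H", npos + 1.01 * t, "HZ", res))
                cap = npos + 1.49 * u
                part.append(_res_atom("C", cap, "CE", res))
                for t in _tetrahedral_dirs(u):
                    part.append(_res_atom("H", cap + 1.09 * t, "HE", res))
                rec_parts.append(part)
            elif cat == "pi_sigma":
                # planted distance = H...centroid; C-H points at the centroid
                h_pos = anchor + d * u
                c_pos = anchor + (d + 1.09) * u
                part = [_res_atom("C", c_pos, "CD1", res), _res_atom("H", h_pos, "HD1", res)]
                for t in _tetrahedral_dirs(-u):
                    part.append(_res_atom("H", c_pos + 1.09 * t, "HD", res))
                rec_parts.append(part)
            else:  # pi_alkyl: ethane with C-C axis outward, H's off-axis
                rec_parts.append(_ethane_part(anchor + d * u, u, res))

        elif cat == "alkyl_alkyl":
            # ligand propane apex carbon at the anchor, chain folded inward
            atoms, bonds = _propane_local()
            lig_groups.append((atoms, bonds, np.column_stack([w, v, -u]), anchor))
            rec_parts.append(_ethane_part(anchor + d * u, u, res))

        elif cat == "sulfur_x":
            # receptor thioether S at distance d from a ligand carbonyl O
            fa, fb = _frag_formaldehyde()
            rot = np.column_stack([-u, -v, w])
            lig_groups.append((fa, fb, rot, anchor))
            s_pos = anchor + d * u
            part = [_res_atom("S", s_pos, "SD", res)]
            for sgn, nm in ((1.0, "CG"), (-1.0, "CE")):
                cdir = _unit(0.7 * u + sgn * 0.714 * v)
                cpos = s_pos + 1.81 * cdir
                part.append(_res_atom("C", cpos, nm, res))
                for t in _tetrahedral_dirs(cdir):
                    part.append(_res_atom("H", cpos + 1.09 * t, "H" + nm[-1], res))
            rec_parts.append(part)

        elif cat == "vdw_contact":
            # ligand methanol C at the anchor (O inward), receptor methane
            atoms = [("C", np.zeros(3), 0, False), ("O", np.array([-1.41, 0.0, 0.0]), 0, False)]
            bonds = [(0, 1, 1)]
            oh = np.array([-1.41, 0.0, 0.0]) + 0.96 * _unit(np.array([-0.3, 0.95, 0.0]))
            atoms.append(("H", oh, 0, False))
            bonds.append((1, 2, 1))
            for t in _tetrahedral_dirs(np.array([-1.0, 0.0, 0.0])):
                atoms.append(("H", 1.09 * t, 0, False))
                bonds.append((0, len(atoms) - 1, 1))
            lig_groups.append((atoms, bonds, frame, anchor))
            c_pos = anchor + d * u
            part = [_res_atom("C", c_pos, "CB", res)]
            for t in _tetrahedral_dirs(u) + [u]:
                part.append(_res_atom("H", c_pos + 1.09 * t, "HB", res))
            rec_parts.append(part)
        else:
            raise ValueError(f"unknown planted category {cat!r}")

    if not spec.contacts:
        # an empty pocket: one remote glycine-like fragment and a methane ligand
        res = ("A", 1, "GLY")
        rec_parts.append([
            _res_atom("C", np.array([30.0, 0.0, 0.0]), "CA", res),
            _res_atom("H", np.array([30.0, 1.09, 0.0]), "HA", res),
        ])
        fa, fb = _frag_methane()
        lig_groups.append((fa, fb, np.eye(3), np.zeros(3)))

    ligand = _assemble(lig_groups, f"toylig_s{spec.seed}")
    for a in ligand.atoms:
        a.name = f"{a.element}{a.serial}"
    rec_atoms: list[Atom] = []
    for part in rec_parts:
        for a in part:
            a.serial = len(rec_atoms) + 1
            rec_atoms.append(a)
    receptor = Molecule3D("toy_pocket", rec_atoms, _residue_bonds(rec_atoms))
    _check_clashes(spec, rec_parts, lig_groups, ligand)
    return ProteinLigandComplex(receptor=receptor, ligand=ligand)


def _ethane_part(c1: np.ndarray, u: np.ndarray, res: ResidueId) -> list[Atom]:
    """An ethane residue mimic: C1 at ``c1``, C2 farther out along ``u``."""
    c2 = c1 + 1.53 * u
    part = [_res_atom("C", c1, "CD1", res), _res_atom("C", c2, "CD2", res)]
    for t in _tetrahedral_dirs(u):
        part.append(_res_atom("H", c1 + 1.09 * t, "HD1", res))
    for t in _tetrahedral_dirs(-u):
        part.append(_res_atom("H", c2 + 1.09 * t, "HD2", res))
    return part


def _propane_local() -> tuple[list, list]:
    """Propane with the apex (C2) carbon at the origin, C1/C3 along +x."""
    c2 = np.zeros(3)
    c1 = np.array([1.26, -0.868, 0.0])
    c3 = np.array([1.26, 0.868, 0.0])
    atoms = [("C", c2, 0, False), ("C", c1, 0, False), ("C", c3, 0, False)]
    bonds = [(0, 1, 1), (0, 2, 1)]
    for idx, center, toward in ((1, c1, c1 - c2), (2, c3, c3 - c2)):
        for t in _tetrahedral_dirs(toward):
            atoms.append(("H", center + 1.09 * t, 0, False))
            bonds.append((idx, len(atoms) - 1, 1))
    for z in (1.0, -1.0):
        d = _unit(np.array([-0.85, 0.0, z]))
        atoms.append(("H", c2 + 1.09 * d, 0, False))
        bonds.append((0, len(atoms) - 1, 1))
    return atoms, bonds


def _residue_ring(centroid, e1, e2, res: ResidueId) -> list[Atom]:
    """An aromatic 6-ring residue mimic in the plane spanned by (e1, e2)."""
    part = []
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    for k in range(6):
        t = math.radians(60 * k)
        pos = centroid + 1.39 * (math.cos(t) * e1 + math.sin(t) * e2)
        part.append(_res_atom("C", pos, names[k], res, aromatic=True))
    for k in range(6):
        t = math.radians(60 * k)
        pos = centroid + 2.48 * (math.cos(t) * e1 + math.sin(t) * e2)
        part.append(_res_atom("H", pos, "H" + names[k][1:], res))
    return part


def _residue_bonds(atoms: list[Atom]) -> list[tuple[int, int, object]]:
    """Distance-based bonds within each residue (fragments are small)."""
    from .molecular_io import _infer_bonds

    bonds = []
    by_res: dict[ResidueId, list[int]] = {}
    for i, a in enumerate(atoms):
        by_res.setdefault(a.residue_id, []).append(i)
    for idxs in by_res.values():
        sub = [atoms[i] for i in idxs]
        for i, j, order in _infer_bonds(sub):
            bonds.append((idxs[i], idxs[j], order))
    return bonds


def _check_clashes(spec, rec_parts, lig_groups, ligand) -> None:
    """Assemblies from different contacts must stay >= 2 Å apart."""
    assemblies = []
    cursor = 0
    for k, (atoms, _, rot, trans) in enumerate(lig_groups):
        pts = [rot @ np.asarray(p, float) + trans for _, p, _, _ in atoms]
        assemblies.append((k, pts))
    for k, part in enumerate(rec_parts):
        assemblies.append((k, [a.position for a in part]))
    for (k1, pts1), (k2, pts2) in (
        (a, b) for i, a in enumerate(assemblies) for b in assemblies[i + 1 :]
    ):
        if k1 == k2:
            continue
        for p in pts1:
            for q in pts2:
                if np.linalg.norm(p - q) < 2.0:
                    raise ValueError(
                        "geometrically infeasible contact spec: assemblies "
                        f"{k1} and {k2} clash (< 2 Å); widen ring_radius or drop contacts"
                    )


# ---------------------------------------------------------------------------
# the reference pocket and its pharmacophore model
# ---------------------------------------------------------------------------

def make_reference_complex() -> ProteinLigandComplex:
    """A VEGFR-2-like mini pocket: Glu885 side-chain carbonyl (OE2 acceptor),
    Glu917 backbone carbonyl (O acceptor), Cys919 backbone amide (N-H donor)
    and two leucine side-chain clusters, arranged around a small aromatic
    ligand.  Its complementary features reproduce the
    2xHBD / 1xHBA / 2xHyP composition of a hinge/back-pocket model."""
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    parts: list[list[Atom]] = []

    def carbonyl(o_pos, u, res, o_name, c_name, cap_name):
        c = o_pos + 1.23 * u
        cap = c + 1.52 * _unit(0.5 * u + 0.866 * ez)
        part = [
            _res_atom("O", o_pos, o_name, res),
            _res_atom("C", c, c_name, res),
            _res_atom("C", cap, cap_name, res),
        ]
        for t in _tetrahedral_dirs(cap - c):
            part.append(_res_atom("H", cap + 1.09 * t, "H" + cap_name, res))
        return part

    parts.append(carbonyl(5.0 * ex, ex, ("A", 885, "GLU"), "OE2", "CD", "CG"))
    parts.append(carbonyl(5.0 * ey, ey, ("A", 917, "GLU"), "O", "C", "CA"))

    res = ("A", 919, "CYS")
    n_pos = 5.0 * ez
    h_pos = n_pos - 1.01 * ez
    cap = n_pos + 1.47 * _unit(0.5 * ez + 0.866 * ex)
    cys = [
        _res_atom("N", n_pos, "N", res),
        _res_atom("H", h_pos, "HN", res),
        _res_atom("C", cap, "CA", res),
    ]
    for t in _tetrahedral_dirs(cap - n_pos):
        cys.append(_res_atom("H", cap + 1.09 * t, "HA", res))
    parts.append(cys)

    def leu_cluster(center, res):
        cg = center
        cb = cg + 1.53 * ez
        cd1 = cg + 1.53 * _unit(ey + 0.3 * ez) if res[1] == 1035 else cg + 1.53 * _unit(ex + 0.3 * ez)
        cd2 = cg + 1.53 * _unit(-ey + 0.3 * ez) if res[1] == 1035 else cg + 1.53 * _unit(-ex + 0.3 * ez)
        part = [
            _res_atom("C", cb, "CB", res),
            _res_atom("C", cg, "CG", res),
            _res_atom("C", cd1, "CD1", res),
            _res_atom("C", cd2, "CD2", res),
        ]
        for c, nm in ((cb, "HB"), (cd1, "HD1"), (cd2, "HD2")):
            for t in _tetrahedral_dirs(c - cg):
                part.append(_res_atom("H", c + 1.09 * t, nm, res))
        return part

    parts.append(leu_cluster(-6.0 * ex, ("A", 1035, "LEU")))
    parts.append(leu_cluster(-6.0 * ey, ("A", 889, "LEU")))

    rec_atoms: list[Atom] = []
    for part in parts:
        for a in part:
            a.serial = len(rec_atoms) + 1
            rec_atoms.append(a)
    receptor = Molecule3D("vegfr2_mimic", rec_atoms, _residue_bonds(rec_atoms))

    fa, fb = _frag_benzene()
    groups = [(fa, fb, np.eye(3), np.zeros(3))]
    ma, mb = _frag_methane()
    groups.append((ma, mb, np.eye(3), 2.6 * ez))
    ligand = _assemble(groups, "reference_ligand")
    for a in ligand.atoms:
        a.name = f"{a.element}{a.serial}"
    return ProteinLigandComplex(receptor=receptor, ligand=ligand)


def reference_model(
    min_n: int = 4, max_n: int = 5, radius: float = 10.0
) -> PharmacophoreModel:
    """The top-ranked model perceived from the reference pocket (five
    features: HBD, HBD, HBA, HyP, HyP)."""
    cx = make_reference_complex()
    site = extract_binding_site(cx, radius=radius)
    fs = perceive_complementary_features(cx, site)
    models = enumerate_models(fs, min_n, max_n, provenance="reference VEGFR-2-like pocket")
    if not models:
        raise RuntimeError("reference pocket produced no models")
    return models[0]
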