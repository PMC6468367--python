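"""Geometric protein-ligand contact detection and type-II classification.

Contacts are classified into the taxonomy used in kinase-inhibitor
interaction tables: hydrogen bonds, the aromatic-ring-mediated classes
(pi-pi stacked, pi-pi T-shaped, pi-cation, pi-sigma, pi-alkyl), alkyl-alkyl
hydrophobic contacts, sulfur-X contacts and residual van der Waals contacts.
Default distance windows (configurable) bracket the ranges reported for
docked type-II VEGFR-2 inhibitor poses:

===============  =======================================  ==========
category         geometric rule                           default
===============  =======================================  ==========
hydrogen_bond    donor-acceptor heavy distance; D-H...A   < 3.0 Å,
                 angle when H is explicit                 >= 120 deg
pi_pi_stacked    ring centroid distance, interplanar      <= 5.5 Å,
                 angle <= 30 deg                          (folded)
pi_pi_T          centroid distance, angle 60-120 deg      <= 6.0 Å
pi_cation        cation to ring centroid                  <= 6.0 Å
pi_sigma         sp3 C-H hydrogen pointing at the ring    H..centroid
                 (C->H within 30 deg of C->centroid)      <= 4.0 Å
pi_alkyl         sp3 carbon (or Cys/Met sulfur) to ring   <= 5.5 Å
alkyl_alkyl      sp3 carbon - sp3 carbon                  <= 5.5 Å
sulfur_x         divalent S to electron-rich N/O/S        <= 3.6 Å
vdw_contact      any heavy-heavy, residues without        <= 4.0 Å
                 another record only
===============  =======================================  ==========

Category assignment is mutually exclusive per (receptor unit, ligand unit)
pair with precedence hydrogen_bond > pi-pi stacked > pi-pi T > pi-cation >
pi-sigma > pi-alkyl > alkyl-alkyl > sulfur-X > vdW.  The type-II verdict is
positive when hydrogen bonds reach both the front pocket (hinge; Glu917 and
Cys919 in VEGFR-2) and the back pocket (allosteric; Glu885 and Asp1046) —
the back-to-front binding mode characteristic of type-II inhibitors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .pharmacophore import _aliphatic_clusters, _donor_acceptor_atoms, aromatic_rings
from .types import (
    Molecule3D,
    PocketDefinition,
    ProteinLigandComplex,
    ResidueId,
    residue_in_set,
)

__all__ = [
    "CATEGORIES",
    "InteractionCutoffs",
    "InteractionRecord",
    "TypeIIVerdict",
    "detect_hbonds",
    "detect_pi_interactions",
    "detect_vdw_contacts",
    "classify_type2",
    "interaction_table",
]

CATEGORIES = (
    "hydrogen_bond",
    "pi_pi_stacked",
    "pi_pi_T",
    "pi_cation",
    "pi_sigma",
    "pi_alkyl",
    "alkyl_alkyl",
    "sulfur_x",
    "vdw_contact",
)


@dataclass(frozen=True)
class InteractionCutoffs:
    """Distance/angle windows in Å and degrees; see the module table."""

    hbond_heavy: float = 3.0
    hbond_angle_min: float = 120.0
    pi_stack_dist: float = 5.5
    pi_stack_angle: float = 30.0
    pi_t_dist: float = 6.0
    pi_t_angle: tuple[float, float] = (60.0, 120.0)
    pi_cation_dist: float = 6.0
    pi_sigma_dist: float = 4.0
    pi_sigma_angle: float = 30.0
    pi_alkyl_dist: float = 5.5
    alkyl_dist: float = 5.5
    sulfur_x_dist: float = 3.6
    vdw_dist: float = 4.0

    def window(self, category: str) -> tuple[float, float]:
        """Accepted distance window (lo, hi) for a category."""
        hi = {
            "hydrogen_bond": self.hbond_heavy,
            "pi_pi_stacked": self.pi_stack_dist,
            "pi_pi_T": self.pi_t_dist,
            "pi_cation": self.pi_cation_dist,
            "pi_sigma": self.pi_sigma_dist,
            "pi_alkyl": self.pi_alkyl_dist,
            "alkyl_alkyl": self.alkyl_dist,
            "sulfur_x": self.sulfur_x_dist,
            "vdw_contact": self.vdw_dist,
        }[category]
        return (0.0, hi)


@dataclass
class InteractionRecord:
    category: str
    residue: ResidueId
    receptor_atom: str
    ligand_atom: str
    distance: float
    angle: Optional[float] = None
    donor_side: str = "n/a"  # receptor | ligand | n/a
    h_distance: Optional[float] = None  # H...acceptor distance for H-bonds

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown interaction category {self.category!r}")
        if self.distance <= 0:
            raise ValueError("interaction distance must be > 0")
        if self.category == "hydrogen_bond" and self.donor_side == "n/a":
            raise ValueError("hydrogen bonds must state the donor side")

    def partner_label(self) -> str:
        """Table-style label, e.g. ``Glu885:OE2-H40 (2.1)``."""
        d = self.h_distance if self.h_distance is not None else self.distance
        return f"{self.receptor_atom}-{self.ligand_atom} ({d:.1f})"


@dataclass
class TypeIIVerdict:
    front_hbonds: list[InteractionRecord]
    back_hbonds: list[InteractionRecord]
    is_back_to_front: bool

    def __post_init__(self) -> None:
        expected = bool(self.front_hbonds) and bool(self.back_hbonds)
        if self.is_back_to_front != expected:
            raise ValueError("is_back_to_front must mirror front/back evidence")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ring_centroid_normal(mol: Molecule3D, ring: tuple[int, ...]):
    pts = np.array([mol.atoms[i].position for i in ring])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    return centroid, vt[-1]  # smallest singular direction = plane normal


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between ring planes folded to [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def _fold_t_angle(angle_window: tuple[float, float]) -> tuple[float, float]:
    lo, hi = angle_window
    return lo, min(hi, 180.0 - lo) if hi > 90 else hi


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(
    complex_: ProteinLigandComplex,
    heavy_cutoff: float = 3.0,
    angle_min: float = 120.0,
) -> list[InteractionRecord]:
    """Donor-acceptor pairs with heavy-atom distance < ``heavy_cutoff``.

    When the donor hydrogen is explicit the D-H...A angle must be at least
    ``angle_min`` degrees and the record also carries the H...A distance.
    """
    rec, lig = complex_.receptor, complex_.ligand
    rec_don, rec_acc = _donor_acceptor_atoms(rec, require_h=False)
    lig_don, lig_acc = _donor_acceptor_atoms(lig, require_h=False)
    records: list[InteractionRecord] = []

    def scan(donors, dmol, acceptors, amol, donor_side):
        for d_idx, h_idxs in donors:
            d_pos = dmol.atoms[d_idx].position
            for a_idx in acceptors:
                a_pos = amol.atoms[a_idx].position
                dist = float(np.linalg.norm(d_pos - a_pos))
                if dist >= heavy_cutoff or dist < 1e-6:
                    continue
                angle = None
                h_dist = None
                if h_idxs:
                    best = None
                    for h in h_idxs:
                        h_pos = dmol.atoms[h].position
                        ang = _angle_deg(d_pos - h_pos, a_pos - h_pos)
                        if best is None or ang > best[0]:
                            best = (ang, float(np.linalg.norm(h_pos - a_pos)))
                    angle, h_dist = best
                    if angle < angle_min:
                        continue
                r_atom = dmol.atoms[d_idx] if donor_side == "receptor" else amol.atoms[a_idx]
                l_atom = amol.atoms[a_idx] if donor_side == "receptor" else dmol.atoms[d_idx]
                records.append(
                    InteractionRecord(
                        category="hydrogen_bond",
                        residue=r_atom.residue_id,
                        receptor_atom=r_atom.label(),
                        ligand_atom=l_atom.name or f"{l_atom.element}{l_atom.serial}",
                        distance=dist,
                        angle=angle,
                        donor_side=donor_side,
                        h_distance=h_dist,
                    )
                )

    scan(rec_don, rec, lig_acc, lig, "receptor")
    scan(lig_don, lig, rec_acc, rec, "ligand")
    return records


def _hbond_claims(
    complex_: ProteinLigandComplex, records: Iterable[InteractionRecord]
) -> set:
    """(receptor atom serial, ligand atom serial) pairs engaged in H-bonds,
    reconstructed geometrically from the record labels."""
    claims = set()
    rec, lig = complex_.receptor, complex_.ligand
    for r in records:
        if r.category != "hydrogen_bond":
            continue
        for ra in rec.atoms:
            if ra.residue_id == r.residue and ra.label() == r.receptor_atom:
                for la in lig.atoms:
                    if (la.name or f"{la.element}{la.serial}") == r.ligand_atom:
                        claims.add((("Ratom", ra.serial), ("Latom", la.serial)))
    return claims


# ---------------------------------------------------------------------------
# pi / hydrophobic / sulfur classes
# ---------------------------------------------------------------------------

def detect_pi_interactions(
    complex_: ProteinLigandComplex,
    cutoffs: InteractionCutoffs = InteractionCutoffs(),
    claimed: Optional[set] = None,
) -> list[InteractionRecord]:
    """Ring-mediated, alkyl-alkyl and sulfur-X contacts.

    ``claimed`` holds (receptor unit, ligand unit) pair keys already assigned
    to a higher-precedence category (hydrogen bonds); pairs found here claim
    their keys in turn, enforcing one category per pair.
    """
    claimed = set() if claimed is None else set(claimed)
    rec, lig = complex_.receptor, complex_.ligand
    rec_rings = aromatic_rings(rec)
    lig_rings = aromatic_rings(lig)
    rec_adj, lig_adj = rec.neighbors(), lig.neighbors()
    records: list[InteractionRecord] = []

    def ring_info(mol, ring):
        return _ring_centroid_normal(mol, ring)

    def atom_label(mol, i, side):
        a = mol.atoms[i]
        return a.label() if side == "R" else (a.name or f"{a.element}{a.serial}")

    def add(category, residue, r_label, l_label, dist, angle, key):
        if key in claimed:
            return
        claimed.add(key)
        records.append(
            InteractionRecord(
                category=category,
                residue=residue,
                receptor_atom=r_label,
                ligand_atom=l_label,
                distance=dist,
                angle=angle,
            )
        )

    def ring_label(mol, ring, side):
        if side == "R":
            a = mol.atoms[ring[0]]
            return f"{a.residue_name.capitalize()}{a.residue_number}:ring"
        return f"ring[{'-'.join(str(i + 1) for i in ring)}]"

    # ---- pi-pi (stacked then T-shaped) ------------------------------------
    t_lo, t_hi = _fold_t_angle(cutoffs.pi_t_angle)
    for rr in rec_rings:
        rc, rn = ring_info(rec, rr)
        r_res = rec.atoms[rr[0]].residue_id
        for lr in lig_rings:
            lc, ln = ring_info(lig, lr)
            d = float(np.linalg.norm(rc - lc))
            ang = _interplanar_angle(rn, ln)
            key = (("Rring", rr), ("Lring", lr))
            if d <= cutoffs.pi_stack_dist and ang <= cutoffs.pi_stack_angle:
                add("pi_pi_stacked", r_res, ring_label(rec, rr, "R"),
                    ring_label(lig, lr, "L"), d, ang, key)
            elif d <= cutoffs.pi_t_dist and t_lo <= ang <= t_hi:
                add("pi_pi_T", r_res, ring_label(rec, rr, "R"),
                    ring_label(lig, lr, "L"), d, ang, key)

    # ---- pi-cation ---------------------------------------------------------
    def cations(mol):
        return [i for i, a in enumerate(mol.atoms) if a.formal_charge > 0]

    for rr in rec_rings:
        rc, _ = ring_info(rec, rr)
        for ci in cations(lig):
            d = float(np.linalg.norm(rc - lig.atoms[ci].position))
            if d <= cutoffs.pi_cation_dist:
                add("pi_cation", rec.atoms[rr[0]].residue_id,
                    ring_label(rec, rr, "R"), atom_label(lig, ci, "L"), d, None,
                    (("Rring", rr), ("Latom", lig.atoms[ci].serial)))
    for lr in lig_rings:
        lc, _ = ring_info(lig, lr)
        for ci in cations(rec):
            d = float(np.linalg.norm(lc - rec.atoms[ci].position))
            if d <= cutoffs.pi_cation_dist:
                add("pi_cation", rec.atoms[ci].residue_id,
                    atom_label(rec, ci, "R"), ring_label(lig, lr, "L"), d, None,
                    (("Ratom", rec.atoms[ci].serial), ("Lring", lr)))

    # ---- pi-sigma ----------------------------------------------------------
    def sigma_partners(mol, adj):
        out = []
        for i in range(len(mol.atoms)):
            if mol.is_sp3_carbon(i, adj):
                hs = [j for j in adj[i] if mol.atoms[j].element.upper() == "H"]
                if hs:
                    out.append((i, hs))
        return out

    def scan_sigma(rings, ring_mol, ring_side, partners, p_mol, p_adj):
        for ring in rings:
            c, _ = ring_info(ring_mol, ring)
            for ci, hs in partners:
                cpos = p_mol.atoms[ci].position
                best = None
                for h in hs:
                    hpos = p_mol.atoms[h].position
                    ang = _angle_deg(hpos - cpos, c - cpos)
                    dh = float(np.linalg.norm(hpos - c))
                    if ang <= cutoffs.pi_sigma_angle and dh <= cutoffs.pi_sigma_dist:
                        if best is None or dh < best:
                            best = dh
                if best is None:
                    continue
                if ring_side == "R":
                    key = (("Rring", ring), ("Latom", p_mol.atoms[ci].serial))
                    add("pi_sigma", ring_mol.atoms[ring[0]].residue_id,
                        ring_label(ring_mol, ring, "R"), atom_label(p_mol, ci, "L"),
                        best, None, key)
                else:
                    key = (("Ratom", p_mol.atoms[ci].serial), ("Lring", ring))
                    add("pi_sigma", p_mol.atoms[ci].residue_id,
                        atom_label(p_mol, ci, "R"), ring_label(ring_mol, ring, "L"),
                        best, None, key)

    scan_sigma(rec_rings, rec, "R", sigma_partners(lig, lig_adj), lig, lig_adj)
    scan_sigma(lig_rings, lig, "L", sigma_partners(rec, rec_adj), rec, rec_adj)

    # ---- pi-alkyl (aggregated per residue/cluster) -------------------------
    def rec_alkyl_by_residue():
        groups: dict[ResidueId, list[int]] = {}
        for i, a in enumerate(rec.atoms):
            is_cysmet_s = (
                a.element.upper() == "S" and a.residue_name.upper() in ("CYS", "MET")
            )
            if rec.is_alkyl_carbon(i, rec_adj) or is_cysmet_s:
                groups.setdefault(a.residue_id, []).append(i)
        return groups

    lig_clusters = _aliphatic_clusters(lig, min_size=1)

    for lr in lig_rings:
        lc, _ = ring_info(lig, lr)
        for res_id, idxs in rec_alkyl_by_residue().items():
            pairs = [
                (float(np.linalg.norm(rec.atoms[i].position - lc)), i)
                for i in idxs
                if (("Ratom", rec.atoms[i].serial), ("Lring", lr)) not in claimed
            ]
            pairs = [p for p in pairs if p[0] <= cutoffs.pi_alkyl_dist]
            if not pairs:
                continue
            d, i = min(pairs)
            add("pi_alkyl", res_id, atom_label(rec, i, "R"),
                ring_label(lig, lr, "L"), d, None,
                (("Rres", res_id), ("Lring", lr)))
    for rr in rec_rings:
        rc, _ = ring_info(rec, rr)
        for cluster in lig_clusters:
            pairs = [
                (float(np.linalg.norm(lig.atoms[i].position - rc)), i)
                for i in cluster
                if (("Rring", rr), ("Latom", lig.atoms[i].serial)) not in claimed
            ]
            pairs = [p for p in pairs if p[0] <= cutoffs.pi_alkyl_dist]
            if not pairs:
                continue
            d, i = min(pairs)
            add("pi_alkyl", rec.atoms[rr[0]].residue_id,
                ring_label(rec, rr, "R"), atom_label(lig, i, "L"), d, None,
                (("Rring", rr), ("Lclust", cluster)))

    # ---- alkyl-alkyl -------------------------------------------------------
    for res_id, idxs in rec_alkyl_by_residue().items():
        for cluster in lig_clusters:
            best = None
            for i in idxs:
                for j in cluster:
                    d = float(np.linalg.norm(rec.atoms[i].position - lig.atoms[j].position))
                    if d <= cutoffs.alkyl_dist and (best is None or d < best[0]):
                        best = (d, i, j)
            if best is None:
                continue
            d, i, j = best
            add("alkyl_alkyl", res_id, atom_label(rec, i, "R"),
                atom_label(lig, j, "L"), d, None, (("Rres", res_id), ("Lclust", cluster)))

    # ---- sulfur-X ----------------------------------------------------------
    def divalent_s(mol, adj):
        return [
            i
            for i, a in enumerate(mol.atoms)
            if a.element.upper() == "S" and len(adj[i]) == 2
        ]

    def electron_rich(mol):
        return [i for i, a in enumerate(mol.atoms) if a.element.upper() in ("N", "O", "S")]

    for si in divalent_s(rec, rec_adj):
        for xi in electron_rich(lig):
            d = float(np.linalg.norm(rec.atoms[si].position - lig.atoms[xi].position))
            key = (("Ratom", rec.atoms[si].serial), ("Latom", lig.atoms[xi].serial))
            if d <= cutoffs.sulfur_x_dist:
                add("sulfur_x", rec.atoms[si].residue_id, atom_label(rec, si, "R"),
                    atom_label(lig, xi, "L"), d, None, key)
    for si in divalent_s(lig, lig_adj):
        for xi in electron_rich(rec):
            d = float(np.linalg.norm(lig.atoms[si].position - rec.atoms[xi].position))
            key = (("Ratom", rec.atoms[xi].serial), ("Latom", lig.atoms[si].serial))
            if d <= cutoffs.sulfur_x_dist:
                add("sulfur_x", rec.atoms[xi].residue_id, atom_label(rec, xi, "R"),
                    atom_label(lig, si, "L"), d, None, key)

    return records


# ---------------------------------------------------------------------------
# van der Waals contacts
# ---------------------------------------------------------------------------

def detect_vdw_contacts(
    complex_: ProteinLigandComplex,
    cutoff: float = 4.0,
    exclude_residues: Iterable[ResidueId] = (),
) -> list[InteractionRecord]:
    """Residues with any heavy atom within ``cutoff`` Å of a ligand heavy
    atom, excluding residues already carrying another interaction record."""
    rec, lig = complex_.receptor, complex_.ligand
    excluded = set(exclude_residues)
    lig_heavy = lig.heavy_indices()
    lig_xyz = np.array([lig.atoms[i].position for i in lig_heavy])
    best: dict[ResidueId, tuple[float, int, int]] = {}
    for i in rec.heavy_indices():
        a = rec.atoms[i]
        if a.residue_id in excluded:
            continue
        d = np.linalg.norm(lig_xyz - a.position, axis=1)
        k = int(d.argmin())
        if d[k] <= cutoff:
            cur = best.get(a.residue_id)
            if cur is None or d[k] < cur[0]:
                best[a.residue_id] = (float(d[k]), i, lig_heavy[k])
    records = []
    for res_id in sorted(best, key=lambda r: (r[0], r[1], r[2])):
        dist, i, j = best[res_id]
        la = lig.atoms[j]
        records.append(
            InteractionRecord(
                category="vdw_contact",
                residue=res_id,
                receptor_atom=rec.atoms[i].label(),
                ligand_atom=la.name or f"{la.element}{la.serial}",
                distance=dist,
            )
        )
    return records


# ---------------------------------------------------------------------------
# type-II verdict and the combined table
# ---------------------------------------------------------------------------

def classify_type2(
    records: Iterable[InteractionRecord], pocket: PocketDefinition
) -> TypeIIVerdict:
    """Partition hydrogen bonds into front- and back-pocket evidence; the
    back-to-front verdict requires at least one bond in each."""
    if not pocket.front_residues or not pocket.back_residues:
        raise ValueError("pocket must define nonempty front and back residue sets")
    front, back = [], []
    for r in records:
        if r.category != "hydrogen_bond":
            continue
        if residue_in_set(r.residue, pocket.front_residues):
            front.append(r)
        elif residue_in_set(r.residue, pocket.back_residues):
            back.append(r)
    return TypeIIVerdict(
        front_hbonds=front,
        back_hbonds=back,
        is_back_to_front=bool(front) and bool(back),
    )


def interaction_table(
    complex_: ProteinLigandComplex,
    pocket: PocketDefinition,
    cutoffs: InteractionCutoffs = InteractionCutoffs(),
    distance_convention: str = "hydrogen",
) -> dict:
    """One structured row per complex: hydrogen bonds with distances, the
    pi/alkyl partner residues, the vdW partner residues and the type-II
    verdict.  ``distance_convention`` picks which distance the H-bond labels
    print when both are known ("hydrogen" = H...acceptor, "heavy" = D...A);
    records always carry both.
    """
    hbonds = detect_hbonds(
        complex_, heavy_cutoff=cutoffs.hbond_heavy, angle_min=cutoffs.hbond_angle_min
    )
    claims = _hbond_claims(complex_, hbonds)
    pis = detect_pi_interactions(complex_, cutoffs=cutoffs, claimed=claims)
    engaged = {r.residue for r in hbonds} | {r.residue for r in pis}
    vdw = detect_vdw_contacts(complex_, cutoff=cutoffs.vdw_dist, exclude_residues=engaged)
    verdict = classify_type2(hbonds, pocket)

    def hb_label(r: InteractionRecord) -> str:
        d = r.distance
        if distance_convention == "hydrogen" and r.h_distance is not None:
            d = r.h_distance
        return f"{r.receptor_atom}-{r.ligand_atom} ({d:.1f})"

    def res_label(res: ResidueId) -> str:
        return f"{res[2].capitalize()}{res[1]}"

    return {
        "compound": complex_.ligand.name,
        "hydrogen_bonds": [hb_label(r) for r in hbonds],
        "pi_hydrophobic": sorted({res_label(r.residue) for r in pis}),
        "vdw": sorted({res_label(r.residue) for r in vdw}),
        "n_hbonds": len(hbonds),
        "n_pi_hydrophobic": len(pis),
        "n_vdw": len(vdw),
        "is_back_to_front": verdict.is_back_to_front,
        "records": hbonds + pis + vdw,
        "verdict": verdict,
    }
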