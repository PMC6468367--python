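"""Pharmacophore feature perception and model building.

A pharmacophore is an abstract 3D arrangement of chemical features — hydrogen
bond donors (HBD), acceptors (HBA) and hydrophobes (HyP) — required for
binding.  Models are perceived either from a ligand directly or as
*complementary* features inside a receptor binding site: a receptor acceptor
implies a donor feature on the ligand side, and vice versa, which is how a
structure-based model is derived from a protein-ligand complex.

Perception chemistry (documented, fixed):

* HBD — any N/O/S atom bearing an explicit hydrogen; feature centred on the
  heavy atom.
* HBA — any N or O with an available lone pair: formal charge <= 0, excluding
  amide-type nitrogens (N bonded to a carbonyl carbon) and 3-coordinate
  aromatic nitrogens (pyrrole type).
* HyP — centroid of each aromatic ring, and centroid of each connected
  cluster of >= 3 aliphatic carbons with no hetero-atom substituent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .types import Atom, Molecule3D, PocketDefinition, ProteinLigandComplex, residue_in_set

__all__ = [
    "FEATURE_KINDS",
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "FeatureSet",
    "perceive_ligand_features",
    "perceive_complementary_features",
    "enumerate_models",
    "selectivity_score",
    "aromatic_rings",
]

FEATURE_KINDS = ("HBD", "HBA", "HyP")

#: default feature sphere radii, Å
DEFAULT_TOLERANCE = {"HBD": 1.6, "HBA": 1.6, "HyP": 1.7}

#: kind rarity priors used by the selectivity heuristic
KIND_PRIOR = {"HBD": 2.0, "HBA": 2.0, "HyP": 1.5}

#: minimum inter-feature spacing accepted when enumerating models, Å
MIN_FEATURE_SPACING = 2.0

#: ideal heavy-atom hydrogen-bond length used to project complementary
#: features from the receptor onto the ligand side, Å
HBOND_PROJECTION = 2.9

#: receptor polar atoms farther than this from every ligand atom are not
#: considered to face the ligand, Å
FACING_CUTOFF = 6.0

#: maximum RMS out-of-plane deviation for a ring to count as aromatic, Å
RING_PLANARITY_RMS = 0.1

_HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "CYS"}


class MissingHydrogensError(ValueError):
    """Donor perception requires explicit hydrogens (or the infer flag)."""


@dataclass
class PharmacophoreFeature:
    """One chemical feature: a sphere of ``tolerance`` Å around ``centroid``.

    ``projection`` (HBD/HBA only) is the hydrogen-bond partner direction
    target, e.g. the receptor acceptor atom a ligand donor should reach.
    """

    kind: str
    centroid: np.ndarray
    tolerance: float
    projection: Optional[np.ndarray] = None
    source_atoms: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be > 0")
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.projection is not None:
            if self.kind == "HyP":
                raise ValueError("projection is only defined for HBD/HBA features")
            self.projection = np.asarray(self.projection, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PharmacophoreFeature":
        proj = None if self.projection is None else rotation @ self.projection + translation
        return PharmacophoreFeature(
            self.kind, rotation @ self.centroid + translation, self.tolerance, proj, self.source_atoms
        )


@dataclass
class PharmacophoreModel:
    """An ordered feature set with its inter-feature distance matrix."""

    features: list[PharmacophoreFeature]
    distance_matrix: np.ndarray = None  # type: ignore[assignment]
    selectivity: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        n = len(self.features)
        if not (3 <= n <= 7):
            raise ValueError(f"a pharmacophore model needs 3-7 features, got {n}")
        pts = np.array([f.centroid for f in self.features])
        computed = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        if self.distance_matrix is None:
            self.distance_matrix = computed
        else:
            self.distance_matrix = np.asarray(self.distance_matrix, dtype=float)
            if self.distance_matrix.shape != (n, n):
                raise ValueError("distance matrix shape mismatch")
            if not np.allclose(self.distance_matrix, self.distance_matrix.T, atol=1e-9):
                raise ValueError("distance matrix must be symmetric")
            if not np.allclose(np.diag(self.distance_matrix), 0.0, atol=1e-9):
                raise ValueError("distance matrix diagonal must be zero")
        d = self.distance_matrix
        for i, j, k in itertools.permutations(range(n), 3):
            if d[i, j] > d[i, k] + d[k, j] + 1e-6:
                raise ValueError("distance matrix violates the triangle inequality")

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(f.kind for f in self.features)

    def mean_tolerance(self) -> float:
        return float(np.mean([f.tolerance for f in self.features]))


@dataclass
class FeatureSet:
    """Perceived features of one molecule, each citing its source atoms."""

    owner: str
    features: list[PharmacophoreFeature] = field(default_factory=list)
    n_atoms: int = 0

    def __post_init__(self) -> None:
        for f in self.features:
            if not f.source_atoms:
                raise ValueError("every perceived feature must cite >= 1 source atom")
            if self.n_atoms and any(not (0 <= i < self.n_atoms) for i in f.source_atoms):
                raise ValueError("feature source atom index out of range")

    def by_kind(self, kind: str) -> list[int]:
        return [i for i, f in enumerate(self.features) if f.kind == kind]


# ---------------------------------------------------------------------------
# ring / cluster perception helpers
# ---------------------------------------------------------------------------

def aromatic_rings(mol: Molecule3D) -> list[tuple[int, ...]]:
    """Smallest aromatic rings (5-7 atoms) with planarity RMS <= 0.1 Å."""
    g = nx.Graph()
    for i, j, order in mol.bonds:
        if order == "ar" or (mol.atoms[i].is_aromatic and mol.atoms[j].is_aromatic):
            g.add_edge(i, j)
    rings = []
    for cycle in nx.cycle_basis(g):
        if not (5 <= len(cycle) <= 7):
            continue
        pts = np.array([mol.atoms[i].position for i in cycle])
        centred = pts - pts.mean(axis=0)
        # RMS distance to the best-fit plane (smallest singular direction)
        _, s, _ = np.linalg.svd(centred, full_matrices=False)
        rms = s[-1] / np.sqrt(len(cycle))
        if rms <= RING_PLANARITY_RMS:
            rings.append(tuple(sorted(cycle)))
    return rings


def _aliphatic_clusters(mol: Molecule3D, min_size: int = 3) -> list[tuple[int, ...]]:
    adj = mol.neighbors()
    alkyl = {i for i in range(len(mol.atoms)) if mol.is_alkyl_carbon(i, adj)}
    g = nx.Graph()
    g.add_nodes_from(alkyl)
    for i, j, _ in mol.bonds:
        if i in alkyl and j in alkyl:
            g.add_edge(i, j)
    return [tuple(sorted(c)) for c in nx.connected_components(g) if len(c) >= min_size]


def _is_amide_nitrogen(mol: Molecule3D, i: int, adj, orders) -> bool:
    for c in adj[i]:
        if mol.atoms[c].element.upper() != "C":
            continue
        for k in adj[c]:
            if mol.atoms[k].element.upper() == "O" and orders[frozenset((c, k))] == 2:
                return True
    return False


def _donor_acceptor_atoms(mol: Molecule3D, require_h: bool = True, infer_h: bool = False):
    """Indices of donor heavy atoms (with their H partners) and acceptors."""
    adj = mol.neighbors()
    orders = mol.bond_orders()
    has_h = any(a.element.upper() == "H" for a in mol.atoms)
    if require_h and not has_h and not infer_h:
        raise MissingHydrogensError(
            f"molecule {mol.name!r} has no explicit hydrogens; donor perception "
            "needs explicit H or infer_h=True"
        )
    donors: list[tuple[int, list[int]]] = []
    acceptors: list[int] = []
    for i, a in enumerate(mol.atoms):
        el = a.element.upper()
        if el in ("N", "O", "S"):
            h_nbrs = [j for j in adj[i] if mol.atoms[j].element.upper() == "H"]
            if h_nbrs:
                donors.append((i, h_nbrs))
            elif infer_h and not has_h:
                # crude open-valence inference for H-less inputs
                typical = {"N": 3, "O": 2, "S": 2}[el]
                if len(adj[i]) < typical and a.formal_charge <= 0:
                    donors.append((i, []))
        if el in ("N", "O") and a.formal_charge <= 0:
            if el == "N":
                if _is_amide_nitrogen(mol, i, adj, orders):
                    continue
                if a.is_aromatic and len(adj[i]) >= 3:
                    continue
            acceptors.append(i)
    return donors, acceptors


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

def perceive_ligand_features(
    mol: Molecule3D,
    tolerances: Optional[dict] = None,
    infer_h: bool = False,
) -> FeatureSet:
    """Perceive HBD/HBA/HyP features of a 3D ligand.

    Raises :class:`MissingHydrogensError` when the molecule carries no
    explicit hydrogens and ``infer_h`` is False.
    """
    tol = dict(DEFAULT_TOLERANCE)
    if tolerances:
        tol.update(tolerances)
    donors, acceptors = _donor_acceptor_atoms(mol, require_h=True, infer_h=infer_h)
    feats: list[PharmacophoreFeature] = []
    for i, h_nbrs in donors:
        feats.append(
            PharmacophoreFeature(
                "HBD", mol.atoms[i].position, tol["HBD"], source_atoms=(i, *h_nbrs)
            )
        )
    for i in acceptors:
        feats.append(
            PharmacophoreFeature("HBA", mol.atoms[i].position, tol["HBA"], source_atoms=(i,))
        )
    for ring in aromatic_rings(mol):
        centroid = np.mean([mol.atoms[i].position for i in ring], axis=0)
        feats.append(PharmacophoreFeature("HyP", centroid, tol["HyP"], source_atoms=ring))
    for cluster in _aliphatic_clusters(mol):
        centroid = np.mean([mol.atoms[i].position for i in cluster], axis=0)
        feats.append(PharmacophoreFeature("HyP", centroid, tol["HyP"], source_atoms=cluster))
    return FeatureSet(owner=mol.name, features=feats, n_atoms=len(mol.atoms))


def perceive_complementary_features(
    complex_: ProteinLigandComplex,
    site: PocketDefinition,
    tolerances: Optional[dict] = None,
) -> FeatureSet:
    """Receptor-complementary features: what a ligand should present.

    For each receptor acceptor facing the ligand, an HBD feature is placed
    2.9 Å along the acceptor's lone-pair direction (projection = the acceptor
    position); symmetrically an HBA feature opposite each receptor donor,
    2.9 Å along the D-H direction.  HyP features sit in front of hydrophobic
    side-chain carbon clusters, displaced toward the ligand.
    """
    if not site.residues:
        raise ValueError("binding site is empty")
    tol = dict(DEFAULT_TOLERANCE)
    if tolerances:
        tol.update(tolerances)
    rec, lig = complex_.receptor, complex_.ligand
    lig_xyz = lig.coords()
    site_idx = [
        i for i, a in enumerate(rec.atoms) if residue_in_set(a.residue_id, site.residues)
    ]
    site_set = set(site_idx)
    adj = rec.neighbors()

    def facing(i: int) -> bool:
        d = np.linalg.norm(lig_xyz - rec.atoms[i].position, axis=1)
        return bool(d.min() <= FACING_CUTOFF)

    # the ligand's geometric centroid is the covariant "inward" reference;
    # a nearest-atom choice would be ambiguous under symmetry ties
    lig_centroid = lig_xyz.mean(axis=0)

    def toward_ligand(i: int) -> np.ndarray:
        v = lig_centroid - rec.atoms[i].position
        return v / np.linalg.norm(v)

    donors, acceptors = _donor_acceptor_atoms(rec, require_h=False)
    donor_map = {i: hs for i, hs in donors}
    feats: list[PharmacophoreFeature] = []
    for i in acceptors:
        if i not in site_set or i in donor_map or not facing(i):
            continue
        heavy_nbrs = [j for j in adj[i] if rec.atoms[j].element.upper() != "H"]
        if heavy_nbrs:
            lone = rec.atoms[i].position - np.mean(
                [rec.atoms[j].position for j in heavy_nbrs], axis=0
            )
            lone = lone / np.linalg.norm(lone)
            if np.dot(lone, toward_ligand(i)) < 0:
                lone = -lone
        else:
            lone = toward_ligand(i)
        feats.append(
            PharmacophoreFeature(
                "HBD",
                rec.atoms[i].position + HBOND_PROJECTION * lone,
                tol["HBD"],
                projection=rec.atoms[i].position,
                source_atoms=(i,),
            )
        )
    for i, h_nbrs in donors:
        if i not in site_set or not facing(i):
            continue
        if h_nbrs:
            u = rec.atoms[h_nbrs[0]].position - rec.atoms[i].position
            u = u / np.linalg.norm(u)
        else:
            u = toward_ligand(i)
        feats.append(
            PharmacophoreFeature(
                "HBA",
                rec.atoms[i].position + HBOND_PROJECTION * u,
                tol["HBA"],
                projection=rec.atoms[i].position,
                source_atoms=(i, *h_nbrs),
            )
        )
    for cluster in _aliphatic_clusters(rec):
        in_site = [i for i in cluster if i in site_set]
        if len(in_site) < 3:
            continue
        res_names = {rec.atoms[i].residue_name.upper() for i in in_site}
        if not res_names & _HYDROPHOBIC_RESIDUES:
            continue
        centroid = np.mean([rec.atoms[i].position for i in in_site], axis=0)
        d = np.linalg.norm(lig_xyz - centroid, axis=1)
        if d.min() > FACING_CUTOFF + 2.0:
            continue
        u = lig_centroid - centroid
        norm = np.linalg.norm(u)
        pos = centroid if norm < 1e-9 else centroid + min(4.0, norm) * (u / norm)
        feats.append(
            PharmacophoreFeature("HyP", pos, tol["HyP"], source_atoms=tuple(in_site))
        )
    return FeatureSet(owner=rec.name, features=feats, n_atoms=len(rec.atoms))


# ---------------------------------------------------------------------------
# model enumeration and ranking
# ---------------------------------------------------------------------------

def selectivity_score(model: PharmacophoreModel) -> float:
    """Deterministic rarity-weighted heuristic standing in for the closed
    commercial selectivity score: kind priors (HBD/HBA 2.0, HyP 1.5) plus
    0.1 x mean inter-feature distance.  Only ordering is meaningful."""
    prior = sum(KIND_PRIOR[f.kind] for f in model.features)
    n = len(model.features)
    iu = np.triu_indices(n, k=1)
    mean_d = float(model.distance_matrix[iu].mean())
    return prior + 0.1 * mean_d


def enumerate_models(
    features: FeatureSet | Iterable[PharmacophoreFeature],
    min_n: int = 4,
    max_n: int = 5,
    provenance: str = "",
) -> list[PharmacophoreModel]:
    """All feature subsets of size in [min_n, max_n] whose members are
    pairwise >= 2 Å apart, ranked by selectivity (descending); ties broken by
    feature count (descending) then lexicographic kind string."""
    pool = list(features.features) if isinstance(features, FeatureSet) else list(features)
    if min_n < 3 or min_n > max_n:
        raise ValueError("need 3 <= min_n <= max_n")
    if len(pool) < min_n:
        warnings.warn(
            f"only {len(pool)} features available but min_n={min_n}; no models",
            stacklevel=2,
        )
        return []
    models: list[PharmacophoreModel] = []
    for n in range(min_n, min(max_n, len(pool)) + 1):
        for combo in itertools.combinations(range(len(pool)), n):
            pts = np.array([pool[i].centroid for i in combo])
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            iu = np.triu_indices(n, k=1)
            if np.any(d[iu] < MIN_FEATURE_SPACING):
                continue
            feats = sorted((pool[i] for i in combo), key=lambda f: f.kind)
            models.append(PharmacophoreModel(list(feats), provenance=provenance))
    for m in models:
        m.selectivity = selectivity_score(m)
    models.sort(key=lambda m: (-m.selectivity, -len(m.features), "".join(m.kinds)))
    return models
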