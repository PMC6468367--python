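"""Ligand-pharmacophore mapping and library screening.

A ligand matches a model when there is an injective, kind-compatible
assignment of model features to perceived ligand features whose pairwise
centroid distances all agree with the model's distance matrix within the sum
of the two features' tolerance radii.  Among feasible assignments the one
with minimum RMSD after optimal rigid superposition of the assigned
centroids wins; ties break lexicographically on the assignment tuple so the
result is reproducible bit-for-bit.

Matching is single-conformer: conformer generation, if needed, is the
caller's concern.  All model features must be matched — partial mappings do
not count as hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .pharmacophore import FeatureSet, PharmacophoreModel, perceive_ligand_features
from .types import Molecule3D

__all__ = ["MatchResult", "LibraryRecord", "ScreeningLibrary", "map_ligand", "screen_library"]


@dataclass
class MatchResult:
    matched: bool
    assignment: dict[int, int] = field(default_factory=dict)
    rmsd: float = float("nan")
    fit: float = 0.0

    def __post_init__(self) -> None:
        if self.matched:
            vals = list(self.assignment.values())
            if len(set(vals)) != len(vals):
                raise ValueError("assignment must be injective")
            if self.rmsd < 0:
                raise ValueError("rmsd must be >= 0")


@dataclass
class LibraryRecord:
    molecule: Molecule3D
    active: Optional[bool] = None
    score: Optional[float] = None
    matched: Optional[bool] = None
    rmsd: Optional[float] = None

    @property
    def name(self) -> str:
        return self.molecule.name


@dataclass
class ScreeningLibrary:
    records: list[LibraryRecord]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("library molecule names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labeled(self) -> bool:
        return all(r.active is not None for r in self.records)


def superpose_rmsd(reference: np.ndarray, moving: np.ndarray) -> float:
    """Minimum RMSD between two ordered point sets over rigid motions
    (Kabsch, via scipy's quaternion-based solver)."""
    a = np.asarray(reference, float)
    b = np.asarray(moving, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(len(a)))


def map_ligand(
    model: PharmacophoreModel,
    mol: Molecule3D,
    feature_set: Optional[FeatureSet] = None,
) -> MatchResult:
    """Map a 3D ligand onto a pharmacophore model.

    A kind mismatch that makes assignment impossible is a normal
    ``matched=False`` result, not an error.
    """
    fs = feature_set if feature_set is not None else perceive_ligand_features(mol)
    n = len(model.features)
    # candidate ligand features per model slot, by kind
    candidates = [fs.by_kind(f.kind) for f in model.features]
    if any(not c for c in candidates):
        return MatchResult(matched=False)
    lig_pts = np.array([f.centroid for f in fs.features])
    model_d = model.distance_matrix
    tols = np.array([f.tolerance for f in model.features])

    best: Optional[tuple[float, tuple[int, ...]]] = None
    assign: list[int] = []
    used: set[int] = set()
    model_pts = np.array([f.centroid for f in model.features])

    def dfs(slot: int) -> None:
        nonlocal best
        if slot == n:
            pts = lig_pts[list(assign)]
            rmsd = superpose_rmsd(model_pts, pts)
            key = (rmsd, tuple(assign))
            if best is None or key < best:
                best = key
            return
        for j in candidates[slot]:
            if j in used:
                continue
            ok = True
            for prev_slot, prev_j in enumerate(assign):
                d_lig = float(np.linalg.norm(lig_pts[j] - lig_pts[prev_j]))
                if abs(d_lig - model_d[slot, prev_slot]) > tols[slot] + tols[prev_slot]:
                    ok = False
                    break
            if ok:
                used.add(j)
                assign.append(j)
                dfs(slot + 1)
                assign.pop()
                used.discard(j)

    dfs(0)
    if best is None:
        return MatchResult(matched=False)
    rmsd, assignment = best
    fit = max(0.0, 1.0 - rmsd / model.mean_tolerance())
    return MatchResult(
        matched=True,
        assignment={i: j for i, j in enumerate(assignment)},
        rmsd=rmsd,
        fit=fit,
    )


def screen_library(
    model: PharmacophoreModel, lib: ScreeningLibrary
) -> tuple[ScreeningLibrary, list[LibraryRecord]]:
    """Score every record; return the scored library and the hit list
    (matched records, sorted by fit descending, ties by name)."""
    if not lib.records:
        raise ValueError("cannot screen an empty library")
    scored = []
    for rec in lib.records:
        res = map_ligand(model, rec.molecule)
        scored.append(
            replace(
                rec,
                score=res.fit,
                matched=res.matched,
                rmsd=res.rmsd if res.matched else None,
            )
        )
    out = ScreeningLibrary(scored)
    hits = sorted(
        (r for r in scored if r.matched), key=lambda r: (-(r.score or 0.0), r.name)
    )
    return out, hits
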