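"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from phore import synthetic as syn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_model():
    """The five-feature (2xHBD, 1xHBA, 2xHyP) reference pocket model."""
    return syn.reference_model()


@pytest.fixture(scope="session")
def ref_complex():
    return syn.make_reference_complex()


# ---------------------------------------------------------------------------
# oracles, independent of the implementation paths they check
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook Kabsch superposition RMSD via an explicit SVD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = bc.T @ ac
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = ac - (r @ bc.T).T
    return float(np.sqrt((diff**2).sum() / len(a)))


def brute_force_map(model, feature_set):
    """Enumerate every injective kind-compatible permutation; return
    (matched, best_rmsd) under the pairwise-distance feasibility rule."""
    n = len(model.features)
    feats = feature_set.features
    best = None
    for perm in itertools.permutations(range(len(feats)), n):
        if any(feats[j].kind != model.features[i].kind for i, j in enumerate(perm)):
            continue
        feasible = True
        for i in range(n):
            for k in range(i + 1, n):
                d_lig = np.linalg.norm(feats[perm[i]].centroid - feats[perm[k]].centroid)
                tol = model.features[i].tolerance + model.features[k].tolerance
                if abs(d_lig - model.distance_matrix[i, k]) > tol:
                    feasible = False
                    break
            if not feasible:
                break
        if not feasible:
            continue
        rmsd = kabsch_rmsd(
            np.array([f.centroid for f in model.features]),
            np.array([feats[j].centroid for j in perm]),
        )
        if best is None or rmsd < best:
            best = rmsd
    return (best is not None), best


def mann_whitney_auc(scores, labels) -> float:
    """Pairwise active/inactive ordering statistic with ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def gh_oracle(D, A, Ht, Ha):
    """One-line spreadsheet-style arithmetic for the decoy-set metrics."""
    return {
        "yield_pct": 100 * Ha / Ht,
        "ratio_pct": 100 * Ha / A,
        "EF": Ha * D / (Ht * A),
        "GF_eq": (Ha * (3 * A + Ht) / (4 * Ht * A)) * (1 - (Ht - Ha) / (D - A)),
        "GF_alt": (Ha * (3 * Ha + Ht) / (4 * Ht * A)) * (1 - (Ht - Ha) / (D - A)),
        "FN": A - Ha,
        "FP": Ht - Ha,
    }


def count_hbd_hba_rotatable(mol):
    """Brute-force Lipinski counts from the molecular graph: donor = O-H/N-H
    hydrogen, acceptor = N or O atom, rotatable = non-ring single bond
    between non-terminal heavy atoms excluding amide C-N."""
    import networkx as nx

    adj = mol.neighbors()
    orders = mol.bond_orders()
    hbd = sum(
        1
        for i, a in enumerate(mol.atoms)
        if a.element.upper() == "H"
        and any(mol.atoms[j].element.upper() in ("N", "O") for j in adj[i])
    )
    hba = sum(1 for a in mol.atoms if a.element.upper() in ("N", "O"))
    g = nx.Graph((i, j) for i, j, _ in mol.bonds)
    ring_edges = set()
    for cycle in nx.cycle_basis(g):
        for i in range(len(cycle)):
            ring_edges.add(frozenset((cycle[i], cycle[(i + 1) % len(cycle)])))

    def heavy_degree(i):
        return sum(1 for j in adj[i] if mol.atoms[j].element.upper() != "H")

    def is_amide_cn(i, j):
        for c, n in ((i, j), (j, i)):
            if mol.atoms[c].element.upper() == "C" and mol.atoms[n].element.upper() == "N":
                if any(
                    mol.atoms[k].element.upper() == "O" and orders[frozenset((c, k))] == 2
                    for k in adj[c]
                ):
                    return True
        return False

    rotatable = 0
    for i, j, order in mol.bonds:
        if order != 1 or frozenset((i, j)) in ring_edges:
            continue
        if mol.atoms[i].element.upper() == "H" or mol.atoms[j].element.upper() == "H":
            continue
        if heavy_degree(i) < 2 or heavy_degree(j) < 2:
            continue
        if is_amide_cn(i, j):
            continue
        rotatable += 1
    return hbd, hba, rotatable


def random_rigid_transform(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans
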