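"""Feature perception, model enumeration and the selectivity heuristic."""

import itertools
import math

import numpy as np
import pytest

from conftest import random_rigid_transform
from phore import synthetic as syn
from phore.molecular_io import extract_binding_site, mol_from_smiles
from phore.pharmacophore import (
    MissingHydrogensError,
    PharmacophoreFeature,
    PharmacophoreModel,
    enumerate_models,
    perceive_complementary_features,
    perceive_ligand_features,
    selectivity_score,
)
from phore.types import Atom, Molecule3D


def _kinds(fs):
    return sorted(f.kind for f in fs.features)


class TestLigandPerception:
    def test_methanol_gives_one_donor_one_acceptor_on_oxygen(self):
        mol = mol_from_smiles("CO", name="methanol", embed=True, seed=1)
        fs = perceive_ligand_features(mol)
        assert _kinds(fs) == ["HBA", "HBD"]
        o_idx = next(i for i, a in enumerate(mol.atoms) if a.element == "O")
        for f in fs.features:
            np.testing.assert_allclose(f.centroid, mol.atoms[o_idx].position)

    def test_benzene_gives_single_ring_hydrophobe(self):
        mol = mol_from_smiles("c1ccccc1", embed=True, seed=1)
        fs = perceive_ligand_features(mol)
        assert _kinds(fs) == ["HyP"]
        ring_centroid = np.mean(
            [a.position for a in mol.atoms if a.element == "C"], axis=0
        )
        np.testing.assert_allclose(fs.features[0].centroid, ring_centroid, atol=1e-6)

    def test_protonated_amine_is_donor_not_acceptor(self):
        mol = mol_from_smiles("C[NH3+]", embed=True, seed=1)
        fs = perceive_ligand_features(mol)
        assert "HBD" in _kinds(fs)
        assert "HBA" not in _kinds(fs)

    def test_amide_nitrogen_not_an_acceptor(self):
        mol = mol_from_smiles("CC(=O)NC", embed=True, seed=1)
        fs = perceive_ligand_features(mol)
        # the carbonyl O accepts; the amide N donates but does not accept
        assert _kinds(fs).count("HBA") == 1

    def test_aliphatic_cluster_needs_three_carbons(self):
        propane = mol_from_smiles("CCC", embed=True, seed=1)
        assert _kinds(perceive_ligand_features(propane)) == ["HyP"]
        ethane = mol_from_smiles("CC", embed=True, seed=1)
        assert _kinds(perceive_ligand_features(ethane)) == []

    def test_missing_hydrogens_raise(self):
        mol = Molecule3D(
            "bare",
            [Atom(1, "O", np.zeros(3)), Atom(2, "C", np.array([1.4, 0.0, 0.0]))],
            [(0, 1, 1)],
        )
        with pytest.raises(MissingHydrogensError):
            perceive_ligand_features(mol)
        fs = perceive_ligand_features(mol, infer_h=True)
        assert "HBD" in _kinds(fs)


class TestComplementaryPerception:
    def test_reference_pocket_composition(self, ref_complex):
        """A hinge acceptor pair + backbone donor + two leucine clusters give
        the 2xHBD / 1xHBA / 2xHyP receptor-complementary composition."""
        site = extract_binding_site(ref_complex, radius=10.0)
        fs = perceive_complementary_features(ref_complex, site)
        assert _kinds(fs) == ["HBA", "HBD", "HBD", "HyP", "HyP"]

    def test_single_carbonyl_site_gives_one_donor_feature(self, ref_complex):
        site = extract_binding_site(ref_complex, radius=10.0)
        only_885 = site.residues & {("A", 885, "GLU")}
        sub = type(site)(radius=site.radius, residues=frozenset(only_885))
        fs = perceive_complementary_features(ref_complex, sub)
        assert _kinds(fs) == ["HBD"]
        f = fs.features[0]
        oe2 = next(a for a in ref_complex.receptor.atoms if a.name == "OE2")
        np.testing.assert_allclose(f.projection, oe2.position, atol=1e-9)
        assert np.linalg.norm(f.centroid - oe2.position) == pytest.approx(2.9, abs=1e-9)

    def test_glycine_only_site_has_no_hydrophobes(self):
        rec_atoms = []
        for k, num in enumerate((10, 11)):
            base = np.array([4.0 + k, 0.0, 0.0])
            rec_atoms += [
                Atom(3 * k + 1, "C", base, residue_name="GLY", residue_number=num,
                     chain_id="A", name="CA"),
                Atom(3 * k + 2, "H", base + [0.0, 1.09, 0.0], residue_name="GLY",
                     residue_number=num, chain_id="A", name="HA"),
            ]
        from phore.types import PocketDefinition, ProteinLigandComplex

        rec = Molecule3D("gly", rec_atoms)
        lig = Molecule3D("lig", [Atom(1, "C", np.zeros(3))])
        cx = ProteinLigandComplex(rec, lig)
        site = PocketDefinition(radius=10.0, residues=frozenset(
            a.residue_id for a in rec_atoms
        ))
        fs = perceive_complementary_features(cx, site)
        assert all(f.kind != "HyP" for f in fs.features)

    def test_rigid_invariance(self, ref_complex):
        """Perception commutes with rigid-body motion of the whole complex."""
        site = extract_binding_site(ref_complex, radius=10.0)
        fs0 = perceive_complementary_features(ref_complex, site)
        rng = np.random.default_rng(11)
        from phore.types import ProteinLigandComplex

        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            moved = ProteinLigandComplex(
                ref_complex.receptor.transformed(rot, trans),
                ref_complex.ligand.transformed(rot, trans),
            )
            site_m = extract_binding_site(moved, radius=10.0)
            assert site_m.residues == site.residues
            fs_m = perceive_complementary_features(moved, site_m)
            assert _kinds(fs_m) == _kinds(fs0)
            for f0, fm in zip(fs0.features, fs_m.features):
                np.testing.assert_allclose(
                    fm.centroid, rot @ f0.centroid + trans, atol=1e-9
                )


class TestEnumeration:
    @staticmethod
    def _well_separated(n):
        pts = 4.0 * np.eye(3)
        extra = [[4.0, 4.0, 0.0], [0.0, 4.0, 4.0], [4.0, 0.0, 4.0], [4.0, 4.0, 4.0]]
        pos = list(pts) + extra
        kinds = ["HBD", "HBA", "HyP", "HBD", "HyP", "HBA", "HBD"]
        return [
            PharmacophoreFeature(kinds[i], np.array(pos[i]), 1.6) for i in range(n)
        ]

    def test_exact_subset_counts(self):
        feats = self._well_separated(5)
        assert len(enumerate_models(feats, 5, 5)) == 1
        assert len(enumerate_models(feats, 4, 5)) == 6  # C(5,4) + C(5,5)

    def test_brute_force_subset_count_oracle(self):
        for n in (5, 6, 7):
            feats = self._well_separated(n)
            got = len(enumerate_models(feats, 4, min(n, 7)))
            expected = sum(math.comb(n, k) for k in range(4, n + 1))
            assert got == expected

    def test_close_features_excluded(self):
        feats = self._well_separated(5)
        feats.append(
            PharmacophoreFeature("HBD", feats[0].centroid + [1.0, 0.0, 0.0], 1.6)
        )
        models = enumerate_models(feats, 4, 6)
        for m in models:
            iu = np.triu_indices(len(m.features), k=1)
            assert (m.distance_matrix[iu] >= 2.0).all()

    def test_too_few_features_warn_and_empty(self):
        feats = self._well_separated(3)
        with pytest.warns(UserWarning):
            assert enumerate_models(feats, 4, 5) == []


class TestSelectivity:
    def test_deterministic(self, ref_model):
        assert selectivity_score(ref_model) == selectivity_score(ref_model)

    def test_supersets_outrank_subsets(self):
        feats = TestEnumeration._well_separated(5)
        full = PharmacophoreModel(list(feats))
        for combo in itertools.combinations(feats, 4):
            sub = PharmacophoreModel(list(combo))
            assert selectivity_score(full) > selectivity_score(sub)

    def test_larger_spread_scores_higher(self):
        tight = [
            PharmacophoreFeature(k, 3.0 * np.array(p), 1.6)
            for k, p in zip(["HBD", "HBA", "HyP"], np.eye(3))
        ]
        wide = [
            PharmacophoreFeature(k, 6.0 * np.array(p), 1.6)
            for k, p in zip(["HBD", "HBA", "HyP"], np.eye(3))
        ]
        assert selectivity_score(PharmacophoreModel(wide)) > selectivity_score(
            PharmacophoreModel(tight)
        )

    def test_five_feature_models_outrank_four_feature_models(self, ref_complex):
        """Within one feature pool every 5-feature model ranks above every
        4-feature model (the published ranking trend)."""
        site = extract_binding_site(ref_complex, radius=10.0)
        fs = perceive_complementary_features(ref_complex, site)
        models = enumerate_models(fs, 4, 5)
        fives = [m for m in models if len(m.features) == 5]
        fours = [m for m in models if len(m.features) == 4]
        assert fives and fours
        assert min(m.selectivity for m in fives) > max(m.selectivity for m in fours)


def test_decoy_distance_matrix_triangle_inequality_enforced():
    with pytest.raises(ValueError, match="triangle"):
        PharmacophoreModel(
            TestEnumeration._well_separated(3),
            distance_matrix=np.array([[0, 1, 10.0], [1, 0, 1], [10.0, 1, 0]]),
        )
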