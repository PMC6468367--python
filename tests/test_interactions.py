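"""Contact detection geometry, category exclusivity and the type-II verdict."""

import itertools

import numpy as np
import pytest

from conftest import random_rigid_transform
from phore import synthetic as syn
from phore.interactions import (
    InteractionCutoffs,
    InteractionRecord,
    classify_type2,
    detect_hbonds,
    detect_vdw_contacts,
    interaction_table,
)
from phore.types import (
    PocketDefinition,
    ProteinLigandComplex,
    VEGFR2_BACK,
    VEGFR2_FRONT,
)

POCKET = PocketDefinition(
    radius=10.0, front_residues=VEGFR2_FRONT, back_residues=VEGFR2_BACK
)


def _toy(*contacts, seed=0, ring_radius=None):
    return syn.make_toy_complex(
        syn.ComplexSpec(contacts=tuple(contacts), seed=seed, ring_radius=ring_radius)
    )


class TestHydrogenBonds:
    def test_backbone_donor_at_2p9(self):
        cx = _toy(
            syn.PlantedContact("hydrogen_bond", ("A", 1046, "ASP"), 2.9, angle=165.0,
                               donor_side="receptor")
        )
        recs = detect_hbonds(cx)
        assert len(recs) == 1
        r = recs[0]
        assert r.distance == pytest.approx(2.9, abs=1e-9)
        assert r.angle == pytest.approx(165.0, abs=1e-6)
        assert r.donor_side == "receptor"
        assert r.residue == ("A", 1046, "ASP")

    def test_stretched_pair_beyond_3A_ignored(self):
        cx = _toy(
            syn.PlantedContact("hydrogen_bond", ("A", 1046, "ASP"), 3.2,
                               donor_side="receptor")
        )
        assert detect_hbonds(cx) == []

    def test_hydrogen_convention_carries_both_distances(self):
        cx = _toy(
            syn.PlantedContact("hydrogen_bond", ("A", 917, "GLU"), 1.9, angle=170.0,
                               measure="hydrogen", donor_side="ligand")
        )
        recs = detect_hbonds(cx)
        assert len(recs) == 1
        r = recs[0]
        assert r.h_distance == pytest.approx(1.9, abs=1e-9)
        assert 2.6 < r.distance < 3.0  # heavy-atom distance implied by geometry
        assert r.donor_side == "ligand"

    def test_bent_geometry_below_angle_cutoff_rejected(self):
        cx = _toy(
            syn.PlantedContact("hydrogen_bond", ("A", 919, "CYS"), 2.9, angle=100.0,
                               donor_side="receptor")
        )
        assert detect_hbonds(cx) == []


class TestPlantedRecovery:
    CASES = [
        ("hydrogen_bond", ("A", 1046, "ASP"), 2.9, dict(donor_side="receptor")),
        ("hydrogen_bond", ("A", 885, "GLU"), 2.6, dict(donor_side="ligand")),
        ("pi_pi_stacked", ("A", 1026, "HIS"), 4.6, {}),
        ("pi_pi_T", ("A", 1047, "PHE"), 4.8, {}),
        ("pi_cation", ("A", 868, "LYS"), 3.1, {}),
        ("pi_sigma", ("A", 1035, "LEU"), 3.5, {}),
        ("pi_alkyl", ("A", 848, "VAL"), 5.0, {}),
        ("alkyl_alkyl", ("A", 889, "LEU"), 4.9, {}),
        ("sulfur_x", ("A", 840, "LEU"), 3.2, {}),
        ("vdw_contact", ("A", 922, "GLY"), 3.8, {}),
    ]

    @pytest.mark.parametrize("cat,res,dist,kw", CASES)
    def test_each_category_recovered_exactly(self, cat, res, dist, kw):
        cx = _toy(syn.PlantedContact(cat, res, dist, **kw))
        rows = interaction_table(cx, POCKET)["records"]
        assert len(rows) == 1
        r = rows[0]
        assert r.category == cat
        assert r.residue == res
        planted = dist
        got = r.h_distance if kw.get("measure") == "hydrogen" else r.distance
        assert got == pytest.approx(planted, abs=1e-6)

    def test_all_categories_coexist_without_cross_talk(self):
        contacts = [syn.PlantedContact(c, r, d, **kw) for c, r, d, kw in self.CASES]
        cx = _toy(*contacts, seed=3)
        rows = interaction_table(cx, POCKET)["records"]
        got = sorted((r.category, r.residue[1]) for r in rows)
        want = sorted((c, r[1]) for c, r, _, _ in self.CASES)
        assert got == want

    def test_rigid_invariance_of_all_detectors(self):
        contacts = [syn.PlantedContact(c, r, d, **kw) for c, r, d, kw in self.CASES]
        cx = _toy(*contacts, seed=3)
        base = sorted(
            (r.category, r.residue, round(r.distance, 9))
            for r in interaction_table(cx, POCKET)["records"]
        )
        rng = np.random.default_rng(8)
        for _ in range(3):
            rot, trans = random_rigid_transform(rng)
            moved = ProteinLigandComplex(
                cx.receptor.transformed(rot, trans), cx.ligand.transformed(rot, trans)
            )
            got = sorted(
                (r.category, r.residue, round(r.distance, 9))
                for r in interaction_table(moved, POCKET)["records"]
            )
            assert [(c, res, pytest.approx(d, abs=1e-6)) for c, res, d in base] == got


class TestVdw:
    def test_isolated_contact_listed(self):
        cx = _toy(syn.PlantedContact("vdw_contact", ("A", 922, "GLY"), 3.8))
        recs = detect_vdw_contacts(cx)
        assert [r.residue for r in recs] == [("A", 922, "GLY")]
        assert recs[0].distance == pytest.approx(3.8, abs=1e-9)

    def test_hbonded_residue_excluded(self):
        cx = _toy(
            syn.PlantedContact("hydrogen_bond", ("A", 919, "CYS"), 2.9,
                               donor_side="receptor")
        )
        row = interaction_table(cx, POCKET)
        assert row["vdw"] == []
        assert row["n_hbonds"] == 1

    def test_beyond_cutoff_absent(self):
        cx = _toy(syn.PlantedContact("vdw_contact", ("A", 922, "GLY"), 4.5))
        assert detect_vdw_contacts(cx) == []


class TestTypeII:
    @staticmethod
    def _hb(residue):
        return InteractionRecord(
            category="hydrogen_bond",
            residue=residue,
            receptor_atom="X",
            ligand_atom="Y",
            distance=2.8,
            donor_side="receptor",
        )

    KEY = [("A", 885, "GLU"), ("A", 917, "GLU"), ("A", 919, "CYS"), ("A", 1046, "ASP")]

    @pytest.mark.parametrize("present", list(itertools.product([0, 1], repeat=4)))
    def test_full_truth_table(self, present):
        """All 16 presence combinations of the four key residues: the verdict
        holds iff a front (917/919) and a back (885/1046) bond both exist."""
        records = [self._hb(res) for res, p in zip(self.KEY, present) if p]
        verdict = classify_type2(records, POCKET)
        front_present = present[1] or present[2]
        back_present = present[0] or present[3]
        assert verdict.is_back_to_front == bool(front_present and back_present)
        assert len(verdict.front_hbonds) == present[1] + present[2]
        assert len(verdict.back_hbonds) == present[0] + present[3]

    def test_non_hbond_records_ignored(self):
        rec = InteractionRecord(
            category="pi_alkyl", residue=("A", 885, "GLU"),
            receptor_atom="X", ligand_atom="Y", distance=4.0,
        )
        assert not classify_type2([rec, self._hb(("A", 919, "CYS"))],
                                  POCKET).is_back_to_front

    def test_undefined_pocket_sets_rejected(self):
        with pytest.raises(ValueError):
            classify_type2([], PocketDefinition(radius=10.0))


class TestStaticDistanceWindows:
    # every distance printed in the published interaction analysis, by category
    PRINTED = {
        "hydrogen_bond": [2.6, 2.8, 2.9, 2.9, 2.1, 1.9, 1.9, 2.0, 1.9, 1.8, 1.9,
                          1.9, 2.1, 2.8, 2.1, 2.8, 2.1, 2.6, 2.6, 2.6, 2.0, 2.2,
                          2.4, 2.9, 1.9, 1.9, 2.5, 2.2],
        "pi_alkyl": [5.0, 5.4, 4.3, 4.6, 3.6, 4.8, 4.4, 4.8, 5.0, 4.2, 4.9, 4.1,
                     5.1, 4.9, 4.9, 4.2, 5.1, 4.8, 4.8, 5.1, 4.2, 5.3, 4.9, 4.4,
                     5.4, 4.3, 4.6, 4.2, 4.3, 5.2],
        "pi_cation": [4.3, 3.1, 3.5, 4.3],
        "pi_sigma": [3.5, 3.5, 3.7, 2.7, 2.6, 2.8],
        "pi_pi_stacked": [5.1, 4.6],
        "pi_pi_T": [4.8],
        "sulfur_x": [3.2],
        "alkyl_alkyl": [4.9, 4.5],
    }

    def test_all_printed_distances_inside_category_windows(self):
        cutoffs = InteractionCutoffs()
        for category, distances in self.PRINTED.items():
            lo, hi = cutoffs.window(category)
            for d in distances:
                assert lo < d <= hi, (category, d)


class TestInteractionTable:
    def test_back_to_front_pose_row(self):
        cx = _toy(
            syn.PlantedContact("hydrogen_bond", ("A", 885, "GLU"), 2.1,
                               donor_side="ligand"),
            syn.PlantedContact("hydrogen_bond", ("A", 917, "GLU"), 1.9,
                               measure="hydrogen", donor_side="ligand"),
            syn.PlantedContact("hydrogen_bond", ("A", 919, "CYS"), 1.9,
                               measure="hydrogen", donor_side="receptor"),
            syn.PlantedContact("hydrogen_bond", ("A", 1046, "ASP"), 2.0,
                               donor_side="receptor"),
            syn.PlantedContact("pi_alkyl", ("A", 840, "LEU"), 4.8),
            syn.PlantedContact("pi_alkyl", ("A", 866, "ALA"), 4.2),
            syn.PlantedContact("vdw_contact", ("A", 888, "ILE"), 3.8),
            syn.PlantedContact("vdw_contact", ("A", 889, "LEU"), 3.9),
            syn.PlantedContact("vdw_contact", ("A", 922, "GLY"), 3.7),
        )
        row = interaction_table(cx, POCKET)
        assert row["n_hbonds"] == 4
        assert row["n_pi_hydrophobic"] == 2
        assert row["n_vdw"] == 3
        assert row["is_back_to_front"] is True

    def test_apolar_ligand_polar_pocket_no_hbonds(self):
        cx = _toy(syn.PlantedContact("pi_alkyl", ("A", 848, "VAL"), 5.0))
        row = interaction_table(cx, POCKET)
        assert row["n_hbonds"] == 0
        assert row["is_back_to_front"] is False

    def test_infeasible_spec_clashes(self):
        contacts = [
            syn.PlantedContact("vdw_contact", ("A", 900 + k, "GLY"), 3.8)
            for k in range(4)
        ]
        with pytest.raises(ValueError, match="infeasible"):
            _toy(*contacts, ring_radius=1.5)
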