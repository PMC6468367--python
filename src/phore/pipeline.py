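"""End-to-end screening funnel orchestration.

Stage order mirrors the virtual-screening workflow the package implements:
pharmacophore perception -> decoy-set/ROC validation -> library screening ->
Rule-of-5 filtering -> interaction profiling of docked poses -> back-to-front
ranking.  Docked poses are consumed, never produced: the profiling stage
takes a directory of PDB complexes (one per ligand), or synthesizes planted
poses in fully synthetic runs.

Two runs with the same config produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import synthetic
from .druglikeness import filter_druglike
from .interactions import InteractionCutoffs, interaction_table
from .molecular_io import read_pharmacophore, read_structure, write_pharmacophore
from .screening import LibraryRecord, ScreeningLibrary, screen_library
from .types import PocketDefinition, VEGFR2_BACK, VEGFR2_FRONT
from .validation import validate_model

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 1
    site_radius: float = 10.0
    min_features: int = 4
    max_features: int = 5
    ro5_strict: bool = True
    model_path: Optional[str] = None
    library_path: Optional[str] = None  # SDF; None -> synthetic library
    labels_path: Optional[str] = None  # CSV with name,active columns
    pose_dir: Optional[str] = None  # PDB complexes; None -> synthetic poses
    library_spec: dict = field(
        default_factory=lambda: {"D": 120, "A": 30, "planted_Ht": 26, "planted_Ha": 23}
    )
    validate: bool = True
    validation_spec: dict = field(
        default_factory=lambda: {"D": 720, "A": 24, "planted_Ht": 26, "planted_Ha": 23}
    )
    n_pose_hits: int = 26
    back_to_front_every: int = 4  # synthetic poses: every k-th hit lacks a back H-bond
    out_dir: str = "phore_run"

    def __post_init__(self) -> None:
        if self.site_radius <= 0:
            raise ValueError("site_radius must be > 0")
        if not (3 <= self.min_features <= self.max_features <= 7):
            raise ValueError("need 3 <= min_features <= max_features <= 7")
        for path in (self.model_path, self.library_path, self.labels_path, self.pose_dir):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _load_library(config: PipelineConfig, model) -> ScreeningLibrary:
    if config.library_path is None:
        spec = synthetic.LibrarySpec(seed=config.seed + 2, **config.library_spec)
        return synthetic.make_library(model, spec)
    mols = read_structure(config.library_path, "sdf")
    labels = {}
    if config.labels_path:
        df = pd.read_csv(config.labels_path)
        labels = dict(zip(df["name"], df["active"].astype(bool)))
    return ScreeningLibrary(
        [LibraryRecord(molecule=m, active=labels.get(m.name)) for m in mols]
    )


def _synthetic_pose(model, index: int, seed: int, back_to_front: bool):
    contacts = [
        synthetic.PlantedContact(
            "hydrogen_bond", ("A", 917, "GLU"), 2.8, donor_side="ligand"
        ),
        synthetic.PlantedContact(
            "hydrogen_bond", ("A", 919, "CYS"), 2.9, donor_side="receptor"
        ),
        synthetic.PlantedContact("pi_alkyl", ("A", 848, "VAL"), 5.0),
        synthetic.PlantedContact("vdw_contact", ("A", 922, "GLY"), 3.8),
    ]
    if back_to_front:
        contacts.insert(
            0,
            synthetic.PlantedContact(
                "hydrogen_bond", ("A", 885, "GLU"), 2.6, donor_side="ligand"
            ),
        )
        contacts.append(
            synthetic.PlantedContact(
                "hydrogen_bond", ("A", 1046, "ASP"), 2.9, donor_side="receptor"
            )
        )
    return synthetic.make_toy_complex(
        synthetic.ComplexSpec(contacts=tuple(contacts), seed=seed + index)
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the funnel; write funnel.json, hits.csv, interactions.csv,
    validation.json and the machine-readable run record; return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def fail(stage: str, exc: Exception):
        report["stages"][stage] = {"error": str(exc)}
        (out / "funnel.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # stage 1: pharmacophore model
    try:
        if config.model_path:
            model = read_pharmacophore(config.model_path)
        else:
            model = synthetic.reference_model(
                config.min_features, config.max_features, config.site_radius
            )
        write_pharmacophore(model, out / "model.json")
        report["stages"]["model"] = {
            "n_features": len(model.features),
            "kinds": list(model.kinds),
            "selectivity": model.selectivity,
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("model", exc)

    # stage 2: validation
    if config.validate:
        try:
            vspec = synthetic.LibrarySpec(seed=config.seed + 1, **config.validation_spec)
            vlib = synthetic.make_library(model, vspec)
            vreport = validate_model(model, vlib)
            (out / "validation.json").write_text(
                json.dumps(vreport.to_dict(), indent=2, sort_keys=True)
            )
            report["stages"]["validation"] = vreport.to_dict()
        except Exception as exc:  # noqa: BLE001
            fail("validation", exc)

    # stage 3: screening
    try:
        lib = _load_library(config, model)
        scored, hits = screen_library(model, lib)
        report["stages"]["screening"] = {"library": len(scored.records), "hits": len(hits)}
    except Exception as exc:  # noqa: BLE001
        fail("screening", exc)

    # stage 4: drug-likeness
    try:
        hit_lib = ScreeningLibrary(list(hits))
        druglike = filter_druglike(hit_lib, strict=config.ro5_strict) if hits else hit_lib
        report["stages"]["druglikeness"] = {"survivors": len(druglike.records)}
    except Exception as exc:  # noqa: BLE001
        fail("druglikeness", exc)

    # stage 5: interaction profiling of poses
    try:
        pocket = PocketDefinition(
            radius=config.site_radius,
            front_residues=VEGFR2_FRONT,
            back_residues=VEGFR2_BACK,
        )
        cutoffs = InteractionCutoffs()
        rows = []
        if config.pose_dir:
            poses = sorted(Path(config.pose_dir).glob("*.pdb"))
            complexes = [read_structure(p, "pdb") for p in poses]
        else:
            survivors = druglike.records[: config.n_pose_hits]
            complexes = []
            for k, rec in enumerate(survivors):
                btf = (k + 1) % config.back_to_front_every != 0
                cx = _synthetic_pose(model, k, config.seed + 1000, btf)
                cx.ligand.name = rec.name
                complexes.append(cx)
        for cx in complexes:
            row = interaction_table(cx, pocket, cutoffs=cutoffs)
            row.pop("records")
            row.pop("verdict")
            rows.append(row)
        n_btf = sum(1 for r in rows if r["is_back_to_front"])
        report["stages"]["profiling"] = {"poses": len(rows), "back_to_front": n_btf}
    except Exception as exc:  # noqa: BLE001
        fail("profiling", exc)

    # funnel summary and outputs
    report["funnel"] = {
        "library": report["stages"]["screening"]["library"],
        "mapped": report["stages"]["screening"]["hits"],
        "ro5_survivors": report["stages"]["druglikeness"]["survivors"],
        "profiled_poses": report["stages"]["profiling"]["poses"],
        "back_to_front_hits": report["stages"]["profiling"]["back_to_front"],
    }
    pd.DataFrame(
        [
            {
                "name": r.name,
                "active": r.active,
                "matched": r.matched,
                "rmsd": r.rmsd,
                "fit": r.score,
            }
            for r in hits
        ]
    ).to_csv(out / "hits.csv", index=False)
    pd.DataFrame(
        [
            {
                "compound": r["compound"],
                "hydrogen_bonds": "; ".join(r["hydrogen_bonds"]),
                "pi_hydrophobic": "; ".join(r["pi_hydrophobic"]),
                "vdw": "; ".join(r["vdw"]),
                "is_back_to_front": r["is_back_to_front"],
            }
            for r in rows
        ]
    ).to_csv(out / "interactions.csv", index=False)
    (out / "funnel.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
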