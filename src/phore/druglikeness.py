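"""Lipinski Rule-of-5 drug-likeness profiling.

Descriptors follow the classic Lipinski conventions: molecular weight from
standard atomic weights, logP by the Wildman-Crippen atom-contribution
scheme, donor count = O-H/N-H hydrogens, acceptor count = N + O atoms, and
rotatable bonds = non-ring single bonds between non-terminal heavy atoms
with amide C-N excluded.  All five rules are applied as strict inequalities
by default (mw < 500, logP < 5, HBD < 5, HBA < 10, rotatable < 10); a
``strict=False`` flag switches to the <=-style thresholds.

Descriptor arithmetic is delegated to RDKit; this module owns the rule
logic, the profile container and the library filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .molecular_io import mol_to_rdkit
from .screening import ScreeningLibrary
from .types import Molecule3D

__all__ = ["Ro5Profile", "ro5_profile", "filter_druglike", "rule_violations", "RO5_LIMITS"]

#: rule thresholds (value must be strictly below, or <= when strict=False)
RO5_LIMITS = {"mw": 500.0, "logp": 5.0, "hbd": 5, "hba": 10, "rotatable": 10}

#: amide C-N single bond between non-terminal heavy atoms
_AMIDE_ROTOR = Chem.MolFromSmarts("[CX3;!D1](=[OX1])-!@[NX3;!D1]")


def rule_violations(values: dict, strict: bool = True) -> tuple[str, ...]:
    """Names of the rules a descriptor set violates.

    ``strict=True`` applies every threshold as "strictly less than" (a
    molecule of exactly 500 Da fails); ``strict=False`` allows equality.
    """
    if strict:
        return tuple(k for k, v in values.items() if v >= RO5_LIMITS[k])
    return tuple(k for k, v in values.items() if v > RO5_LIMITS[k])


@dataclass(frozen=True)
class Ro5Profile:
    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable: int
    violations: tuple[str, ...]
    passes: bool

    def __post_init__(self) -> None:
        if min(self.hbd, self.hba, self.rotatable) < 0:
            raise ValueError("descriptor counts must be nonnegative")
        if self.passes != (not self.violations):
            raise ValueError("passes must mirror an empty violation list")


def ro5_profile(mol: Molecule3D, strict: bool = True) -> Ro5Profile:
    """Compute the Rule-of-5 profile of a valence-complete molecule."""
    try:
        # collapse explicit hydrogens: descriptor SMARTS (rotatable bonds)
        # assume implicit-H degree conventions
        rd = Chem.RemoveHs(mol_to_rdkit(mol))
    except Exception as exc:
        raise ValueError(f"molecule {mol.name!r}: unparseable valence ({exc})") from exc
    mw = float(Descriptors.MolWt(rd))
    logp = float(Crippen.MolLogP(rd))
    hbd = int(rdMolDescriptors.CalcNumLipinskiHBD(rd))  # O-H + N-H hydrogens
    hba = int(rdMolDescriptors.CalcNumLipinskiHBA(rd))  # N + O count
    # non-ring single bonds between non-terminal heavy atoms, minus amide
    # C-N bonds (the NonStrict pattern counts those)
    rotatable = int(
        rdMolDescriptors.CalcNumRotatableBonds(
            rd, rdMolDescriptors.NumRotatableBondsOptions.NonStrict
        )
    ) - len(rd.GetSubstructMatches(_AMIDE_ROTOR))
    values = {"mw": mw, "logp": logp, "hbd": hbd, "hba": hba, "rotatable": rotatable}
    violations = rule_violations(values, strict=strict)
    return Ro5Profile(
        mw=mw,
        logp=logp,
        hbd=hbd,
        hba=hba,
        rotatable=rotatable,
        violations=violations,
        passes=not violations,
    )


def filter_druglike(lib: ScreeningLibrary, strict: bool = True) -> ScreeningLibrary:
    """Retain records passing Ro5, order preserved; each surviving record's
    molecule carries its profile under ``properties['ro5']``."""
    if not lib.records:
        raise ValueError("cannot filter an empty library")
    kept = []
    for rec in lib.records:
        profile = ro5_profile(rec.molecule, strict=strict)
        if profile.passes:
            mol = rec.molecule
            mol.properties = {**mol.properties, "ro5": profile}
            kept.append(replace(rec, molecule=mol))
    return ScreeningLibrary(kept)
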