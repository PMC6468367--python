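# phore

Structure-based pharmacophore screening, decoy-set validation and
protein–ligand interaction profiling for type-II kinase inhibitor discovery.

## The problem

Type-II kinase inhibitors bind the inactive (DFG-out) conformation of a
kinase, hydrogen-bonding simultaneously to the ATP-site **front pocket** and
an adjacent allosteric **back pocket** — for the angiogenesis target VEGFR-2
the front pocket is Glu917/Cys919 (hinge) and the back pocket is
Glu885/Asp1046. A practical route to new type-II chemotypes is: derive a
pharmacophore (an abstract 3D arrangement of hydrogen-bond donors HBD,
acceptors HBA and hydrophobes HyP) from a co-crystallised inhibitor complex,
validate it against a decoy set, screen a 3D library with it, gate the hits
by Lipinski drug-likeness, and keep only docked poses that show the
back-to-front hydrogen-bonding pattern.

`phore` implements that funnel as a tested, reusable library for
computational chemists: perception, matching, validation statistics and
geometric interaction classification are all explicit and configurable, and
a synthetic-data module generates every input deterministically so the
whole pipeline runs and is testable without any external download.

## The statistics at its core

Screening a decoy database of `D` molecules containing `A` known actives
and retrieving `Ht` hits of which `Ha` are active is summarised by

```
% yield  = 100·Ha/Ht                % ratio = 100·Ha/A
EF       = (Ha·D)/(Ht·A)            (enrichment factor)
GF       = [Ha·(3A+Ht)/(4·Ht·A)]·[1 − (Ht−Ha)/(D−A)]   (goodness of fit)
```

together with FN = A−Ha, FP = Ht−Ha and the ROC AUC over fit scores. The
GF numerator is typeset ambiguously in the source literature: the report
computes both the `(3A+Ht)` form and the `(3Ha+Ht)` variant (which is what
reproduces the published worked-example value) and flags the discrepancy.

A ligand *matches* a pharmacophore model when an injective, kind-compatible
assignment of model features to perceived ligand features exists whose
pairwise distances agree with the model's distance matrix within the summed
tolerance radii; the fit score is `max(0, 1 − RMSD/τ̄)` after optimal rigid
superposition (Kabsch), with `τ̄` the mean feature tolerance.

## Worked example

```python
from phore import synthetic, screen_library, gh_metrics, DecoySetCounts

model = synthetic.reference_model()          # 2×HBD, 1×HBA, 2×HyP
lib = synthetic.make_library(
    model, synthetic.LibrarySpec(D=720, A=24, planted_Ht=26, planted_Ha=23, seed=42)
)
scored, hits = screen_library(model, lib)
counts = DecoySetCounts(
    D=len(scored.records),
    A=sum(1 for r in scored.records if r.active),
    Ht=len(hits),
    Ha=sum(1 for r in hits if r.active),
)
report = gh_metrics(counts)
print(report.display)
```

prints

```
{'yield_pct': 88, 'ratio_pct': 95.8, 'EF': 26.53, 'GF_eq': 0.9,
 'GF_alt': 0.87, 'FN': 1, 'FP': 3}
```

i.e. 88 % of the 26 retrieved hits are active, 95.8 % of the 24 actives are
recovered, retrieval is 26.5-fold enriched over the 3.3 % background active
rate, and the goodness-of-fit score is 0.87 (0.90 under the alternate
numerator — the report's `notes` field explains the difference).

The same objects drive the command line:

```bash
phore run --seed 1 --out run/        # full synthetic funnel
phore perceive --complex pose.pdb    # model from a real complex
phore screen --model model.json --library lib.sdf --out hits.csv
phore profile --complex pose.pdb     # H-bond/π/vdW table + verdict
```

## Layout

| module | contents |
| --- | --- |
| `phore.types` | `Atom`, `Molecule3D`, `ProteinLigandComplex`, pocket definitions |
| `phore.molecular_io` | PDB/SDF/MOL2/SMILES readers & writers, pharmacophore JSON, site extraction |
| `phore.pharmacophore` | feature perception, model enumeration, selectivity heuristic |
| `phore.screening` | ligand→model mapping, library screening |
| `phore.validation` | Güner-Henry metrics, ROC/AUC |
| `phore.druglikeness` | Lipinski Rule-of-5 profiling and filtering |
| `phore.interactions` | H-bond/π/alkyl/sulfur/vdW detection, type-II verdict |
| `phore.synthetic` | seeded generators: ligands, libraries, planted complexes |
| `phore.pipeline` / `phore.cli` | funnel orchestration and the `phore` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
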