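# Methods

This note documents the models, rules, parameters and design choices behind
`phore`, and what its synthetic benchmarks do and do not demonstrate.

## Pharmacophore perception

Perception chemistry is fixed and intentionally simple; commercial packages
use richer (closed) rule sets, so these rules are documented here in full.

**Ligand features.**

* *HBD*: every N/O/S atom bearing an explicit hydrogen, centred on the
  heavy atom. Explicit hydrogens are required (or `infer_h=True`, which
  falls back to open-valence inference) because donor identity is undefined
  without them.
* *HBA*: every N or O with an available lone pair — formal charge ≤ 0,
  excluding amide-type nitrogens (bonded to a carbonyl carbon) and
  3-coordinate aromatic nitrogens. Sulfur is deliberately not an acceptor,
  matching the classic Lipinski-style N/O convention.
* *HyP*: centroid of each aromatic ring (smallest rings of 5–7 atoms,
  out-of-plane RMS ≤ 0.1 Å), and centroid of each connected cluster of ≥ 3
  aliphatic carbons with no hetero-atom substituent.

**Receptor-complementary features.** Inside a binding site (residues with
any atom within the site radius of the ligand, boundary inclusive; default
10 Å), each receptor acceptor facing the ligand (≤ 6 Å from a ligand atom)
projects an HBD feature 2.9 Å along its lone-pair direction — the mean
heavy-neighbour direction, flipped toward the ligand centroid if needed —
with the acceptor position stored as the feature's projection point.
Receptor donors symmetrically project HBA features 2.9 Å along the D–H
direction. Hydrophobic side-chain carbon clusters (Ala/Val/Leu/Ile/Pro/
Phe/Met/Trp/Cys) project HyP features up to 4 Å toward the ligand centroid.
The ligand *centroid* (not the nearest atom) defines "toward the ligand" so
that perception is exactly covariant under rigid motion even when a
symmetric ligand makes the nearest atom ambiguous.

**Defaults.** Feature tolerance 1.6 Å (HBD/HBA) and 1.7 Å (HyP) — typical
pharmacophore sphere radii; configurable. Candidate models are all feature
subsets of size 4–5 (configurable within 3–7) whose members are pairwise
≥ 2 Å apart, the spacing floor preventing degenerate overlapping features.

**Selectivity.** The ranking score is an openly documented heuristic:
kind priors (HBD 2.0, HBA 2.0, HyP 1.5) plus 0.1 × mean inter-feature
distance. Only its *ordering* is meaningful — in particular every
5-feature model drawn from a pool outranks every 4-feature model, the
qualitative trend reported for receptor–ligand model rankings. No numeric
selectivity value from any external package is reproduced or targeted.

## Ligand–pharmacophore matching

Matching is single-conformer and rigid: conformer generation is the
caller's concern, and synthetic fixtures control geometry directly. The
search enumerates injective kind-compatible assignments depth-first,
pruning with the pairwise-distance feasibility test (|ligand distance −
model distance| ≤ sum of the two tolerances); every surviving assignment is
scored by Kabsch superposition RMSD of the assigned centroids and the
minimum wins, with lexicographic tie-breaking for bit-for-bit
reproducibility. All model features must be matched; partial mappings are
not hits. The pruned search is verified against a full permutation oracle
in the tests. Fit = max(0, 1 − RMSD/mean tolerance) ∈ [0, 1].

## Validation statistics

`gh_metrics` implements the decoy-set summary exactly as defined in the
README. Two display conventions deserve note:

* **GF numerator ambiguity.** The goodness-of-fit equation as printed in
  the source literature reads numerator `Ha·(3A+Ht)`, which evaluates to
  0.8992 on the worked-example counts (D=720, A=24, Ht=26, Ha=23), while
  the published table prints 0.87 — reproduced exactly by the `(3Ha+Ht)`
  variant (0.8716). Both are computed (`GF_eq`, `GF_alt`), the report's
  `notes` field states the discrepancy, and nothing is silently resolved.
* **Display rounding.** To match the published table's figures, the
  display block floors the yield to an integer, truncates the ratio to one
  decimal and EF to two, and rounds GF to two; full-precision raw values
  are always retained alongside.

ROC curves use a standard threshold sweep (scikit-learn) with trapezoidal
AUC, which equals the Mann–Whitney pair statistic with ties counted ½ — an
identity asserted to 1e-12 in the tests against an explicit pair-counting
oracle.

## Rule-of-5 profiling

MW from standard atomic weights, logP by the Wildman–Crippen atom
contribution scheme, HBD = O-H/N-H hydrogen count, HBA = N+O count,
rotatable bonds = non-ring single bonds between non-terminal heavy atoms
with amide C–N excluded (descriptors via RDKit on the hydrogen-collapsed
graph). All five thresholds (mw < 500, logP < 5, HBD < 5, HBA < 10,
rotatable < 10) are applied as strict inequalities by default, following
the source wording ("less than"); `strict=False` switches to ≤. The
"500 kDa" figure in the source text is read as 500 Da, the universal
Rule-of-5 threshold. Proprietary ADMET descriptor models are deliberately
not implemented; the pipeline accepts an external ADMET table instead.

## Interaction profiling

Contacts are classified geometrically; the distance windows are not taken
from any disclosed algorithm (the commercial monitor's cutoffs are closed)
but chosen to bracket the distances actually reported for docked type-II
VEGFR-2 poses, and every one is configurable:

| category | rule | default |
| --- | --- | --- |
| hydrogen bond | donor–acceptor heavy distance, D–H…A ≥ 120° when H explicit | < 3.0 Å |
| π–π stacked | ring-centroid distance, interplanar angle ≤ 30° | ≤ 5.5 Å |
| π–π T-shaped | centroid distance, angle 60–120° | ≤ 6.0 Å |
| π–cation | cation (formal charge > 0) to ring centroid | ≤ 6.0 Å |
| π–σ | sp³ C–H with the H within 30° of the C→centroid line; H…centroid | ≤ 4.0 Å |
| π–alkyl | sp³ carbon (or Cys/Met sulfur) to ring centroid | ≤ 5.5 Å |
| alkyl–alkyl | closest sp³-carbon pair per residue/cluster | ≤ 5.5 Å |
| sulfur–X | divalent S to electron-rich N/O/S | ≤ 3.6 Å |
| vdW | any heavy–heavy pair, residues with no other record | ≤ 4.0 Å |

Hydrogen-bond records carry both the heavy-atom and the H…acceptor
distance when the hydrogen is explicit, because published interaction
tables mix the two conventions; the table writer prints whichever a flag
selects. Category assignment is mutually exclusive per (receptor unit,
ligand unit) pair with precedence hydrogen bond > π classes (in the table's
order) > vdW, and alkyl-type contacts are aggregated per residue/cluster at
the minimum distance so one physical contact yields one record.

The **type-II verdict** partitions hydrogen bonds by front-pocket
(Glu917/Cys919) and back-pocket (Glu885/Asp1046) membership — residue
numbering follows the VEGFR-2 kinase-domain author numbering, and the
pocket definition is a plain data object so the classifier transfers to
other kinases. `is_back_to_front` is true iff both partitions are
non-empty.

## Synthetic data

The generators exist to make every pipeline stage testable with exact,
known ground truth:

* **Matcher ligands** are valence-correct fragment assemblies — one group
  per model feature, each expressing exactly one feature kind under the
  perception rules: methanethiol (S–H donates, S never accepts) for HBD,
  formaldehyde (carbonyl O, no H) for HBA, cyclopropane (3-carbon
  aliphatic cluster) for HyP. Groups sit exactly on the model centroids,
  each displaced rigidly by a seeded vector of length `jitter`, which
  bounds the post-superposition RMSD by the jitter itself. Fragments are
  deliberately disconnected: a connecting scaffold would add uncontrolled
  features and void the exactness guarantees. Methane is the inert filler
  for kind-violation decoys; distance-violation decoys displace one group
  by 2×diameter + 2×tolerance + 3.1 Å, provably breaking every assignment.
* **Libraries** plant the confusion counts exactly: `planted_Ha` actives
  and `planted_Ht − planted_Ha` inactives are built as matchers (jitter
  drawn in [0.02, 0.3] Å, far inside the tolerance budget), the rest as
  decoys, shuffled by seed. Screening therefore measures — not assumes —
  the planted (D, A, Ht, Ha).
* **Toy complexes** place one residue-fragment/ligand-group pair per
  requested contact on a circle wide enough (chord ≥ 8 Å, beyond every
  detection window) that no unplanted cross-contact can appear; each
  planted distance/angle is realized in closed form, exact to float
  precision. A spec that forces assemblies within 2 Å raises a
  geometric-infeasibility error.
* The default decoy-set composition (D=720, A=24, Ht=26, Ha=23) mirrors
  the published validation run this package emulates; the pose benchmark
  (26 docked hits, 7 back-to-front) mirrors its reported funnel outcome.

All randomness uses numpy's Philox counter-based generator keyed by the
caller's seed — never the platform default — so output is byte-identical
across runs and platforms.

**What passing synthetic tests shows — and does not.** The generators
prove the *machinery*: perception rules fire as specified, the matcher is
exact against brute force, planted statistics are recovered, detectors
report planted geometry to 1e-6 Å. They do not emulate real screening
libraries (no property-matched decoys, no conformational flexibility, no
tautomers/protomers) or real poses (no strain, no water-mediated bridges),
so performance numbers on synthetic data say nothing about prospective
enrichment on a real target.

## Numerical choices and degenerate inputs

* Superposition via scipy's quaternion-based `align_vectors`; RMSD ties
  broken lexicographically on the assignment tuple.
* Distance matrices are validated for symmetry, zero diagonal and the
  triangle inequality (tolerance 1e-6 Å) on construction.
* Site extraction uses an inclusive boundary (≤ radius), the common
  reading of "within".
* PDB input: author residue numbering preserved verbatim; insertion codes
  rejected loudly; bonds inferred from covalent radii (+0.4 Å slack);
  aromaticity reconstructed from planar 5–7 rings of C/N (RMS ≤ 0.1 Å)
  plus standard side-chain templates, since PDB files carry neither bonds
  nor aromatic flags. Saturated rings (chairs, cyclopropane) fail the
  planarity or size test and stay aliphatic.
* Undefined decoy-set denominators (Ht=0, A=0, D=A) raise
  `UndefinedMetricError` naming the offending quantity rather than
  returning NaN.

## Known limitations

* Single-conformer matching only; a flexible ligand that could match after
  torsional adjustment is scored as-is.
* No excluded-volume spheres or shape penalties in matching.
* Halogen bonds and water-mediated bridges are not detected.
* The PDB aromaticity reconstruction can mislabel genuinely planar
  saturated rings (rare) and does not kekulize.
* Lipinski HBA counts N+O; lone-pair-based acceptor counting would differ
  for e.g. amide nitrogens.
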