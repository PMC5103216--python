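# Methods

## Scope

`gpr139pharm` is a ligand-based virtual-screening toolkit built around the
agonist chemotype of the orphan G protein-coupled receptor GPR139: two
terminal aromatic systems (R1, R2) joined by a six-atom polar linker with
carbonyls at positions 1 and 4 and an N–H at position 2. The package
reconstructs the published seven-feature pharmacophore hypothesis from
that chemotype, screens conformer ensembles against it, validates the
screen with property-matched decoys and ROC/enrichment statistics, and
profiles CNS-penetration properties.

## The pharmacophore model

The hypothesis has composition AAADHRR — three hydrogen-bond acceptors
(A2, A3, A4), one donor (D5), one hydrophobic/halogen element (H6) and two
aromatic rings (R1, R2) — at six spatial positions:

| site  | anchored on (reference agonist 1a)      | kind(s)                     |
|-------|------------------------------------------|-----------------------------|
| A3    | linker 1-carbonyl oxygen                 | acceptor                    |
| D5    | linker 2-position N–H                    | donor                       |
| A4    | linker 4-carbonyl oxygen                 | acceptor                    |
| A2/H6 | 3-substituent of the R1 ring (3-OMe O)   | acceptor or hydrophobic/halogen |
| R1    | proximal aryl ring centroid              | aromatic ring               |
| R2    | distal naphthyl ring centroid            | aromatic ring               |

A2 and H6 are *co-located*: the 3-position of R1 tolerates either an
acceptor (methoxy oxygen) or a hydrophobic/halogen element (chlorine), so
a single feature of either kind within tolerance anchors both labels and
contributes two matched sites. This is what makes the seven-site
self-match of 1a attainable with six spatial positions.

The model is rebuilt programmatically at run time from the reconstructed
1a structure: conformers are embedded with a pinned seed (139), the
global-minimum non-collapsed conformation is selected, and site positions
are copied from the perceived features. Coordinates are therefore
reproducible within the package for a fixed RDKit version, but are not
bit-identical to any external tool's model.

**Exclusion volumes.** Seven curated spheres (radius 1.2 Å) encode the
substituent positions that abolished activity in inactive analogues: the
third substituent atoms of R1 positions 2, 3 and 5; the region around
linker position 3 (no room for bulk); and R2 ring positions 4, 5 and 7.
They are constructed geometrically from the reference conformer (ring
atom + outward radial offset: 3.7 Å for the R1 third atoms, 2.5 Å for the
R2 first substituent atoms, 2.2 Å along the linker 3-N–H direction) and
any sphere that would clash the reference active's own heavy atoms is
dropped. `derive_exclusion_volumes` additionally derives spheres from
aligned active/inactive sets: a sphere is placed at every inactive heavy
atom farther than radius + margin (default 0.5 Å) from all active heavy
atoms and outside all site tolerance spheres.

**Site tolerance (default 0.7 Å).** The tolerance is calibrated once from
the model's structural discrimination requirement: the des-5-nitrogen
analogue of 1a (a 5-atom linker, inactive in the assay) must not achieve a
full seven-site match, while the reference self-match and the partial
matches of genuine actives must survive. On our geometry the shortened
linker needs per-site residuals of ≥ 0.8 Å for a seventh site, whereas
legitimate six-site fits sit at ≤ 0.1 Å; 0.7 Å separates the regimes with
margin. The tolerance is a per-site parameter and can be overridden.

## Conformer ensembles

Distance-geometry embedding (ETKDGv3) followed by MMFF94 minimization
(UFF fallback), with the sampling caps used in screening-database
preparation: at most 100 conformers, at most 10 per rotatable bond, a
6.0 kcal/mol relative strain-energy window, and near-duplicate removal at
0.5 Å heavy-atom RMSD. Energies are relative to the ensemble minimum and
comparable only within one molecule. Per-molecule embedding seeds are
derived from the policy seed and the molecule id by hashing, so screens
are deterministic and insensitive to library order. The reference
("global energy non-collapsed") conformation is the lowest-energy
conformer in which no heavy-atom pair at least four bonds apart lies
closer than 2.0 Å through space; "non-collapsed" is not defined precisely
in the source protocol, and this clash predicate is our operationalization.

## Feature perception

A fixed, versioned substructure table (shipped as package data,
`feature_patterns.tsv`, version v1) defines acceptors (carbonyl,
ether/hydroxyl oxygen, pyridine-type and sp2/sp3 amine nitrogen — amide,
anilide and pyrrole-type nitrogens excluded), donors (N–H, O–H),
halogens (Cl/Br/I on aromatic carbon, dual-typed as hydrophobic) and
hydrophobic points (halogens on carbon, plus centroids of ≥ 2 contiguous
carbons bonded only to carbon/hydrogen). Aromatic 5/6-rings contribute
centroid features with unit normals. Two conventions matter downstream:
amide N–H counts as a donor (so D5 exists on the linker), and
methoxy/dioxole ether oxygen counts as an acceptor (so the 3-OMe of 1a
can occupy A2). Ring normals are currently not scored by the matcher — no
angular tolerances are published — but are emitted for future use.

## Matching and fitness

For each conformer, the matcher enumerates injective assignments between
site locations and type-compatible features, for every location subset
whose matched-site weight is at least `min_match` (default 4, the
screening protocol's partial-match floor; the dual A2/H6 location weighs
2). Assignments are pruned by the pairwise-distance necessary condition
|d(fᵢ,fⱼ) − d(sᵢ,sⱼ)| ≤ tolᵢ + tolⱼ, rigidly aligned by Kabsch
superposition, and accepted only if every matched feature falls within
its site tolerance. Poses with any heavy atom inside an exclusion sphere
are rejected (a molecule with only such poses is reported `excluded`,
fitness 0). Among valid candidates the matcher prefers more matched
sites, then lower RMSD, then the earliest conformer, then the
lexicographically smallest correspondence — fully deterministic.

The fitness surrogate is

    fitness = matched_count / 7 + max(0, 1 − rmsd / 2.0)   ∈ [0, 2]

which preserves the two published ranking drivers (more sites preferred;
tighter fit preferred). The original tool's 0–3 composite fitness is
proprietary and is not reproduced. Note one consequence: fitness is not
globally monotone in the site tolerance — shrinking the tolerance can
drop a site yet leave a much tighter partial fit. The monotone quantities
are the matched count, and the RMSD at fixed matched count.

## Properties

PSA is the Ertl atom-contribution topological PSA; it reproduces both
printed reference values (88.70 Å² for 1a, 76.7 Å² for 1s) and doubles as
the transcription guard for the reference fixtures. logP is the Crippen
atom-contribution estimate and logS the ESOL (Delaney) regression; both
are open surrogates for proprietary calculators and are labelled as such
in reports — no published value is claimed for them. The Hitchcock CNS
criteria are evaluated as strict inequalities exactly as printed
(N+O < 5, ClogP − (N+O) > 0, PSA < 90 Å², MW < 450); boundary values
fail. The solubility window is −6 ≤ logS ≤ −1 with logP < 3.5 desired
for CNS exposure.

## Synthetic benchmark

No machine-readable compound deck is published, so the benchmark is
generated:

* **Actives** sample the scaffold grammar — R1 ∈ {3,5-dimethoxyphenyl,
  3-chlorophenyl, benzodioxole, 1-ethyl-2-methyl-benzimidazole,
  1H-benzimidazole}, linker positions 3 and 5 ∈ {N–H, CH₂}, R2 ∈
  {naphthalen-2-yl, 1-phenylethyl, tetrahydronaphthalenyl,
  tetrahydroquinolinyl, thiochromanyl, indanyl} — without replacement
  (120 base combinations, then benzylic position-6 variants). The
  three-ring naphtho[2,1-b]furan R2 bioisostere is excluded by default
  (its feature mapping to the single R2 ring site is ambiguous) and
  available behind `include_naphthofuran`.
* **Inactives** carry exactly one tagged SAR violation: linker shortened
  to 5 atoms, extended to 7+, 1-carbonyl oxygen removed, 2-N methylated,
  bulk at linker position 3, or ethyloxy-type bulk at the R1 2-position.
  Inactives are guaranteed structurally disjoint from the active grammar.
* **Decoy candidates** are assembled from an unrelated fragment pool
  (compact core–connector–core or extended five-part chains), targeted at
  each active's property windows using the exact additivity of fragment
  masses and donor counts under fragment joining, and rejection-checked:
  full property windows versus the assigned anchor, Morgan-Tanimoto
  < 0.35 to every active, no instance of the agonist linker motif.
  Decoy selection (DUD-E-style windows |ΔMW| ≤ 25, |ΔlogP| ≤ 1,
  |ΔHBD| ≤ 1, |ΔHBA| ≤ 2, |Δrot| ≤ 2, equal formal charge) assigns each
  active its nearest eligible candidates round-robin, scarcest anchor
  first, with no decoy reused.

Default set sizes mirror the published validation: 126 actives, 30
inactives, 50 decoys per active (6300 decoys) from a 20 000-candidate
pool. What the generator does *not* emulate: assay noise in the labels,
tautomeric/protonation heterogeneity of vendor libraries, and the
structural idiosyncrasy of real inactive analogues — passing benchmarks
show the pipeline's internal consistency and discrimination on this
chemotype, not prospective performance on a vendor deck.

## Validation statistics

ROC analysis follows the published convention: actives are compared
against the property-matched decoys, while the SAR-violating inactives —
whose role is to test the exclusion volumes — are summarized separately
(fraction scoring below the median active). AUC is the tie-averaged
Mann–Whitney rank statistic; the ROC curve is swept over descending
scores with tie groups stepped jointly, so trapezoidal integration of
the curve equals the rank statistic (both are computed and cross-checked
in tests). Enrichment at fraction x uses the
top ⌈xN⌉ molecules with *pessimistic* tie handling (decoys outrank
actives within a tie group), reports EF(x) = recall/x and the percentage
of top slots occupied by actives, and `fraction_to_recall(r)` is the
smallest screened fraction reaching recall r. No BEDROC/bootstrap
intervals are provided.

## Problem sizes in the routine test suite

The default test run exercises the full 126-active / 6300-decoy selection
arithmetic, and screens the benchmark at a routine scale chosen for a
desk machine: 126 actives + 30 inactives + 20 decoys/active (seed 1) with
6 conformers per molecule and 60 minimization steps. At this scale the
screen yields AUC ≈ 0.96 and EF(1%) ≈ 20, with roughly two thirds of the
SAR-violating inactives scoring below the median active. The full
50-decoys-per-active screen at any seed is available through
`gpr139pharm benchmark --seed N --out DIR`.

## Known limitations

* Model coordinates depend on the RDKit/MMFF version used to embed the
  pinned reference conformer; hypotheses written to JSON are portable,
  the in-session rebuild is not guaranteed bit-stable across RDKit
  releases.
* Aromatic sites match centroids only; ring-plane orientation is ignored.
* Conformational flexibility is handled entirely by the ensemble; there
  is no on-the-fly torsional refinement during alignment.
* Energies are relative within one molecule; no cross-molecule strain
  comparison is meaningful.
* Tautomer handling is canonical-tautomer normalization only, and the
  fixed protonation rule table (carboxylic acids deprotonated, aliphatic
  amines protonated, heteroaromatics neutral) approximates pH 7.4 without
  pKa calculation.
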