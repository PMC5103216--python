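# gpr139pharm

Ligand-based pharmacophore modelling and virtual screening for agonists of
GPR139, an orphan class A G protein-coupled receptor expressed mainly in
the hypothalamus and striatum and discussed as a target in Parkinson's
disease and metabolic disorders.

All published GPR139 surrogate agonist series share one chemotype: two
terminal aromatic systems, R1 and R2, joined by a six-atom polar linker

    R1 – C(=O) – NH – X3 – C(=O) – X5 – X6(R2)        X3, X5 ∈ {NH, CH2}

with critical hydrogen-bond acceptors at the two carbonyls (features A3,
A4), a donor at the 2-position N–H (D5), a dual hydrophobic/halogen-or-
acceptor element at the R1 3-position (H6/A2), and the two aromatic rings
(R1, R2) — the seven-feature **AAADHRR** pharmacophore. This package
implements that model end to end:

* reconstruction of the reference agonists (1a, 1s, 7c, the inactive
  des-5-N analogue, L-Trp/L-Phe) from their structure–activity
  description, with the printed PSA values as transcription guards;
* bounded conformer-ensemble generation (ETKDG + MMFF94; ≤ 100
  conformers, ≤ 10 per rotatable bond, 6 kcal/mol window);
* deterministic feature perception from a versioned substructure table;
* the packaged GPR139 hypothesis with curated exclusion volumes, plus
  derivation of exclusion volumes from aligned actives/inactives;
* ensemble screening with partial matching (≥ 4 of 7 sites), Kabsch
  alignment, exclusion checks and the fitness score
  `matched/7 + max(0, 1 − rmsd/2)`;
* DUD-E-style property-matched decoy selection and ROC / enrichment
  statistics;
* CNS property profiling: topological PSA, Crippen logP and ESOL logS
  surrogates, the four Hitchcock criteria (N+O < 5, ClogP − (N+O) > 0,
  PSA < 90 Å², MW < 450);
* a synthetic benchmark generator (grammar actives, tagged SAR-violating
  inactives, drug-like decoy candidates) so the whole pipeline is testable
  without any download.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

```python
from gpr139pharm import (
    ConformerPolicy, compute_profile, generate_conformers, hitchcock, match,
)
from gpr139pharm.chem import reference_compound
from gpr139pharm.hypothesis import gpr139_model

model = gpr139_model()                      # rebuilt from 1a, pinned seed
mol = generate_conformers(reference_compound("1a"), ConformerPolicy(seed=139))
result = match(mol, model)
profile = compute_profile(mol)
verdict = hitchcock(profile)
print(f"matched {result.matched_count}/7 sites, rmsd {result.rmsd:.3f} A, "
      f"fitness {result.fitness:.3f}")
print(f"PSA {profile.psa:.2f} A^2, MW {profile.mw:.1f}, N+O {profile.n_plus_o}")
print(f"Hitchcock: N+O<5 {verdict.c1}, PSA<90 {verdict.c3}, MW<450 {verdict.c4}")
```

prints

```
matched 7/7 sites, rmsd 0.000 A, fitness 2.000
PSA 88.69 A^2, MW 365.4, N+O 7
Hitchcock: N+O<5 False, PSA<90 True, MW<450 True
```

The reference agonist matches its own model perfectly (all seven sites at
zero RMSD, the fitness maximum of 2.0). Its topological PSA of 88.69 Å²
sits just under the 90 Å² blood–brain-barrier heuristic, but with seven
N+O atoms it fails the strictest CNS atom-count criterion — the same
property tension reported for this series.

The command line mirrors the pipeline stages:

```bash
gpr139pharm synth --actives 126 --inactives 30 --candidates 20000 --seed 7 --out bench/
gpr139pharm screen --library bench/actives.csv --hypothesis packaged:gpr139 --out report.csv
gpr139pharm props --library bench/actives.csv --out props.csv
gpr139pharm benchmark --seed 1 --out run1/       # full generate→screen→validate
```

`benchmark` writes `summary.json` (AUC, EF, recall fractions, Hitchcock
pass rates), `report.csv` (the ranked screen) and a `manifest.json` that
reproduces the run byte-for-byte.

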