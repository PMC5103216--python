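"""Synthetic benchmark generation from the GPR139 agonist scaffold grammar.

Actives are assembled from the validated chemotype: an R1 aromatic system
and an R2 system joined by a six-atom polar linker (1 = C(=O), 2 = N-H,
3 ∈ {N-H, CH2}, 4 = C(=O), 5 ∈ {N-H, CH2}, 6 ∈ {aromatic C of R2, CH2,
CH(CH3)}), with R1/R2 drawn from the published parent moieties and their
bioisosteres.  Inactives are grammar molecules carrying exactly one
structure-activity violation (tagged).  Decoy candidates are drug-like
molecules assembled from an unrelated fragment pool, rejection-sampled into
the actives' property windows while guaranteed topologically dissimilar and
free of the agonist grammar.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem, DataStructs

from .chem import Molecule, mol_from_smiles
from .props import PropertyProfile, compute_profile
from .screen import morgan_fingerprint
from .validate import DecoyWindows

GRAMMAR_VERSION = "v1"

# The full agonist grammar as a substructure query: aryl-C(=O)-NH-X3-C(=O)-X5-X6
GRAMMAR_SMARTS = Chem.MolFromSmarts(
    "[c]-[CX3](=[OX1])-[NX3H1]-[$([NX3H1]),$([CX4H2])]-[CX3](=[OX1])"
    "-[$([NX3H1]),$([CX4H2])]-[$([c]),$([CX4H2]),$([CX4H1])]"
)

_R1_POOL: dict[str, str] = {
    "dimethoxyphenyl": "[*:1]c1cc(OC)cc(OC)c1",
    "chlorophenyl": "[*:1]c1cccc(Cl)c1",
    "benzodioxole": "[*:1]c1ccc2OCOc2c1",
    "et-me-benzimidazole": "[*:1]c1ccc2c(c1)nc(C)n2CC",
    "benzimidazole": "[*:1]c1ccc2[nH]cnc2c1",
}

# R2 systems; aromatic-attached entries place linker position 6 on the ring,
# the phenylethyl entry carries an aliphatic CH(CH3) as position 6.
_R2_POOL: dict[str, tuple[str, bool]] = {
    "naphthalenyl": ("[*:2]c1ccc2ccccc2c1", True),
    "phenylethyl": ("[*:2]C(C)c1ccccc1", False),
    "tetrahydronaphthalenyl": ("[*:2]c1ccc2c(c1)CCCC2", True),
    "tetrahydroquinolinyl": ("[*:2]c1ccc2c(c1)CCCN2", True),
    "thiochromanyl": ("[*:2]c1ccc2c(c1)CCCS2", True),
    "indanyl": ("[*:2]c1ccc2c(c1)CCC2", True),
}

_NAPHTHOFURAN = ("[*:2]c1ccc2ccc3ccoc3c2c1", True)  # behind a config flag


@dataclass(frozen=True)
class ScaffoldGrammar:
    """The generative grammar of the agonist chemotype."""

    r1_pool: tuple[str, ...] = tuple(_R1_POOL)
    r2_pool: tuple[str, ...] = tuple(_R2_POOL)
    x3_choices: tuple[str, ...] = ("N", "C")
    x5_choices: tuple[str, ...] = ("N", "C")
    include_naphthofuran: bool = False
    include_benzylic: bool = True  # CH2-inserted position-6 variants
    version: str = GRAMMAR_VERSION

    def r1_smiles(self, name: str) -> str:
        return _R1_POOL[name]

    def r2_smiles(self, name: str) -> tuple[str, bool]:
        if name == "naphthofuran":
            return _NAPHTHOFURAN
        return _R2_POOL[name]

    def r2_names(self) -> tuple[str, ...]:
        names = self.r2_pool
        if self.include_naphthofuran:
            names = names + ("naphthofuran",)
        return names


def _assemble(r1: str, linker: str, r2: str) -> Chem.Mol | None:
    combined = Chem.MolFromSmiles(f"{r1}.{linker}.{r2}")
    if combined is None:
        return None
    try:
        mol = Chem.molzip(combined)
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def matches_grammar(mol: Chem.Mol) -> bool:
    """True if the molecule contains the full agonist 6-atom linker motif."""
    return mol.HasSubstructMatch(GRAMMAR_SMARTS)


def _active_combos(grammar: ScaffoldGrammar) -> list[tuple[str, str, str, str, str]]:
    """(combo_id, r1, x3, x5, r2_variant) for the base cross product plus
    benzylic (CH2-inserted) decorated variants of aromatic-attached R2s."""
    combos = []
    for r1 in grammar.r1_pool:
        for x3 in grammar.x3_choices:
            for x5 in grammar.x5_choices:
                for r2 in grammar.r2_names():
                    combos.append((f"{r1}|{x3}{x5}|{r2}", r1, x3, x5, r2))
    if grammar.include_benzylic:
        for r1 in grammar.r1_pool:  # decorated: position 6 = CH2, ring pushed out
            for x3 in grammar.x3_choices:
                for x5 in grammar.x5_choices:
                    for r2 in grammar.r2_names():
                        if grammar.r2_smiles(r2)[1]:
                            combos.append((f"{r1}|{x3}{x5}|{r2}-bn", r1, x3, x5, f"{r2}-bn"))
    return combos


def _build_active(grammar: ScaffoldGrammar, r1: str, x3: str, x5: str, r2: str) -> Chem.Mol | None:
    benzylic = r2.endswith("-bn")
    r2_smiles, _aromatic = grammar.r2_smiles(r2[:-3] if benzylic else r2)
    if benzylic:
        r2_smiles = r2_smiles.replace("[*:2]", "[*:2]C", 1)
    linker = f"[*:1]C(=O)N{x3}C(=O){x5}[*:2]"
    return _assemble(grammar.r1_smiles(r1), linker, r2_smiles)


def generate_actives(
    n: int, seed: int, grammar: ScaffoldGrammar | None = None
) -> list[Molecule]:
    """Generate ``n`` unique grammar-conforming active-like molecules.

    Combinations of R1 x linker variant x R2 are sampled without
    replacement (base cross product first, then benzylic decorated
    variants).  Every output satisfies the grammar invariant: a six-atom
    linker with carbonyls at positions 1 and 4 and N-H at position 2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grammar = grammar or ScaffoldGrammar()
    combos = _active_combos(grammar)
    if n > len(combos):
        raise ValueError(f"grammar supports at most {len(combos)} distinct actives")
    rng = random.Random(seed)
    order = list(combos)
    rng.shuffle(order)
    out: list[Molecule] = []
    seen: set[str] = set()
    for combo_id, r1, x3, x5, r2 in order:
        mol = _build_active(grammar, r1, x3, x5, r2)
        if mol is None or not matches_grammar(mol):
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        seen.add(smiles)
        record = Molecule(f"ACT-{len(out):03d}", mol)
        record.mol.SetProp("combo", combo_id)
        out.append(record)
        if len(out) == n:
            break
    if len(out) < n:
        raise RuntimeError(f"could only generate {len(out)} of {n} actives")
    return out


# ---------------------------------------------------------------------------
# Inactives: one SAR violation each
# ---------------------------------------------------------------------------

VIOLATION_CLASSES = (
    "short_linker",  # (a) linker shortened to 5 atoms (des-5 analogue)
    "long_linker",  # (b) linker extended to 7 atoms
    "no_carbonyl_o",  # (c) 1-carbonyl oxygen removed
    "n2_methylated",  # (d) donor at position 2 blocked by methylation
    "bulk_at_3",  # (e) bulky substituent on linker position 3
    "r1_ethyloxy",  # (f) ethyloxy-type bulk on the R1 2-position
)

_R1_ETHYLOXY = "[*:1]c1c(OCC)c(OC)cc(OC)c1"


def _build_inactive(
    grammar: ScaffoldGrammar, violation: str, r1: str, x3: str, x5: str, r2: str
) -> Chem.Mol | None:
    benzylic = r2.endswith("-bn")
    r2_smiles, aromatic = grammar.r2_smiles(r2[:-3] if benzylic else r2)
    if benzylic:
        r2_smiles = r2_smiles.replace("[*:2]", "[*:2]C", 1)
    r1_smiles = grammar.r1_smiles(r1)
    if violation == "short_linker":
        linker = f"[*:1]C(=O)N{x3}C(=O)[*:2]"
    elif violation == "long_linker":
        # must exceed any 6-atom active topology, including the benzylic
        # variants in which position 6 is already an aliphatic CH2
        extension = "CC" if (aromatic and not benzylic) else "C"
        linker = f"[*:1]C(=O)N{x3}C(=O){x5}{extension}[*:2]"
    elif violation == "no_carbonyl_o":
        linker = f"[*:1]CN{x3}C(=O){x5}[*:2]"
    elif violation == "n2_methylated":
        linker = f"[*:1]C(=O)N(C){x3}C(=O){x5}[*:2]"
    elif violation == "bulk_at_3":
        linker = f"[*:1]C(=O)NN(C(C)C)C(=O){x5}[*:2]"
    elif violation == "r1_ethyloxy":
        linker = f"[*:1]C(=O)N{x3}C(=O){x5}[*:2]"
        r1_smiles = _R1_ETHYLOXY
    else:
        raise ValueError(f"unknown violation class: {violation}")
    return _assemble(r1_smiles, linker, r2_smiles)


def generate_inactives(
    n: int, seed: int, grammar: ScaffoldGrammar | None = None
) -> list[Molecule]:
    """Generate ``n`` inactive analogues, each an active-grammar molecule
    with exactly one SAR violation; the violation class is recorded in the
    molecule's ``violation`` property (and parent combo in ``parent``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grammar = grammar or ScaffoldGrammar()
    combos = _active_combos(grammar)
    # label disjointness: an inactive may never coincide with a structure
    # the active grammar can emit
    active_space = {
        Chem.MolToSmiles(m)
        for m in (_build_active(grammar, r1, x3, x5, r2) for _cid, r1, x3, x5, r2 in combos)
        if m is not None
    }
    rng = random.Random(seed)
    out: list[Molecule] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 100 * n:
        attempts += 1
        violation = VIOLATION_CLASSES[len(out) % len(VIOLATION_CLASSES)]
        combo_id, r1, x3, x5, r2 = rng.choice(combos)
        mol = _build_inactive(grammar, violation, r1, x3, x5, r2)
        if mol is None:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen or smiles in active_space:
            continue
        seen.add(smiles)
        record = Molecule(f"INA-{len(out):03d}", mol)
        record.mol.SetProp("violation", violation)
        record.mol.SetProp("parent", combo_id)
        out.append(record)
    if len(out) < n:
        raise RuntimeError(f"could only generate {len(out)} of {n} inactives")
    return out


def violation_tag(molecule: Molecule) -> str:
    return molecule.mol.GetProp("violation") if molecule.mol.HasProp("violation") else ""


# ---------------------------------------------------------------------------
# Decoy candidates
# ---------------------------------------------------------------------------

_DECOY_CORE1 = (
    "[*:1]c1ccccc1", "[*:1]c1ccc(F)cc1", "[*:1]c1ccc(Cl)cc1", "[*:1]c1cccc(OC)c1",
    "[*:1]c1ccc(C)cc1", "[*:1]c1cccnc1", "[*:1]c1ccncc1", "[*:1]c1cccs1",
    "[*:1]c1cnn(C)c1", "[*:1]c1ccc2ncccc2c1", "[*:1]c1ccc2occc2c1",
    "[*:1]c1cccc(C(F)(F)F)c1", "[*:1]c1ccc(OC)c(OC)c1", "[*:1]c1ccc(C#N)cc1",
    "[*:1]c1ccc2ccccc2c1", "[*:1]c1ccc(Cl)c(Cl)c1", "[*:1]c1ccc(N)cc1",
    "[*:1]c1ccc2[nH]ccc2c1", "[*:1]c1ccc(O)cc1", "[*:1]c1ccc2[nH]ncc2c1",
    "[*:1]c1ccc2[nH]c(C)cc2c1", "[*:1]c1ccc2[nH]nc(C)c2c1",
    "[*:1]c1ccc(O)c(OC)c1", "[*:1]c1ccc(O)c(Cl)c1", "[*:1]c1cc(C)cc(O)c1",
    "[*:1]c1ccc(O)c(O)c1", "[*:1]c1cc(N)ccc1O", "[*:1]c1ccc2[nH]c(N)nc2c1",
)
_DECOY_CONN_A = (
    "[*:1]C(=O)N(C)[*:2]", "[*:1]C(=O)N[*:2]", "[*:1]NC(=O)[*:2]",
    "[*:1]S(=O)(=O)N[*:2]", "[*:1]CN[*:2]", "[*:1]OC[*:2]", "[*:1]C(=O)[*:2]",
    "[*:1]CO[*:2]", "[*:1]CC[*:2]", "[*:1]C(=O)O[*:2]", "[*:1]NC(=O)N[*:2]",
)
_DECOY_MIDDLE = (
    "[*:2]c1ccc([*:3])cc1", "[*:2]c1cccc([*:3])c1", "[*:2]C1CCN([*:3])CC1",
    "[*:2]CC[*:3]", "[*:2]C1CCC([*:3])CC1", "[*:2]c1ccc([*:3])cn1",
    "[*:2]CC(O)C[*:3]", "[*:2]C1CN([*:3])CCO1", "[*:2]CNC(=O)C[*:3]",
    "[*:2]c1ccc([*:3])cc1C", "[*:2]C(C)C[*:3]",
)
_DECOY_CONN_B = (
    "[*:3]C(=O)N[*:4]", "[*:3]NC(=O)[*:4]", "[*:3]O[*:4]", "[*:3]C[*:4]",
    "[*:3]N(C)[*:4]", "[*:3]S(=O)(=O)[*:4]", "[*:3]OC[*:4]", "[*:3]C(=O)[*:4]",
)
_DECOY_CORE2 = (
    "[*:4]c1ccccc1", "[*:4]C1CCCCC1", "[*:4]N1CCCCC1", "[*:4]N1CCOCC1",
    "[*:4]C1CCOCC1", "[*:4]c1ccc(O)cc1", "[*:4]c1ccc(N)cc1", "[*:4]C(N)=O",
    "[*:4]c1ccco1", "[*:4]CC(C)C", "[*:4]c1ccc(F)cc1", "[*:4]C1CCNC1",
    "[*:4]c1ccc(S(C)(=O)=O)cc1", "[*:4]c1ccc(C(F)(F)F)cc1",
    "[*:4]c1ccc2ncccc2c1", "[*:4]C1CCC(O)CC1", "[*:4]c1ccc(CO)cc1",
    "[*:4]N1CCC(C(N)=O)CC1", "[*:4]C", "[*:4]CCO", "[*:4]CC(N)=O",
    "[*:4]c1ccc(S(N)(=O)=O)cc1", "[*:4]C1CCCC1", "[*:4]c1ccc(Cl)cc1",
    "[*:4]c1ccc(NC(C)=O)cc1", "[*:4]CNC(N)=O", "[*:4]c1ccc(NC(N)=O)cc1",
    "[*:4]c1ccc2[nH]ccc2c1", "[*:4]C1CCC(NC(C)=O)CC1", "[*:4]c1ccc(CN)cc1",
    "[*:4]c1ccc(CNC(C)=O)cc1", "[*:4]c1ccc(NS(C)(=O)=O)cc1",
    "[*:4]c1ccc2[nH]c(=O)[nH]c2c1", "[*:4]c1ccc2c(c1)CC(=O)N2",
    "[*:4]c1ccc(C(=O)NC)cc1", "[*:4]c1ccc(NC(=O)C(C)C)cc1",
    "[*:4]c1ccc(N)cc1C(N)=O", "[*:4]c1ccc(O)cc1C(N)=O",
    "[*:4]c1ccc(NC(N)=O)c(C)c1", "[*:4]c1cc2[nH]c(=O)[nH]c2cc1C",
    "[*:4]c1ccc(NC(N)=O)cc1Cl",
)


@lru_cache(maxsize=None)
def _fragment_stats(smiles: str) -> tuple[float, int, int]:
    # dummy atoms have zero mass and occupy the junction valence, so
    # fragment molecular weight and donor counts are additive under molzip
    # (acceptor counts nearly so; exact windows are re-checked after assembly)
    from rdkit.Chem import Descriptors, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    return (
        Descriptors.MolWt(mol),
        rdMolDescriptors.CalcNumHBD(mol),
        rdMolDescriptors.CalcNumHBA(mol),
    )


def _assemble_decoy(
    rng: random.Random, anchor: PropertyProfile, windows: "DecoyWindows"
) -> Chem.Mol | None:
    """Assemble a candidate aimed at the anchor's property windows.

    Either a compact three-part (core-connector-core) or an extended
    five-part chain is built — compact assemblies are favoured for anchors
    with few rotatable bonds.  The terminal core is drawn from the
    fragments that close the additive mass/donor/acceptor balance.
    """
    compact_bias = 0.8 if anchor.rotatable_bonds <= 4 else 0.25
    if rng.random() < compact_bias:
        parts = [rng.choice(_DECOY_CORE1), rng.choice(_DECOY_CONN_A)]
        terminal_pool = [s.replace("[*:4]", "[*:2]") for s in _DECOY_CORE2]
    else:
        parts = [
            rng.choice(_DECOY_CORE1),
            rng.choice(_DECOY_CONN_A),
            rng.choice(_DECOY_MIDDLE),
            rng.choice(_DECOY_CONN_B),
        ]
        terminal_pool = list(_DECOY_CORE2)
    mw = hbd = hba = 0
    for p in parts:
        s = _fragment_stats(p)
        mw, hbd, hba = mw + s[0], hbd + s[1], hba + s[2]
    eligible = []
    for s in terminal_pool:
        fmw, fhbd, fhba = _fragment_stats(s)
        if (
            abs(mw + fmw - anchor.mw) <= windows.mw
            and abs(hbd + fhbd - anchor.hbd) <= windows.hbd
            and abs(hba + fhba - anchor.hba) <= windows.hba
        ):
            eligible.append(s)
    if not eligible:
        return None
    parts.append(rng.choice(eligible))
    combined = Chem.MolFromSmiles(".".join(parts))
    if combined is None:
        return None
    try:
        mol = Chem.molzip(combined)
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def generate_decoy_candidates(
    n: int,
    seed: int,
    anchors: list[Molecule],
    windows: DecoyWindows | None = None,
    max_attempt_factor: int = 200,
) -> list[Molecule]:
    """Generate a drug-like decoy candidate pool spanning the anchors'
    property windows.

    Candidates are assembled from an unrelated fragment pool and
    rejection-sampled: each must satisfy the property windows of the
    (cyclically assigned) anchor active, have Morgan Tanimoto < the cutoff
    to *every* anchor, and contain no instance of the agonist linker
    grammar.  Raises with an attrition report if the pool cannot be filled
    in bounded attempts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not anchors:
        raise ValueError("anchor active set is empty")
    windows = windows or DecoyWindows()
    anchor_profiles: list[PropertyProfile] = [compute_profile(a) for a in anchors]
    anchor_fps = [morgan_fingerprint(a.mol) for a in anchors]
    rng = random.Random(seed)
    out: list[Molecule] = []
    seen: set[str] = set()
    n_anchors = len(anchor_profiles)
    attempts_per_slot = max(1, max_attempt_factor)
    total_attempts = 0

    def try_anchor(anchor: PropertyProfile) -> Molecule | None:
        nonlocal total_attempts
        for _ in range(attempts_per_slot):
            total_attempts += 1
            mol = _assemble_decoy(rng, anchor, windows)
            if mol is None:
                continue
            smiles = Chem.MolToSmiles(mol)
            if smiles in seen:
                continue
            profile = compute_profile(Molecule("", mol))
            if not windows.satisfied(anchor, profile):
                continue
            if matches_grammar(mol):
                continue
            fp = morgan_fingerprint(mol)
            if max(DataStructs.BulkTanimotoSimilarity(fp, anchor_fps)) >= windows.tanimoto:
                continue
            seen.add(smiles)
            return Molecule(f"DEC-{len(out):05d}", mol)
        return None

    # each pool slot is tied to an anchor in round-robin order; a slot whose
    # anchor's windows are hard falls through to the following anchors so
    # generation can never stall on one pathological anchor
    for slot in range(n):
        accepted = None
        for offset in range(n_anchors):
            accepted = try_anchor(anchor_profiles[(slot + offset) % n_anchors])
            if accepted is not None:
                break
        if accepted is None:
            raise RuntimeError(
                f"decoy pool not reachable: {len(out)} of {n} candidates after "
                f"{total_attempts} attempts; no anchor window can be filled"
            )
        out.append(accepted)
    return out


# ---------------------------------------------------------------------------
# Benchmark set
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkSet:
    """A labelled synthetic benchmark; regeneration from (seed, grammar) is
    byte-identical."""

    actives: list[Molecule]
    inactives: list[Molecule]
    decoy_candidates: list[Molecule]
    seed: int
    grammar: ScaffoldGrammar = field(default_factory=ScaffoldGrammar)

    @classmethod
    def generate(
        cls,
        n_actives: int = 126,
        n_inactives: int = 30,
        n_candidates: int = 20000,
        seed: int = 7,
        grammar: ScaffoldGrammar | None = None,
    ) -> "BenchmarkSet":
        grammar = grammar or ScaffoldGrammar()
        actives = generate_actives(n_actives, seed, grammar)
        inactives = generate_inactives(n_inactives, seed + 1000003, grammar)
        candidates = generate_decoy_candidates(n_candidates, seed + 2000003, actives)
        return cls(actives, inactives, candidates, seed, grammar)

    @property
    def violation_tags(self) -> dict[str, str]:
        return {m.id: violation_tag(m) for m in self.inactives}
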