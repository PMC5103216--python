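"""Molecular structure model, library I/O and reference-compound fixtures.

Molecules are thin wrappers around RDKit graphs.  Conformers are stored on
the wrapped RDKit molecule (heavy atoms only) together with a parallel list
of relative strain energies in kcal/mol.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

EC50_CUTOFF_UM = 1.0  # activity cutoff: active iff EC50 <= 1 uM


@dataclass
class Conformer:
    """A single 3D conformation: heavy-atom coordinates (Å) and relative
    strain energy (kcal/mol, ensemble minimum = 0)."""

    coords: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("conformer coordinates must be an (n_atoms, 3) array")


@dataclass
class Molecule:
    """A molecule in the screening pipeline.

    Parameters
    ----------
    id : str
        Library-unique identifier.
    mol : rdkit.Chem.Mol
        Heavy-atom graph (implicit hydrogens); may carry 3D conformers.
    energies : list of float
        Relative conformer energies, parallel to ``mol``'s conformers,
        sorted non-decreasing.
    """

    id: str
    mol: Chem.Mol
    energies: list[float] = field(default_factory=list)

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def conformers(self) -> list[Conformer]:
        out = []
        for conf, e in zip(self.mol.GetConformers(), self.energies):
            out.append(Conformer(np.array(conf.GetPositions(), dtype=float), e))
        return out

    def copy(self, new_id: str | None = None) -> "Molecule":
        return Molecule(new_id or self.id, Chem.Mol(self.mol), list(self.energies))


@dataclass
class ActivityRecord:
    """Activity annotation: EC50 in μM (None = inactive), Emax in % and the
    derived active/inactive label (active iff EC50 <= cutoff)."""

    molecule_id: str
    ec50: float | None
    emax: float | None = None
    cutoff: float = EC50_CUTOFF_UM

    @property
    def label(self) -> str:
        if self.ec50 is not None and self.ec50 <= self.cutoff:
            return "active"
        return "inactive"


@dataclass
class RejectRecord:
    line: int
    id: str
    reason: str


@dataclass
class LibraryLoad:
    """Result of reading a molecule library: parsed molecules in input
    order, activity annotations (where present) and per-record rejects."""

    molecules: list[Molecule]
    activities: list[ActivityRecord]
    rejects: list[RejectRecord]

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)


def mol_from_smiles(smiles: str, mol_id: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` (raises ValueError on
    unparsable input)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES for {mol_id!r}: {smiles!r}")
    return Molecule(mol_id, mol)


def _parse_ec50(text: str) -> float | None:
    text = text.strip()
    if not text or text.upper() in {"NA", "NAN", "INACTIVE", "NONE"}:
        return None
    return float(text)


def read_library(path: str | Path, ec50_cutoff: float = EC50_CUTOFF_UM) -> LibraryLoad:
    """Read a molecule library from a SMILES table (.csv/.tsv/.smi) or an
    SDF file.

    SMILES tables need header columns ``id, smiles`` and may carry optional
    ``ec50`` (μM; "NA" = inactive) and ``emax`` (%) columns.  Invalid
    records are reported with their line numbers in the returned rejects
    list, never silently dropped.  Duplicate ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"library file not found: {path}")
    if path.suffix.lower() in {".sdf", ".sd", ".mol"}:
        return _read_sdf(path)
    return _read_table(path, ec50_cutoff)


def _read_table(path: Path, ec50_cutoff: float) -> LibraryLoad:
    delimiter = "\t" if path.suffix.lower() in {".tsv", ".smi", ".txt"} else ","
    molecules: list[Molecule] = []
    activities: list[ActivityRecord] = []
    rejects: list[RejectRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or not {"id", "smiles"} <= {
            f.strip().lower() for f in reader.fieldnames
        }:
            raise ValueError(f"{path}: header must contain columns 'id' and 'smiles'")
        for lineno, row in enumerate(reader, start=2):
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
            mol_id = row.get("id", "")
            smiles = row.get("smiles", "")
            if not mol_id or not smiles:
                rejects.append(RejectRecord(lineno, mol_id, "missing id or smiles"))
                continue
            if mol_id in seen:
                rejects.append(RejectRecord(lineno, mol_id, "duplicate id"))
                continue
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                rejects.append(RejectRecord(lineno, mol_id, f"unparsable SMILES: {smiles}"))
                continue
            seen.add(mol_id)
            molecules.append(Molecule(mol_id, mol))
            if "ec50" in row:
                try:
                    ec50 = _parse_ec50(row["ec50"])
                except ValueError:
                    rejects.append(RejectRecord(lineno, mol_id, f"bad ec50: {row['ec50']}"))
                    ec50 = None
                emax = None
                if row.get("emax"):
                    try:
                        emax = float(row["emax"])
                    except ValueError:
                        rejects.append(RejectRecord(lineno, mol_id, f"bad emax: {row['emax']}"))
                activities.append(ActivityRecord(mol_id, ec50, emax, cutoff=ec50_cutoff))
    return LibraryLoad(molecules, activities, rejects)


def _read_sdf(path: Path) -> LibraryLoad:
    molecules: list[Molecule] = []
    rejects: list[RejectRecord] = []
    by_base: dict[str, Molecule] = {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rejects.append(RejectRecord(i + 1, "", "unparsable SDF record"))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        base, _, suffix = name.partition("_conf")
        if suffix and base in by_base and mol.GetNumConformers():
            # additional conformer record for an already-seen molecule
            parent = by_base[base]
            conf = Chem.Conformer(mol.GetConformer())
            parent.mol.AddConformer(conf, assignId=True)
            parent.energies.append(float(mol.GetProp("energy")) if mol.HasProp("energy") else 0.0)
            continue
        energies = []
        if mol.GetNumConformers():
            energies = [float(mol.GetProp("energy")) if mol.HasProp("energy") else 0.0]
        record = Molecule(base if suffix else name, mol, energies)
        by_base[record.id] = record
        molecules.append(record)
    return LibraryLoad(molecules, [], rejects)


def write_library(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules to a SMILES table (.csv/.tsv) or a V2000 SDF.

    SDF output emits one record per conformer with ``<id>_confN`` names so
    that :func:`read_library` round-trips ids, graphs and conformer counts.
    """
    path = Path(path)
    molecules = list(molecules)
    if path.suffix.lower() in {".sdf", ".sd"}:
        writer = Chem.SDWriter(str(path))
        writer.SetForceV3000(False)
        for m in molecules:
            if m.mol.GetNumConformers() == 0:
                mol = Chem.Mol(m.mol)
                mol.SetProp("_Name", m.id)
                writer.write(mol)
            else:
                for ci, conf in enumerate(m.mol.GetConformers()):
                    mol = Chem.Mol(m.mol)
                    mol.SetProp("_Name", f"{m.id}_conf{ci}")
                    if ci < len(m.energies):
                        mol.SetProp("energy", repr(m.energies[ci]))
                    writer.write(mol, confId=conf.GetId())
        writer.close()
        return
    delimiter = "\t" if path.suffix.lower() in {".tsv", ".smi", ".txt"} else ","
    with open(path, "w", newline="") as fh:
        out = csv.writer(fh, delimiter=delimiter)
        out.writerow(["id", "smiles"])
        for m in molecules:
            out.writerow([m.id, m.smiles])


def write_rejects(rejects: Sequence[RejectRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        out = csv.writer(fh)
        out.writerow(["line", "id", "reason"])
        for r in rejects:
            out.writerow([r.line, r.id, r.reason])


# ---------------------------------------------------------------------------
# Ligand preparation
# ---------------------------------------------------------------------------

# Deterministic protonation rules approximating physiological pH (7.4):
# carboxylic acids deprotonated, aliphatic amines protonated.  Benzimidazole
# and other (het)aromatic nitrogens are left neutral.
_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_ALIPHATIC_AMINE = Chem.MolFromSmarts(
    "[NX3;H2,H1,H0;+0;!$([N]-[C,S,P]=[O,S,N]);!$([N]-a);!$([N]~[!#6;!#1])]"
)


def _apply_protonation_rules(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.RWMol(mol)
    for (c_idx, _o_dbl, o_idx) in mol.GetSubstructMatches(_CARBOXYLIC_ACID):
        atom = mol.GetAtomWithIdx(o_idx)
        atom.SetFormalCharge(-1)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(True)
    for (n_idx,) in mol.GetSubstructMatches(_ALIPHATIC_AMINE):
        atom = mol.GetAtomWithIdx(n_idx)
        atom.SetFormalCharge(1)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def prepare_ligand(
    molecule: Molecule,
    max_stereoisomers: int = 32,
    protonate: bool = True,
) -> list[Molecule]:
    """Standardize a ligand for screening.

    Keeps the largest fragment (desalting), normalizes to the canonical
    tautomer, applies the fixed protonation rule table and enumerates
    unassigned stereocentres up to ``max_stereoisomers`` (the preparation
    cap used throughout the pipeline; default 32).  Each output carries a
    ``_sN`` suffixed id when more than one stereoisomer is produced.
    """
    if max_stereoisomers < 1:
        raise ValueError("max_stereoisomers must be >= 1")
    mol = rdMolStandardize.LargestFragmentChooser().choose(molecule.mol)
    mol = rdMolStandardize.TautomerEnumerator().Canonicalize(mol)
    if protonate:
        mol = _apply_protonation_rules(mol)
    opts = StereoEnumerationOptions(
        maxIsomers=max_stereoisomers, onlyUnassigned=True, rand=0x1CEB00DA % (2**31)
    )
    isomers = list(EnumerateStereoisomers(mol, options=opts))
    if len(isomers) <= 1:
        only = isomers[0] if isomers else mol
        return [Molecule(molecule.id, only)]
    return [
        Molecule(f"{molecule.id}_s{i}", iso) for i, iso in enumerate(isomers)
    ]


# ---------------------------------------------------------------------------
# Reference compounds
# ---------------------------------------------------------------------------

# Reference agonists reconstructed from the published SAR description of the
# GPR139 chemotype: R1 aryl - C(=O) - NH - X3 - C(=O) - X5 - X6(R2).
# 1a:   3,5-dimethoxyphenyl / linker N3,N5 / naphthalen-2-yl  (EC50 39 nM)
# 1s:   1a with the linker 5-nitrogen replaced by CH2
# 7c:   3-chlorophenyl / glycine linker (C3,N5) / 1-phenylethyl (racemic)
# DL96: des-5-nitrogen analogue of 1a (5-atom linker, inactive)
_REFERENCE_SMILES: dict[str, str] = {
    "1a": "COc1cc(OC)cc(c1)C(=O)NNC(=O)Nc1ccc2ccccc2c1",
    "1s": "COc1cc(OC)cc(c1)C(=O)NNC(=O)Cc1ccc2ccccc2c1",
    "7c": "Clc1cccc(c1)C(=O)NCC(=O)NC(C)c1ccccc1",
    "DL96": "COc1cc(OC)cc(c1)C(=O)NNC(=O)c1ccc2ccccc2c1",
    "L-Trp": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O",
    "L-Phe": "N[C@@H](Cc1ccccc1)C(=O)O",
}


def reference_compounds() -> list[Molecule]:
    """Return the transcribed reference structures (1a, 1s, 7c racemic,
    DL96 des-5-N analogue, L-Trp, L-Phe).

    A transcription self-check verifies that the topological PSA of the
    reconstructed 1a rounds to the published 88.70 Å² (and 1s to 76.7 Å²);
    failure indicates a corrupted fixture and is fatal.
    """
    from rdkit.Chem import rdMolDescriptors

    mols = [mol_from_smiles(smi, mol_id) for mol_id, smi in _REFERENCE_SMILES.items()]
    psa_1a = rdMolDescriptors.CalcTPSA(mols[0].mol)
    psa_1s = rdMolDescriptors.CalcTPSA(mols[1].mol)
    if abs(psa_1a - 88.70) > 0.05 or abs(psa_1s - 76.7) > 0.05:
        raise RuntimeError(
            "reference fixture integrity check failed: "
            f"PSA(1a)={psa_1a:.2f} (expected 88.70), PSA(1s)={psa_1s:.2f} (expected 76.7)"
        )
    return mols


def reference_compound(mol_id: str) -> Molecule:
    """Look up a single reference compound by id (e.g. ``"1a"``)."""
    for mol in reference_compounds():
        if mol.id == mol_id:
            return mol
    raise KeyError(f"unknown reference compound: {mol_id!r}")
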