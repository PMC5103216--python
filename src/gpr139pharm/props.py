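"""Physicochemical descriptors and CNS-penetration (Hitchcock) criteria.

PSA is the Ertl atom-contribution topological PSA; logP is the Crippen
atom-contribution estimate (surrogate for the proprietary QPlogP_o/w); logS
is the ESOL (Delaney) regression on logP, molecular weight, rotatable bonds
and aromatic proportion (surrogate for QPlogS).  All values are
conformer-independent.  Reports should label logP/logS as surrogate
estimates, not reproductions of the original proprietary calculations; PSA
is the one property with a printed cross-check and the topological method
reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem import Molecule


@dataclass
class PropertyProfile:
    mw: float  # g/mol
    psa: float  # Å², topological (Ertl)
    clogp: float  # Crippen atom-contribution logP
    logs: float  # ESOL estimate, log mol/dm³
    n_plus_o: int
    hbd: int
    hba: int
    rotatable_bonds: int
    formal_charge: int


@dataclass
class HitchcockVerdict:
    """The four CNS drug-likeness criteria, strict inequalities exactly as
    published: N+O < 5, ClogP − (N+O) > 0, PSA < 90 Å², MW < 450."""

    c1: bool
    c2: bool
    c3: bool
    c4: bool

    @property
    def pass_all(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4


@dataclass
class SolubilityFlags:
    in_logs_window: bool  # −6 <= logS <= −1
    cns_logp_ok: bool  # logP < 3.5


def compute_profile(molecule: Molecule) -> PropertyProfile:
    """Compute the physicochemical profile of a molecule (2D, deterministic,
    conformer-independent)."""
    mol = molecule.mol
    mw = Descriptors.MolWt(mol)
    clogp = Crippen.MolLogP(mol)
    rot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    # ESOL: Delaney's regression for aqueous solubility
    logs = 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rot - 0.74 * ap
    return PropertyProfile(
        mw=mw,
        psa=rdMolDescriptors.CalcTPSA(mol),
        clogp=clogp,
        logs=logs,
        n_plus_o=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        rotatable_bonds=rot,
        formal_charge=sum(a.GetFormalCharge() for a in mol.GetAtoms()),
    )


def hitchcock(profile: PropertyProfile) -> HitchcockVerdict:
    """Evaluate the four Hitchcock CNS criteria; boundary values (N+O = 5,
    PSA = 90, MW = 450, logP − (N+O) = 0) fail their criterion."""
    return HitchcockVerdict(
        c1=profile.n_plus_o < 5,
        c2=profile.clogp - profile.n_plus_o > 0,
        c3=profile.psa < 90.0,
        c4=profile.mw < 450.0,
    )


def solubility_flags(profile: PropertyProfile) -> SolubilityFlags:
    """Solubility window (−6 <= logS <= −1) and CNS logP (< 3.5) flags."""
    return SolubilityFlags(
        in_logs_window=-6.0 <= profile.logs <= -1.0,
        cns_logp_ok=profile.clogp < 3.5,
    )
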