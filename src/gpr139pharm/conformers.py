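"""Bounded conformer-ensemble generation and reference-conformer selection.

Ensembles are produced by distance-geometry embedding (ETKDG) followed by
MMFF94 minimization, capped by an ensemble size limit, a per-rotatable-bond
limit and a relative strain-energy window — the same caps used by the
torsional Monte-Carlo search protocols of commercial pharmacophore tools.
Energies are relative to the ensemble minimum and comparable only within a
molecule.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

from .chem import Conformer, Molecule


@dataclass
class ConformerPolicy:
    """Sampling limits for conformer generation.

    Defaults mirror the screening-database preparation protocol: at most
    100 conformers, up to 10 per rotatable bond, a 6.0 kcal/mol relative
    energy window, and amide-bond variation sampled.
    """

    max_conformers: int = 100
    max_per_rotatable_bond: int = 10
    energy_window: float = 6.0
    sample_amide_bonds: bool = True
    seed: int = 7
    minimize_iterations: int = 200
    dedup_rmsd: float = 0.5  # heavy-atom RMSD threshold for duplicates, Å

    def __post_init__(self) -> None:
        if self.max_conformers < 1 or self.max_per_rotatable_bond < 1:
            raise ValueError("conformer counts must be >= 1")
        if self.energy_window <= 0:
            raise ValueError("energy window must be > 0")


def _molecule_seed(policy_seed: int, mol_id: str) -> int:
    """Stable per-molecule embedding seed below 2**31."""
    digest = hashlib.sha256(f"{policy_seed}:{mol_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1) + 1


def generate_conformers(molecule: Molecule, policy: ConformerPolicy | None = None) -> Molecule:
    """Return a copy of ``molecule`` carrying a bounded conformer ensemble.

    The ensemble size is at most ``min(max_conformers,
    max_per_rotatable_bond * rotatable_bonds)`` (and at least 1); every
    conformer's relative energy lies within the policy's energy window;
    near-duplicate conformers (heavy-atom RMSD < 0.5 Å) are removed.
    Deterministic for a fixed policy seed.
    """
    policy = policy or ConformerPolicy()
    base = Chem.Mol(molecule.mol)
    base.RemoveAllConformers()
    molh = Chem.AddHs(base)
    n_rot = rdMolDescriptors.CalcNumRotatableBonds(base)
    target = max(1, min(policy.max_conformers, policy.max_per_rotatable_bond * max(n_rot, 1)))

    params = AllChem.ETKDGv3()
    params.randomSeed = _molecule_seed(policy.seed, molecule.id)
    params.pruneRmsThresh = policy.dedup_rmsd
    params.enforceChirality = True
    params.useRandomCoords = False
    cids = list(AllChem.EmbedMultipleConfs(molh, numConfs=target, params=params))
    if not cids:
        # bounded retry with random coordinates before giving up
        params.useRandomCoords = True
        params.randomSeed += 1
        cids = list(AllChem.EmbedMultipleConfs(molh, numConfs=target, params=params))
    if not cids:
        raise RuntimeError(f"conformer embedding failed for molecule {molecule.id!r}")

    energies = _minimize(molh, cids, policy)

    # order by energy, apply window relative to minimum, de-duplicate
    order = sorted(range(len(cids)), key=lambda i: (energies[i], i))
    e_min = energies[order[0]]
    heavy = Chem.RemoveHs(molh)
    coords = [np.array(heavy.GetConformer(cids[i]).GetPositions()) for i in range(len(cids))]
    kept_idx: list[int] = []
    for i in order:
        rel = energies[i] - e_min
        if rel > policy.energy_window:
            continue
        if any(_rmsd_no_align_ok(coords[i], coords[j], policy.dedup_rmsd) for j in kept_idx):
            continue
        kept_idx.append(i)
        if len(kept_idx) >= target:
            break

    out = Chem.Mol(base)
    out.RemoveAllConformers()
    out_energies = []
    for i in kept_idx:
        conf = Chem.Conformer(heavy.GetConformer(cids[i]))
        out.AddConformer(conf, assignId=True)
        out_energies.append(energies[i] - e_min)
    return Molecule(molecule.id, out, out_energies)


def _minimize(molh: Chem.Mol, cids: list[int], policy: ConformerPolicy) -> list[float]:
    """MMFF94 minimization; falls back to UFF, then to zero energies for
    molecules the force fields cannot type."""
    try:
        if AllChem.MMFFHasAllMoleculeParams(molh):
            results = AllChem.MMFFOptimizeMoleculeConfs(
                molh, maxIters=policy.minimize_iterations, numThreads=1
            )
        else:
            results = AllChem.UFFOptimizeMoleculeConfs(
                molh, maxIters=policy.minimize_iterations, numThreads=1
            )
        return [e for _converged, e in results]
    except Exception:
        return [0.0 for _ in cids]


def _rmsd_no_align_ok(a: np.ndarray, b: np.ndarray, threshold: float) -> bool:
    """True if two already-embedded coordinate sets are near-duplicates.

    Embedded conformers of the same molecule share an arbitrary frame, so
    the comparison aligns them (Kabsch) before the RMSD test.
    """
    from .screen import align_points

    try:
        _rot, _trans, rmsd = align_points(a, b)
    except ValueError:
        rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    return rmsd < threshold


def _collapsed(molecule_graph: Chem.Mol, coords: np.ndarray, min_dist: float = 2.0) -> bool:
    """Collapse predicate: any heavy-atom pair >= 4 bonds apart closer than
    ``min_dist`` Å through space."""
    topo = Chem.GetDistanceMatrix(molecule_graph)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    mask = topo >= 4
    return bool(np.any(dist[mask] < min_dist))


def select_reference_conformer(molecule: Molecule) -> Conformer:
    """Pick the global-minimum non-collapsed conformation.

    "Collapsed" means some heavy-atom pair at least 4 bonds apart lies
    closer than 2.0 Å through space (a folded, self-clashing geometry).  If
    every conformer is collapsed the minimum-energy one is returned with a
    warning.  Pure function of the ensemble.
    """
    confs = molecule.conformers
    if not confs:
        raise ValueError(f"molecule {molecule.id!r} has no conformers")
    for conf in sorted(confs, key=lambda c: c.energy):
        if not _collapsed(molecule.mol, conf.coords):
            return conf
    import warnings

    warnings.warn(
        f"all conformers of {molecule.id!r} are collapsed; returning the energy minimum",
        stacklevel=2,
    )
    return min(confs, key=lambda c: c.energy)
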