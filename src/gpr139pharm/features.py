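"""Pharmacophore feature perception on 3D conformers.

Features (hydrogen-bond acceptor, donor, aromatic ring, hydrophobic,
halogen) are detected from a fixed, versioned substructure-pattern table
shipped as package data, plus two geometric constructions computed in code:
aromatic-ring centroids (with unit normals) and alkyl-cluster centroids.
Perception is deterministic and equivariant under rigid motion of the
conformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from rdkit import Chem

from .chem import Conformer, Molecule

FEATURE_KINDS = ("acceptor", "donor", "aromatic_ring", "hydrophobic", "halogen")


@dataclass
class PharmFeature:
    """A 3D pharmacophore feature point.

    ``position`` is the source-atom position, the ring centroid (aromatic
    rings) or the group centroid (hydrophobic clusters), in Å.  Aromatic
    rings carry a unit ``normal``; other kinds do not.
    """

    kind: str
    position: np.ndarray
    atoms: tuple[int, ...]
    normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind: {self.kind}")
        if not self.atoms:
            raise ValueError("feature must reference at least one source atom")


@lru_cache(maxsize=1)
def load_pattern_table() -> tuple[str, tuple[tuple[str, str, Chem.Mol], ...]]:
    """Load the shipped (version, patterns) substructure table."""
    text = resources.files("gpr139pharm.data").joinpath("feature_patterns.tsv").read_text()
    version = "unversioned"
    patterns: list[tuple[str, str, Chem.Mol]] = []
    for line in text.splitlines():
        if line.startswith("# feature-patterns"):
            version = line.split("\t")[1].strip()
        if not line or line.startswith("#"):
            continue
        name, kind, smarts = line.split("\t")
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise RuntimeError(f"invalid SMARTS in pattern table: {name}")
        patterns.append((name, kind, query))
    return version, tuple(patterns)


def pattern_table_version() -> str:
    return load_pattern_table()[0]


def _pattern_atom_indices(mol: Chem.Mol) -> dict[str, set[int]]:
    """Atom indices matched per feature kind by the pattern table."""
    _version, patterns = load_pattern_table()
    hits: dict[str, set[int]] = {kind: set() for kind in FEATURE_KINDS}
    for _name, kind, query in patterns:
        for match in mol.GetSubstructMatches(query):
            hits[kind].add(match[0])
    return hits


def _aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) in (5, 6) and all(
            mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring
        ):
            rings.append(tuple(ring))
    return rings


def _alkyl_clusters(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Connected components of >= 2 contiguous non-polar aliphatic carbons
    (carbons bonded only to carbon or hydrogen)."""
    nonpolar = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if all(nbr.GetAtomicNum() in (1, 6) for nbr in atom.GetNeighbors()):
            nonpolar.add(atom.GetIdx())
    seen: set[int] = set()
    clusters = []
    for start in sorted(nonpolar):
        if start in seen:
            continue
        stack, component = [start], []
        seen.add(start)
        while stack:
            idx = stack.pop()
            component.append(idx)
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j in nonpolar and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(component) >= 2:
            clusters.append(tuple(sorted(component)))
    return clusters


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    # deterministic sign: first non-zero component positive
    for component in normal:
        if abs(component) > 1e-12:
            if component < 0:
                normal = -normal
            break
    return normal / np.linalg.norm(normal)


def perceive_features(molecule: Molecule, conformer: Conformer) -> list[PharmFeature]:
    """Detect pharmacophore features on one conformer of ``molecule``.

    Returns acceptor/donor features at heteroatom positions, one
    aromatic_ring feature per aromatic 5/6-ring (centroid + unit normal),
    hydrophobic features at halogen atoms on carbon and at alkyl-cluster
    centroids, and halogen features for Cl/Br/I on aromatic carbon (also
    emitted as hydrophobic).  Deterministic; the feature order is fixed by
    kind and ascending atom indices.
    """
    mol = molecule.mol
    coords = np.asarray(conformer.coords, dtype=float)
    if coords.shape[0] != mol.GetNumHeavyAtoms():
        raise ValueError(
            f"conformer has {coords.shape[0]} atoms but molecule "
            f"{molecule.id!r} has {mol.GetNumHeavyAtoms()} heavy atoms"
        )
    hits = _pattern_atom_indices(mol)
    features: list[PharmFeature] = []
    for kind in ("acceptor", "donor"):
        for idx in sorted(hits[kind]):
            features.append(PharmFeature(kind, coords[idx], (idx,)))
    for ring in _aromatic_rings(mol):
        ring_coords = coords[list(ring)]
        features.append(
            PharmFeature(
                "aromatic_ring",
                ring_coords.mean(axis=0),
                ring,
                normal=_ring_normal(ring_coords),
            )
        )
    for idx in sorted(hits["hydrophobic"]):
        features.append(PharmFeature("hydrophobic", coords[idx], (idx,)))
    for cluster in _alkyl_clusters(mol):
        features.append(
            PharmFeature("hydrophobic", coords[list(cluster)].mean(axis=0), cluster)
        )
    for idx in sorted(hits["halogen"]):
        features.append(PharmFeature("halogen", coords[idx], (idx,)))
    return features


def features_to_csv(molecule: Molecule, features: list[PharmFeature], path) -> None:
    """Write perceived features as CSV (molecule id, kind, x, y, z, atoms)."""
    import csv

    with open(path, "w", newline="") as fh:
        out = csv.writer(fh)
        out.writerow(["molecule_id", "kind", "x", "y", "z", "atoms"])
        for f in features:
            x, y, z = (f"{v:.4f}" for v in f.position)
            out.writerow([molecule.id, f.kind, x, y, z, "|".join(map(str, f.atoms))])


def feature_type_counts(molecule: Molecule) -> dict[str, int]:
    """Conformer-independent feature counts per kind (used to skip 3D work
    for molecules that cannot possibly reach the minimum match level)."""
    mol = molecule.mol
    hits = _pattern_atom_indices(mol)
    return {
        "acceptor": len(hits["acceptor"]),
        "donor": len(hits["donor"]),
        "aromatic_ring": len(_aromatic_rings(mol)),
        "hydrophobic": len(hits["hydrophobic"]) + len(_alkyl_clusters(mol)),
        "halogen": len(hits["halogen"]),
    }
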