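"""Pharmacophore hypothesis: feature sites, exclusion volumes and the
packaged GPR139 AAADHRR model.

The GPR139 model carries seven feature sites at six spatial positions: two
terminal aromatic rings R1 and R2, two linker hydrogen-bond acceptors A3
(1-carbonyl oxygen) and A4 (4-carbonyl oxygen), one linker donor D5
(2-position N-H), and a dual hydrophobic/halogen-or-acceptor element H6/A2
at position 3 of the R1 ring.  A2 and H6 are co-located: a single feature
of an allowed kind within tolerance anchors both labels and contributes two
matched sites.  Exclusion volumes encode substituent positions that
abolished activity in inactive analogues.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem

from .chem import Conformer, Molecule, reference_compound
from .conformers import ConformerPolicy, generate_conformers, select_reference_conformer
from .features import PharmFeature, perceive_features

SCHEMA_VERSION = 1

#: default site tolerance (Å).  Calibrated once from the structural
#: discrimination requirement of the model: the des-5-nitrogen (shortened
#: linker) analogue of the reference agonist must fail a full seven-site
#: match, which needs per-site residuals >= ~0.8 Å, while valid partial
#: matches sit below ~0.1 Å; 0.7 Å separates the two regimes with margin.
DEFAULT_SITE_TOLERANCE = 0.7

#: feature kinds each site label may match
SITE_KINDS: dict[str, frozenset[str]] = {
    "A2": frozenset({"acceptor"}),
    "A3": frozenset({"acceptor"}),
    "A4": frozenset({"acceptor"}),
    "D5": frozenset({"donor"}),
    "H6": frozenset({"hydrophobic", "halogen"}),
    "R1": frozenset({"aromatic_ring"}),
    "R2": frozenset({"aromatic_ring"}),
}

#: labels sharing one spatial position (a matching feature satisfies all)
DUAL_GROUPS: tuple[frozenset[str], ...] = (frozenset({"A2", "H6"}),)


@dataclass
class FeatureSite:
    label: str
    allowed_kinds: frozenset[str]
    position: np.ndarray
    tolerance: float = DEFAULT_SITE_TOLERANCE

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.allowed_kinds = frozenset(self.allowed_kinds)
        if self.tolerance <= 0:
            raise ValueError("site tolerance must be > 0")


@dataclass
class ExclusionSphere:
    position: np.ndarray
    radius: float = 1.2
    provenance: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise ValueError("exclusion radius must be > 0")


@dataclass
class Location:
    """A spatial site location; dual locations carry two labels and count
    double in the matched-site tally."""

    labels: tuple[str, ...]
    kinds: frozenset[str]
    position: np.ndarray
    tolerance: float

    @property
    def weight(self) -> int:
        return len(self.labels)


@dataclass
class Hypothesis:
    sites: list[FeatureSite]
    exclusions: list[ExclusionSphere] = field(default_factory=list)
    min_match: int = 4
    provenance: str = ""

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError("site labels must be unique")
        if self.min_match > sum(1 for _ in self.sites):
            raise ValueError(
                f"min_match {self.min_match} exceeds site count {len(self.sites)}"
            )

    @property
    def variant(self) -> str:
        kind_letter = {
            "acceptor": "A",
            "donor": "D",
            "hydrophobic": "H",
            "halogen": "H",
            "aromatic_ring": "R",
        }
        letters = []
        for site in self.sites:
            # a site's letter is the one implied by its label's primary kind
            primary = sorted(site.allowed_kinds)[0]
            letters.append(kind_letter[primary])
        return "".join(sorted(letters))

    def site(self, label: str) -> FeatureSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)

    def locations(self) -> list[Location]:
        """Group co-located dual sites into single match locations."""
        used: set[str] = set()
        locations: list[Location] = []
        for group in DUAL_GROUPS:
            members = [s for s in self.sites if s.label in group]
            if len(members) == len(group):
                locations.append(
                    Location(
                        labels=tuple(sorted(s.label for s in members)),
                        kinds=frozenset().union(*(s.allowed_kinds for s in members)),
                        position=members[0].position,
                        tolerance=min(s.tolerance for s in members),
                    )
                )
                used.update(s.label for s in members)
        for s in self.sites:
            if s.label not in used:
                locations.append(
                    Location((s.label,), s.allowed_kinds, s.position, s.tolerance)
                )
        return locations


# ---------------------------------------------------------------------------
# Building a hypothesis from a reference conformation
# ---------------------------------------------------------------------------


def build_hypothesis(
    reference: Molecule,
    conformer: Conformer,
    mapping: dict[str, tuple[int, ...]],
    tolerance: float = DEFAULT_SITE_TOLERANCE,
    min_match: int = 4,
    provenance: str = "",
) -> Hypothesis:
    """Build a hypothesis by anchoring each site label on perceived features
    of a reference conformer.

    ``mapping`` assigns each label a tuple of source-atom indices; the
    matching perceived feature of a compatible kind supplies the site
    position.  A label of a dual group (H6 with A2) may share its partner's
    anchoring feature, since the pair occupies one spatial position.
    """
    feats = perceive_features(reference, conformer)
    by_atoms: dict[tuple[str, tuple[int, ...]], PharmFeature] = {}
    for f in feats:
        by_atoms[(f.kind, tuple(sorted(f.atoms)))] = f

    def find(label: str, atoms: tuple[int, ...]) -> PharmFeature | None:
        for kind in sorted(SITE_KINDS[label]):
            f = by_atoms.get((kind, tuple(sorted(atoms))))
            if f is not None:
                return f
        return None

    sites: list[FeatureSite] = []
    for label in ("A2", "A3", "A4", "D5", "H6", "R1", "R2"):
        if label not in mapping:
            raise ValueError(f"mapping missing label {label}")
        atoms = tuple(mapping[label]) if not isinstance(mapping[label], int) else (mapping[label],)
        feat = find(label, atoms)
        if feat is None:
            # dual-group fallback: co-located partner anchors the position
            partner = None
            for group in DUAL_GROUPS:
                if label in group:
                    others = group - {label}
                    for other in others:
                        if tuple(sorted(mapping.get(other, ()))) == tuple(sorted(atoms)):
                            partner = find(other, atoms)
            if partner is None:
                raise ValueError(f"kind mismatch at {label}")
            feat = partner
        sites.append(FeatureSite(label, SITE_KINDS[label], feat.position, tolerance))
    return Hypothesis(sites, [], min_match, provenance)


# ---------------------------------------------------------------------------
# Exclusion volumes
# ---------------------------------------------------------------------------


def derive_exclusion_volumes(
    hypothesis: Hypothesis,
    actives: list[Molecule],
    inactives: list[Molecule],
    margin: float = 0.5,
    radius: float = 1.2,
) -> Hypothesis:
    """Derive exclusion spheres from aligned actives and inactives.

    Spheres are placed at heavy-atom positions occupied by at least one
    inactive and farther than ``radius + margin`` from every active heavy
    atom (and outside every site tolerance sphere).  All molecules must be
    pre-aligned to the hypothesis frame (first conformer used).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if not inactives:
        warnings.warn("empty inactive set; returning hypothesis unchanged", stacklevel=2)
        return hypothesis
    active_coords = (
        np.vstack([m.conformers[0].coords for m in actives])
        if actives
        else np.zeros((0, 3))
    )
    new_spheres: list[ExclusionSphere] = []
    for mol in inactives:
        coords = mol.conformers[0].coords
        for i, pos in enumerate(coords):
            if active_coords.shape[0]:
                if np.min(np.linalg.norm(active_coords - pos, axis=1)) <= radius + margin:
                    continue
            if any(
                np.linalg.norm(site.position - pos) <= site.tolerance
                for site in hypothesis.sites
            ):
                continue
            if any(
                np.linalg.norm(s.position - pos) < 0.5
                for s in list(hypothesis.exclusions) + new_spheres
            ):
                continue  # merge near-duplicates
            new_spheres.append(
                ExclusionSphere(pos.copy(), radius, provenance=f"inactive:{mol.id}:atom{i}")
            )
    return Hypothesis(
        sites=list(hypothesis.sites),
        exclusions=list(hypothesis.exclusions) + new_spheres,
        min_match=hypothesis.min_match,
        provenance=hypothesis.provenance,
    )


# ---------------------------------------------------------------------------
# The packaged GPR139 model
# ---------------------------------------------------------------------------

_LINKER_1A = Chem.MolFromSmarts(
    "[c][CX3](=[OX1])[NX3H1][NX3H1][CX3](=[OX1])[NX3H1][c]"
)
_METHOXY_O = Chem.MolFromSmarts("[OX2]([CH3])[c]")

#: pinned conformer-generation seed for the packaged model build
GPR139_MODEL_SEED = 139


def _ring_of(mol: Chem.Mol, atom_idx: int) -> tuple[int, ...]:
    for ring in mol.GetRingInfo().AtomRings():
        if atom_idx in ring and len(ring) == 6:
            return tuple(ring)
    raise ValueError(f"atom {atom_idx} not in a 6-ring")


def _gpr139_mapping(mol: Chem.Mol) -> dict[str, tuple[int, ...]]:
    """Site-label -> atom/ring assignment for the reconstructed 1a."""
    matches = mol.GetSubstructMatches(_LINKER_1A)
    if not matches:
        raise RuntimeError("reference 1a does not contain the expected linker")
    aryl_c, _c1, o1, n2, _n3, _c4, o4, _n5, naph_c = matches[0]
    r1_ring = _ring_of(mol, aryl_c)
    # A2: methoxy oxygen on the R1 ring (smallest atom index for determinism)
    methoxy_os = sorted(
        m[0] for m in mol.GetSubstructMatches(_METHOXY_O) if m[2] in r1_ring
    )
    if not methoxy_os:
        raise RuntimeError("reference 1a lacks an R1 methoxy substituent")
    a2_atom = methoxy_os[0]
    # R2: distal naphthyl ring (the 6-ring not containing the attachment atom)
    distal = None
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) == 6 and naph_c not in ring:
            if any(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring) and ring != r1_ring:
                distal = tuple(ring)
    if distal is None:
        raise RuntimeError("could not locate the distal R2 ring")
    return {
        "A2": (a2_atom,),
        "A3": (o1,),
        "A4": (o4,),
        "D5": (n2,),
        "H6": (a2_atom,),
        "R1": r1_ring,
        "R2": distal,
    }


def _outward(position: np.ndarray, centroid: np.ndarray, distance: float) -> np.ndarray:
    direction = position - centroid
    return position + direction / np.linalg.norm(direction) * distance


def _curated_exclusions(
    mol: Chem.Mol,
    coords: np.ndarray,
    mapping: dict[str, tuple[int, ...]],
    radius: float = 1.2,
) -> list[ExclusionSphere]:
    """Exclusion spheres encoding the disfavoured substituent positions:
    R1 ring positions 2/3/5 (third substituent atom), bulk around linker
    position 3, and R2 ring positions 4/5/7."""
    spheres: list[ExclusionSphere] = []
    r1_ring = list(mapping["R1"])
    r1_centroid = coords[r1_ring].mean(axis=0)
    attach = next(
        a for (a, *_rest) in mol.GetSubstructMatches(_LINKER_1A) if a in mapping["R1"]
    )
    a2_atom = mapping["A2"][0]
    # R1 numbering: position 1 = linker attachment; position 3 = the meta
    # carbon bearing the A2 methoxy; position 2 = the ortho carbon between
    # them; position 5 = the other meta carbon.
    ring_nbrs = [i for i in r1_ring if mol.GetBondBetweenAtoms(attach, i)]
    meta3 = next(i for i in r1_ring if mol.GetBondBetweenAtoms(i, a2_atom))
    ortho2 = next(i for i in ring_nbrs if mol.GetBondBetweenAtoms(i, meta3))
    para4 = next(
        i
        for i in r1_ring
        if i not in (attach, ortho2, meta3)
        and mol.GetBondBetweenAtoms(i, meta3)
    )
    meta5 = next(
        i for i in r1_ring if i not in (attach, ortho2, meta3, para4) and
        mol.GetBondBetweenAtoms(i, para4)
    )
    for pos_label, idx in (("R1-2", ortho2), ("R1-3", meta3), ("R1-5", meta5)):
        spheres.append(
            ExclusionSphere(
                _outward(coords[idx], r1_centroid, 3.7),
                radius,
                provenance=f"{pos_label}-third-atom",
            )
        )
    # linker position 3: no room for bulk; sphere where a substituent's
    # second atom would sit, along the N3 substituent direction
    linker = mol.GetSubstructMatches(_LINKER_1A)[0]
    n3 = linker[4]
    nbr_pos = np.array([coords[n.GetIdx()] for n in mol.GetAtomWithIdx(n3).GetNeighbors()])
    direction = coords[n3] - nbr_pos.mean(axis=0)
    direction /= np.linalg.norm(direction)
    spheres.append(
        ExclusionSphere(coords[n3] + direction * 2.2, radius, provenance="linker-3-bulk")
    )
    # R2 ring positions 4, 5 and 7 (naphthalene numbering, attachment = 2)
    naph_c = linker[-1]
    proximal = _ring_of(mol, naph_c)
    distal = mapping["R2"]
    fusion = [i for i in proximal if i in distal]
    prox_nbrs = [i for i in proximal if mol.GetBondBetweenAtoms(naph_c, i)]
    pos3 = next(i for i in prox_nbrs if not any(mol.GetBondBetweenAtoms(i, f) for f in fusion))
    pos4 = next(
        i for i in proximal if i != naph_c and mol.GetBondBetweenAtoms(i, pos3)
    )
    fuse4a = next(f for f in fusion if mol.GetBondBetweenAtoms(f, pos4))
    pos5 = next(
        i for i in distal if i not in fusion and mol.GetBondBetweenAtoms(i, fuse4a)
    )
    pos6 = next(i for i in distal if i not in fusion and mol.GetBondBetweenAtoms(i, pos5))
    pos7 = next(
        i for i in distal if i not in fusion and i != pos5 and mol.GetBondBetweenAtoms(i, pos6)
    )
    prox_centroid = coords[list(proximal)].mean(axis=0)
    dist_centroid = coords[list(distal)].mean(axis=0)
    for pos_label, idx, centroid in (
        ("R2-4", pos4, prox_centroid),
        ("R2-5", pos5, dist_centroid),
        ("R2-7", pos7, dist_centroid),
    ):
        spheres.append(
            ExclusionSphere(
                _outward(coords[idx], centroid, 2.5), radius, provenance=f"{pos_label}-substituent"
            )
        )
    return spheres


@lru_cache(maxsize=4)
def gpr139_model(min_match: int = 4, tolerance: float = DEFAULT_SITE_TOLERANCE) -> Hypothesis:
    """Build the packaged GPR139 AAADHRR pharmacophore model.

    The model is rebuilt programmatically from the reconstructed reference
    agonist 1a: conformers are generated with a pinned seed, the global
    non-collapsed energy minimum is selected, sites are anchored on the
    mapped features (A3 = 1-carbonyl O, D5 = 2-N-H, A4 = 4-carbonyl O,
    A2/H6 = 3-methoxy O, R1 = proximal aryl centroid, R2 = distal naphthyl
    centroid) and the curated exclusion spheres are added.  Coordinates are
    reproducible within this package for a fixed RDKit version.
    """
    ref = reference_compound("1a")
    policy = ConformerPolicy(seed=GPR139_MODEL_SEED)
    with_confs = generate_conformers(ref, policy)
    conf = select_reference_conformer(with_confs)
    mapping = _gpr139_mapping(ref.mol)
    hyp = build_hypothesis(
        ref,
        conf,
        mapping,
        tolerance=tolerance,
        min_match=min_match,
        provenance="gpr139-aaadhrr-v1 (built from reconstructed 1a)",
    )
    spheres = _curated_exclusions(ref.mol, conf.coords, mapping)
    # integrity guard: no curated sphere may clash the reference active
    spheres = [
        s
        for s in spheres
        if np.min(np.linalg.norm(conf.coords - s.position, axis=1)) > s.radius
    ]
    hyp.exclusions.extend(spheres)
    return hyp


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_hypothesis(hypothesis: Hypothesis, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "variant": hypothesis.variant,
        "min_match": hypothesis.min_match,
        "provenance": hypothesis.provenance,
        "sites": [
            {
                "label": s.label,
                "kinds": sorted(s.allowed_kinds),
                "position": [float(x) for x in s.position],
                "tolerance": s.tolerance,
            }
            for s in hypothesis.sites
        ],
        "exclusions": [
            {
                "position": [float(x) for x in s.position],
                "radius": s.radius,
                "provenance": s.provenance,
            }
            for s in hypothesis.exclusions
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_hypothesis(path) -> Hypothesis:
    with open(path) as fh:
        payload = json.load(fh)  # malformed JSON raises with line/column
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"hypothesis schema version mismatch: file has {version!r}, "
            f"this package reads {SCHEMA_VERSION}"
        )
    if "min_match" not in payload:
        warnings.warn("hypothesis file missing 'min_match'; defaulting to 4", stacklevel=2)
    sites = [
        FeatureSite(
            s["label"], frozenset(s["kinds"]), np.array(s["position"]), s["tolerance"]
        )
        for s in payload["sites"]
    ]
    exclusions = [
        ExclusionSphere(np.array(e["position"]), e["radius"], e.get("provenance", ""))
        for e in payload.get("exclusions", [])
    ]
    return Hypothesis(
        sites, exclusions, payload.get("min_match", 4), payload.get("provenance", "")
    )
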