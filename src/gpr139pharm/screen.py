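"""Ensemble screening against a pharmacophore hypothesis.

The matcher enumerates type-compatible correspondences between hypothesis
site locations and perceived conformer features (bounded by the seven-site
model), rigidly aligns each correspondence (Kabsch), accepts it only if
every matched feature lies within its site tolerance, rejects poses whose
heavy atoms enter an exclusion sphere, and ranks candidates by "more sites
preferred": maximum matched count, then minimum RMSD, then earliest
conformer, then lexicographic correspondence.  The fitness surrogate

    fitness = matched_count / 7 + max(0, 1 - rmsd / 2.0)   in [0, 2]

preserves the two published ranking drivers (more matched sites preferred,
tighter geometric fit preferred).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem import Molecule
from .conformers import ConformerPolicy, generate_conformers
from .features import PharmFeature, feature_type_counts, perceive_features
from .hypothesis import Hypothesis, Location

logger = logging.getLogger(__name__)

FITNESS_RMSD_SCALE = 2.0  # Å; fitness geometric term = max(0, 1 - rmsd/scale)
N_MODEL_SITES = 7


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------


def align_points(
    ref_points: np.ndarray, mov_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of ``mov_points`` onto
    ``ref_points``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``mov @ rotation.T + translation ≈ ref``.  Raises
    ``ValueError`` for fewer than 3 points or collinear point sets.
    """
    ref = np.asarray(ref_points, dtype=float)
    mov = np.asarray(mov_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    for pts in (ref_c, mov_c):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-8 * max(sv[0], 1.0):
            raise ValueError("degenerate (collinear) point set")
    cov = mov_c.T @ ref_c
    u, _s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref.mean(axis=0) - rotation @ mov.mean(axis=0)
    moved = mov @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    molecule_id: str
    conformer_index: int = -1
    correspondence: dict[str, int] = field(default_factory=dict)
    matched_count: int = 0
    rmsd: float = float("inf")
    excluded: bool = False
    fitness: float = 0.0
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None

    def sort_key(self) -> tuple:
        return (-self.fitness, -self.matched_count, self.rmsd, self.molecule_id)


def _fitness(matched_count: int, rmsd: float) -> float:
    return matched_count / N_MODEL_SITES + max(0.0, 1.0 - rmsd / FITNESS_RMSD_SCALE)


def _max_possible_matches(counts: dict[str, int]) -> int:
    """Upper bound on matched sites from conformer-independent type counts."""
    n_a, n_d = counts["acceptor"], counts["donor"]
    n_r = counts["aromatic_ring"]
    n_h = counts["hydrophobic"] + counts["halogen"]
    plain_a = min(2, n_a)  # A3, A4
    bound = plain_a + min(1, n_d) + min(2, n_r)
    if n_h >= 1 or n_a > plain_a:
        bound += 2  # dual A2/H6 location counts two sites
    return bound


def _candidate_assignments(
    locations: list[Location],
    feats: list[PharmFeature],
    feat_dist: np.ndarray,
    loc_dist: np.ndarray,
):
    """Backtracking enumeration of injective location->feature assignments,
    pruned by the pairwise-distance necessary condition
    |d(f_i, f_j) - d(s_i, s_j)| <= tol_i + tol_j."""
    compat = [
        [i for i, f in enumerate(feats) if f.kind in loc.kinds] for loc in locations
    ]
    n = len(locations)
    assignment: list[int] = []
    used: set[int] = set()

    def recurse(k: int):
        if k == n:
            yield tuple(assignment)
            return
        for fi in compat[k]:
            if fi in used:
                continue
            ok = True
            for j in range(k):
                tol = locations[k].tolerance + locations[j].tolerance
                if abs(feat_dist[fi, assignment[j]] - loc_dist[k, j]) > tol:
                    ok = False
                    break
            if ok:
                assignment.append(fi)
                used.add(fi)
                yield from recurse(k + 1)
                assignment.pop()
                used.discard(fi)

    yield from recurse(0)


def match(molecule: Molecule, hypothesis: Hypothesis) -> MatchResult:
    """Match a conformer ensemble against a hypothesis.

    Returns the best valid partial match with at least ``min_match`` sites,
    preferring more matched sites, then lower RMSD, then the earliest
    conformer, then the lexicographically smallest correspondence.  A pose
    whose heavy atoms enter an exclusion sphere is rejected; if only
    excluded poses exist the result is flagged ``excluded`` with fitness 0.
    No valid correspondence yields a zero result (not an error).
    """
    conformers = molecule.conformers
    if not conformers:
        raise ValueError(f"molecule {molecule.id!r} has no conformers")
    locations = hypothesis.locations()
    min_match = hypothesis.min_match
    loc_positions = np.array([loc.position for loc in locations])
    excl_centers = (
        np.array([s.position for s in hypothesis.exclusions])
        if hypothesis.exclusions
        else np.zeros((0, 3))
    )
    excl_radii = np.array([s.radius for s in hypothesis.exclusions])

    best: MatchResult | None = None
    best_excluded: MatchResult | None = None

    # location subsets grouped by total matched weight, descending
    subsets_by_weight: dict[int, list[tuple[int, ...]]] = {}
    for r in range(1, len(locations) + 1):
        for subset in combinations(range(len(locations)), r):
            w = sum(locations[i].weight for i in subset)
            if w >= min_match:
                subsets_by_weight.setdefault(w, []).append(subset)

    per_conf = []
    for ci, conf in enumerate(conformers):
        feats = perceive_features(molecule, conf)
        fpos = np.array([f.position for f in feats]) if feats else np.zeros((0, 3))
        fdist = (
            np.linalg.norm(fpos[:, None, :] - fpos[None, :, :], axis=2)
            if len(feats)
            else np.zeros((0, 0))
        )
        per_conf.append((conf, feats, fdist))

    ldist_full = np.linalg.norm(
        loc_positions[:, None, :] - loc_positions[None, :, :], axis=2
    )

    for weight in sorted(subsets_by_weight, reverse=True):
        for ci, (conf, feats, fdist) in enumerate(per_conf):
            if not feats:
                continue
            for subset in subsets_by_weight[weight]:
                sub_locs = [locations[i] for i in subset]
                ldist = ldist_full[np.ix_(subset, subset)]
                for assignment in _candidate_assignments(sub_locs, feats, fdist, ldist):
                    # expand dual locations into per-label point pairs
                    site_pts, feat_pts, labels = [], [], []
                    for loc, fi in zip(sub_locs, assignment):
                        for label in loc.labels:
                            site_pts.append(loc.position)
                            feat_pts.append(feats[fi].position)
                            labels.append((label, fi))
                    try:
                        rot, trans, rmsd = align_points(
                            np.array(site_pts), np.array(feat_pts)
                        )
                    except ValueError:
                        continue
                    placed = np.array(feat_pts) @ rot.T + trans
                    residuals = np.linalg.norm(placed - np.array(site_pts), axis=1)
                    tol_ok = all(
                        res <= loc.tolerance
                        for loc, res in zip(
                            [l for l in sub_locs for _ in l.labels], residuals
                        )
                    )
                    if not tol_ok:
                        continue
                    candidate = MatchResult(
                        molecule_id=molecule.id,
                        conformer_index=ci,
                        correspondence=dict(sorted(labels)),
                        matched_count=weight,
                        rmsd=rmsd,
                        rotation=rot,
                        translation=trans,
                    )
                    atoms_placed = conf.coords @ rot.T + trans
                    clashes = False
                    if excl_centers.shape[0]:
                        dists = np.linalg.norm(
                            atoms_placed[:, None, :] - excl_centers[None, :, :], axis=2
                        )
                        clashes = bool(np.any(dists < excl_radii[None, :]))
                    key = (rmsd, ci, tuple(sorted(candidate.correspondence.items())))
                    if clashes:
                        candidate.excluded = True
                        if best_excluded is None or key < (
                            best_excluded.rmsd,
                            best_excluded.conformer_index,
                            tuple(sorted(best_excluded.correspondence.items())),
                        ):
                            best_excluded = candidate
                        continue
                    if best is None or key < (
                        best.rmsd,
                        best.conformer_index,
                        tuple(sorted(best.correspondence.items())),
                    ):
                        best = candidate
        if best is not None:
            break  # found valid matches at the highest attainable weight

    if best is not None:
        best.fitness = _fitness(best.matched_count, best.rmsd)
        return best
    if best_excluded is not None:
        best_excluded.fitness = 0.0
        return best_excluded
    return MatchResult(molecule_id=molecule.id)


# ---------------------------------------------------------------------------
# Library screening
# ---------------------------------------------------------------------------


@dataclass
class ScreenReport:
    """Ranked best-per-molecule match results plus provenance."""

    results: list[MatchResult]
    hypothesis_provenance: str = ""
    library_provenance: str = ""
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.results = sorted(self.results, key=MatchResult.sort_key)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            out = csv.writer(fh)
            out.writerow(
                ["id", "matched_count", "rmsd", "fitness", "excluded", "conformer_index"]
            )
            for r in self.results:
                rmsd = "" if not np.isfinite(r.rmsd) else f"{r.rmsd:.6f}"
                out.writerow(
                    [r.molecule_id, r.matched_count, rmsd, f"{r.fitness:.6f}",
                     int(r.excluded), r.conformer_index]
                )


def screen_library(
    library: list[Molecule],
    hypothesis: Hypothesis,
    policy: ConformerPolicy | None = None,
) -> ScreenReport:
    """Screen a library against a hypothesis.

    Molecules without conformers are embedded with ``policy`` first;
    molecules whose conformer-independent feature counts cannot reach the
    minimum match level are scored 0 without 3D work.  Per-molecule
    failures are logged and never abort the screen.  Deterministic for a
    fixed policy seed.
    """
    if not library:
        raise ValueError("empty library")
    policy = policy or ConformerPolicy()
    results = []
    for mol in library:
        try:
            if _max_possible_matches(feature_type_counts(mol)) < hypothesis.min_match:
                results.append(MatchResult(molecule_id=mol.id))
                continue
            target = mol if mol.mol.GetNumConformers() else generate_conformers(mol, policy)
            results.append(match(target, hypothesis))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("screening failed for %s: %s", mol.id, exc)
            results.append(MatchResult(molecule_id=mol.id))
    return ScreenReport(
        results,
        hypothesis_provenance=hypothesis.provenance,
        config={"min_match": hypothesis.min_match, "seed": policy.seed},
    )


# ---------------------------------------------------------------------------
# Diversity selection
# ---------------------------------------------------------------------------

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_fingerprint(mol: Chem.Mol):
    return _MORGAN.GetFingerprint(mol)


def diversity_select(
    report: ScreenReport,
    molecules: dict[str, Molecule] | list[Molecule],
    n: int,
    similarity_cutoff: float = 0.6,
) -> list[str]:
    """Greedy leader clustering down the fitness ranking.

    Walks the ranked results and keeps a molecule iff its Morgan-fingerprint
    Tanimoto similarity to every already-kept molecule is below the cutoff;
    stops after ``n`` leaders.  Returns fewer than ``n`` ids (with a
    warning) when the library holds fewer distinct clusters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < similarity_cutoff < 1:
        raise ValueError("similarity_cutoff must be in (0, 1)")
    if isinstance(molecules, list):
        molecules = {m.id: m for m in molecules}
    leaders: list[str] = []
    leader_fps = []
    for result in report.results:
        mol = molecules.get(result.molecule_id)
        if mol is None:
            continue
        fp = morgan_fingerprint(mol.mol)
        if any(
            DataStructs.TanimotoSimilarity(fp, kept) >= similarity_cutoff
            for kept in leader_fps
        ):
            continue
        leaders.append(result.molecule_id)
        leader_fps.append(fp)
        if len(leaders) >= n:
            return leaders
    if len(leaders) < n:
        import warnings

        warnings.warn(
            f"only {len(leaders)} distinct clusters available (requested {n})",
            stacklevel=2,
        )
    return leaders
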