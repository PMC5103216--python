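"""Property-matched decoy selection and screen-quality statistics.

Decoy selection follows the DUD-E protocol: for each active, candidate
molecules matched on physicochemical property windows but topologically
dissimilar (Morgan Tanimoto below a cutoff to *every* active) are ranked by
property distance and the top n taken, without reuse across actives.

Ranking quality is summarized by the ROC curve and its area (computed as
the tie-averaged Mann-Whitney rank statistic), enrichment factors at a
screened fraction, the percentage of actives among the top slots, and the
fraction of the deck that must be screened to reach a recall level.  Ties
at a cutoff are handled pessimistically (decoys ranked above actives within
a tie group) so early enrichment is never overstated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import DataStructs
from scipy.stats import rankdata

from .chem import Molecule
from .props import PropertyProfile, compute_profile
from .screen import morgan_fingerprint


@dataclass
class DecoyWindows:
    """Property-matching windows (absolute differences to the anchor
    active) and the topological dissimilarity cutoff."""

    mw: float = 25.0
    clogp: float = 1.0
    hbd: int = 1
    hba: int = 2
    rotatable_bonds: int = 2
    tanimoto: float = 0.35  # candidate excluded if >= to any active

    def satisfied(self, anchor: PropertyProfile, candidate: PropertyProfile) -> bool:
        return (
            abs(candidate.mw - anchor.mw) <= self.mw
            and abs(candidate.clogp - anchor.clogp) <= self.clogp
            and abs(candidate.hbd - anchor.hbd) <= self.hbd
            and abs(candidate.hba - anchor.hba) <= self.hba
            and abs(candidate.rotatable_bonds - anchor.rotatable_bonds)
            <= self.rotatable_bonds
            and candidate.formal_charge == anchor.formal_charge
        )

    def distance(self, anchor: PropertyProfile, candidate: PropertyProfile) -> float:
        """Window-normalized property distance used to rank candidates."""
        return (
            abs(candidate.mw - anchor.mw) / self.mw
            + abs(candidate.clogp - anchor.clogp) / self.clogp
            + abs(candidate.hbd - anchor.hbd) / self.hbd
            + abs(candidate.hba - anchor.hba) / self.hba
            + abs(candidate.rotatable_bonds - anchor.rotatable_bonds)
            / self.rotatable_bonds
        )


@dataclass
class DecoySelection:
    per_active: dict[str, list[str]]
    windows: DecoyWindows
    shortfalls: dict[str, int] = field(default_factory=dict)

    @property
    def all_decoys(self) -> list[str]:
        out: list[str] = []
        for ids in self.per_active.values():
            out.extend(ids)
        return out


def select_decoys(
    actives: list[Molecule],
    candidates: list[Molecule],
    n_per_active: int = 50,
    windows: DecoyWindows | None = None,
) -> DecoySelection:
    """Select property-matched, topologically dissimilar decoys.

    Deterministic for fixed input order; shortfalls are reported per
    active, never silently padded; no decoy is reused across actives.
    """
    if n_per_active < 1:
        raise ValueError("n_per_active must be >= 1")
    if not candidates:
        raise ValueError("empty candidate pool")
    windows = windows or DecoyWindows()
    active_ids = {m.id for m in actives}
    if active_ids & {m.id for m in candidates}:
        raise ValueError("candidate pool overlaps the active set")

    active_fps = [morgan_fingerprint(m.mol) for m in actives]
    anchor_profiles = [compute_profile(m) for m in actives]
    cand_profiles = [compute_profile(m) for m in candidates]
    dissimilar: list[bool] = []
    for m in candidates:
        sims = DataStructs.BulkTanimotoSimilarity(morgan_fingerprint(m.mol), active_fps)
        dissimilar.append(max(sims) < windows.tanimoto)

    eligible_lists: list[list[tuple[float, str, int]]] = []
    for anchor in anchor_profiles:
        eligible = [
            (windows.distance(anchor, cand_profiles[j]), candidates[j].id, j)
            for j in range(len(candidates))
            if dissimilar[j] and windows.satisfied(anchor, cand_profiles[j])
        ]
        eligible.sort()
        eligible_lists.append(eligible)

    # round-robin assignment: each active takes its nearest still-available
    # candidate per round, so rare candidates are not hoarded by the actives
    # that happen to come first in input order.  Within a round, actives
    # with the scarcest eligible pools pick first.  Deterministic.
    scarcity_order = sorted(
        range(len(actives)), key=lambda ai: (len(eligible_lists[ai]), ai)
    )
    taken: set[int] = set()
    cursors = [0] * len(actives)
    per_active: dict[str, list[str]] = {m.id: [] for m in actives}
    shortfalls: dict[str, int] = {}
    for _round in range(n_per_active):
        for ai in scarcity_order:
            active = actives[ai]
            chosen = per_active[active.id]
            if len(chosen) > _round:
                continue
            eligible = eligible_lists[ai]
            cursor = cursors[ai]
            while cursor < len(eligible) and eligible[cursor][2] in taken:
                cursor += 1
            cursors[ai] = cursor
            if cursor < len(eligible):
                _dist, cid, j = eligible[cursor]
                chosen.append(cid)
                taken.add(j)
                cursors[ai] = cursor + 1
    for active in actives:
        if len(per_active[active.id]) < n_per_active:
            shortfalls[active.id] = n_per_active - len(per_active[active.id])
    if shortfalls:
        warnings.warn(
            f"decoy shortfall for {len(shortfalls)} active(s); "
            f"largest {max(shortfalls.values())}",
            stacklevel=2,
        )
    return DecoySelection(per_active, windows, shortfalls)


# ---------------------------------------------------------------------------
# ROC / enrichment
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    labels: list[str]  # labels in pessimistic rank order (best first)
    points: list[tuple[float, float]]  # (FPR, TPR) steps
    auc: float
    ef: dict[float, float] = field(default_factory=dict)
    fraction_to_recall: dict[float, float] = field(default_factory=dict)


def _check_two_class(scored: list[tuple[float, str]]) -> tuple[int, int]:
    n_active = sum(1 for _s, lab in scored if lab == "active")
    n_decoy = len(scored) - n_active
    if n_active == 0 or n_decoy == 0:
        raise ValueError("need at least one active and one decoy")
    return n_active, n_decoy


def _pessimistic_order(scored: list[tuple[float, str]]) -> list[str]:
    """Labels sorted by descending score; within a tie group decoys are
    ranked above actives (conservative early enrichment)."""
    return [
        t[2]
        for t in sorted(
            ((-s, lab == "active", lab) for s, lab in scored),
            key=lambda t: (t[0], t[1]),
        )
    ]


def roc(scored: list[tuple[float, str]]) -> ROCResult:
    """ROC curve and AUC for (score, label) pairs, labels "active"/"decoy".

    AUC is the tie-averaged Mann-Whitney statistic
    ``P(score_active > score_decoy) + 0.5 P(tie)``; the curve is traced by
    a descending-score sweep with tie groups stepped jointly, so the
    trapezoidal area under it equals the rank statistic.
    """
    n_active, n_decoy = _check_two_class(scored)
    scores = np.array([s for s, _ in scored], dtype=float)
    is_active = np.array([lab == "active" for _, lab in scored])
    ranks = rankdata(scores)  # average ranks for ties
    auc = (ranks[is_active].sum() - n_active * (n_active + 1) / 2) / (
        n_active * n_decoy
    )
    points = [(0.0, 0.0)]
    tp = fp = 0
    for score in sorted(set(scores), reverse=True):
        group = scores == score
        tp += int(np.sum(group & is_active))
        fp += int(np.sum(group & ~is_active))
        points.append((fp / n_decoy, tp / n_active))
    return ROCResult(_pessimistic_order(scored), points, float(auc))


def trapezoid_auc(points: list[tuple[float, float]]) -> float:
    """Trapezoidal integration of an ROC step curve (oracle counterpart of
    the rank-statistic AUC)."""
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2
    return area


@dataclass
class EnrichmentResult:
    fraction: float
    n_top: int
    actives_in_top: int
    ef: float  # (actives_in_top/total_actives) / fraction
    pct_actives_in_top: float  # actives_in_top / n_top * 100 (the "% actives" convention)
    recall: float  # actives_in_top / total_actives


def enrichment(scored: list[tuple[float, str]], fraction: float) -> EnrichmentResult:
    """Early enrichment at a screened fraction, with pessimistic ties.

    ``ef`` is the enrichment factor EF(x) = (actives_in_top / total_actives)
    / x; ``pct_actives_in_top`` is the percentage of the top slots occupied
    by actives.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_active, _ = _check_two_class(scored)
    order = _pessimistic_order(scored)
    n_top = math.ceil(fraction * len(order))
    actives_in_top = sum(1 for lab in order[:n_top] if lab == "active")
    recall = actives_in_top / n_active
    return EnrichmentResult(
        fraction=fraction,
        n_top=n_top,
        actives_in_top=actives_in_top,
        ef=recall / fraction,
        pct_actives_in_top=100.0 * actives_in_top / n_top,
        recall=recall,
    )


def fraction_to_recall(scored: list[tuple[float, str]], recall: float) -> float:
    """Smallest fraction of the deck that must be screened (pessimistic
    order) for the recall of actives to reach ``recall``."""
    if not 0 < recall <= 1:
        raise ValueError("recall must be in (0, 1]")
    n_active, _ = _check_two_class(scored)
    needed = math.ceil(recall * n_active)
    order = _pessimistic_order(scored)
    seen = 0
    for i, lab in enumerate(order, start=1):
        if lab == "active":
            seen += 1
            if seen >= needed:
                return i / len(order)
    return 1.0
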