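"""Cross-predictor consensus calling for proteome-scale screens.

When no holo reference exists (e.g. screening AlphaFold models of an
entire proteome), a protein is called a zinc protein when at least two
independent predictors propose the *same site*.  "Same site" mirrors the
n−1 matching rule of the reference benchmark: two residue sets agree when
they share all but at most one residue of the smaller set.

Per-predictor confusion matrices follow the negative-output convention:
a predictor whose outputs for a structure all fail its score threshold
(or that produced nothing) makes a *negative* call — a true negative on a
structure without consensus sites, a false negative per consensus site it
thereby misses.  Passing predictions that match a consensus site are true
positives; passing predictions matching nothing are false positives, so a
site missed while the tool still emitted passing (wrong) predictions costs
precision, not recall bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .predictions import Prediction, ScoreConvention, is_negative_output, select_top
from .scoring import MetricError, round_pct


class ConsensusError(ValueError):
    """Domain error for consensus analysis."""


@dataclass(eq=False)
class ConsensusSite:
    struct_id: str
    residues: FrozenSet
    supporters: FrozenSet[str]

    def __post_init__(self) -> None:
        self.residues = frozenset(self.residues)
        self.supporters = frozenset(self.supporters)
        if len(self.supporters) < 2:
            raise ConsensusError("a consensus site needs >= 2 supporters")


@dataclass
class ConfusionMatrix:
    predictor_id: str
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def precision_pct(self) -> float:
        if self.tp + self.fp == 0:
            raise MetricError("precision undefined: no positive predictions")
        return 100.0 * self.tp / (self.tp + self.fp)

    def recall_pct(self, total_sites: int) -> float:
        if total_sites <= 0:
            raise MetricError("recall undefined: no consensus sites")
        return 100.0 * self.tp / total_sites


def same_site(a: Set, b: Set) -> bool:
    """Agreement rule: the sets share all but at most one of the smaller set."""
    if not a or not b:
        raise ConsensusError("same_site requires non-empty residue sets")
    return len(frozenset(a) & frozenset(b)) >= min(len(a), len(b)) - 1


def call_consensus(
    preds_by_predictor: Mapping[str, Sequence[FrozenSet]],
    struct_id: str,
    min_support: int = 2,
    predictor_order: Optional[Sequence[str]] = None,
) -> List[ConsensusSite]:
    """Cluster one structure's per-predictor residue-set predictions.

    Greedy: predictions are visited in (predictor order, rank) order; each
    joins the first cluster whose seed it agrees with (``same_site``) and
    that its predictor has not already supported, else seeds a new cluster.
    Clusters backed by >= ``min_support`` distinct predictors become
    consensus sites; the consensus residue set is the most frequent set in
    the cluster (ties: the set contributed by the earliest predictor).
    """
    if min_support < 2:
        raise ConsensusError("min_support must be >= 2")
    order = list(predictor_order) if predictor_order else sorted(preds_by_predictor)
    clusters: List[List[Tuple[int, FrozenSet]]] = []  # (predictor index, set)
    for p_idx, pid in enumerate(order):
        for residues in preds_by_predictor.get(pid, []):
            residues = frozenset(residues)
            if not residues:  # empty attribution supports no site
                continue
            placed = False
            for cluster in clusters:
                if any(member_idx == p_idx for member_idx, _ in cluster):
                    continue
                if same_site(residues, cluster[0][1]):
                    cluster.append((p_idx, residues))
                    placed = True
                    break
            if not placed:
                clusters.append([(p_idx, residues)])

    sites = []
    for cluster in clusters:
        supporters = {order[i] for i, _ in cluster}
        if len(supporters) < min_support:
            continue
        freq: Dict[FrozenSet, int] = {}
        first_seen: Dict[FrozenSet, int] = {}
        for i, residues in cluster:
            freq[residues] = freq.get(residues, 0) + 1
            first_seen.setdefault(residues, i)
        best = min(freq, key=lambda r: (-freq[r], first_seen[r]))
        sites.append(
            ConsensusSite(struct_id=struct_id, residues=best, supporters=frozenset(supporters))
        )
    return sites


def confusion(
    predictor_id: str,
    preds_by_structure: Mapping[str, Sequence[Prediction]],
    conv: ScoreConvention,
    consensus_sites: Sequence[ConsensusSite],
    structure_universe: Iterable[str],
    top_m: int = 5,
) -> ConfusionMatrix:
    """Confusion matrix of one predictor against the consensus reference."""
    universe = set(structure_universe)
    unknown = set(preds_by_structure) - universe
    if unknown:
        raise ConsensusError(
            f"predictions for structures outside the reference universe: {sorted(unknown)}"
        )
    sites_by_struct: Dict[str, List[ConsensusSite]] = {}
    for site in consensus_sites:
        sites_by_struct.setdefault(site.struct_id, []).append(site)

    cm = ConfusionMatrix(predictor_id=predictor_id)
    for sid in sorted(universe):
        preds = list(preds_by_structure.get(sid, []))
        sites_here = sites_by_struct.get(sid, [])
        if is_negative_output(preds, conv):
            if sites_here:
                cm.fn += len(sites_here)
            else:
                cm.tn += 1
            continue
        passing = select_top(preds, conv, top_m)
        passing_sets = []
        for p in passing:
            if p.residues is None:
                raise ConsensusError(
                    "coordinate predictions must be attributed to residues "
                    "before the consensus analysis"
                )
            passing_sets.append(p.residues)
        used = [False] * len(passing_sets)
        for site in sites_here:
            matched = False
            for idx, residues in enumerate(passing_sets):
                if not used[idx] and residues and same_site(residues, site.residues):
                    used[idx] = True
                    matched = True
                    break
            if matched:
                cm.tp += 1
            # a positive-output miss is covered by the FPs below
        cm.fp += sum(1 for u in used if not u)
    return cm


def venn_partition(
    reference: Sequence[ConsensusSite],
) -> Tuple[Dict[FrozenSet[str], int], Dict[FrozenSet[str], float]]:
    """Counts and half-up integer percentages of sites per supporter subset."""
    counts: Dict[FrozenSet[str], int] = {}
    for site in reference:
        counts[site.supporters] = counts.get(site.supporters, 0) + 1
    total = len(reference)
    pcts = {
        subset: round_pct(100.0 * n / total, ndigits=0)
        for subset, n in counts.items()
    }
    return counts, pcts


def pairwise_agreement(
    reference: Sequence[ConsensusSite],
    predictors: Sequence[str],
) -> Dict[Tuple[str, str], float]:
    """Fraction of consensus sites supported by both tools of each pair (%)."""
    total = len(reference)
    out = {}
    for i, a in enumerate(predictors):
        for b in predictors[i + 1:]:
            both = sum(1 for s in reference if a in s.supporters and b in s.supporters)
            out[(a, b)] = 100.0 * both / total if total else 0.0
    return out
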