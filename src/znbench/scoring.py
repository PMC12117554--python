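"""Prediction–site matching and benchmark statistics.

A prediction of a site with n ligand residues is a true positive (TP) when
it names at least n−1 of them; further TPs matching an already-identified
site are *redundant* TPs (RTP); everything else is a false positive (FP).
Precision keeps RTPs in the numerator (they are correct predictions).

Recall for multi-site structures uses the capped denominator: when only m
predictions per structure are examined, a structure with k sites can
contribute at most min(k, m) identifiable sites, so the denominator is

    sum_k  N_k_sites * min(k, m) / k

where N_k_sites is the number of sites contained in structures holding
exactly k sites.  With this definition R(top m) can *decrease* as m grows,
unlike the recall of ordinary binary classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .predictions import Prediction
from .structures import Cles, ReferenceSite

TP = "TP"
RTP = "RTP"
FP = "FP"


class MetricError(ValueError):
    """Raised when a statistic is undefined for the given counts."""


def round_pct(value: float, ndigits: int = 1) -> float:
    """Round-half-up percentage rounding (what printed tables use)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(eq=False)
class MatchRecord:
    prediction: Prediction
    label: str
    matched_site_id: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.label in (TP, RTP)) != (self.matched_site_id is not None):
            raise MetricError("TP/RTP records must carry a matched site id")


@dataclass(frozen=True)
class EvalTally:
    """Bookkeeping per predictor/m: outputs = TP (incl. redundant) + FP."""

    n_outputs: int
    n_tp: int  # includes redundant TPs
    n_rtp: int
    n_fp: int

    def __post_init__(self) -> None:
        if self.n_outputs != self.n_tp + self.n_fp:
            raise MetricError("n_outputs must equal n_tp + n_fp")
        if self.n_rtp > self.n_tp:
            raise MetricError("redundant TPs cannot exceed TPs")
        if min(self.n_outputs, self.n_tp, self.n_rtp, self.n_fp) < 0:
            raise MetricError("counts must be non-negative")


@dataclass(frozen=True)
class SiteCounts:
    """Sites stratified by how many sites their parent structure holds."""

    per_k: Mapping[int, int]
    total_structures: int

    def __post_init__(self) -> None:
        for k, n_sites in self.per_k.items():
            if k < 1 or n_sites % k:
                raise MetricError(
                    f"per_k[{k}] = {n_sites} is not divisible by {k}"
                )

    @classmethod
    def from_sites(cls, sites: Sequence[ReferenceSite]) -> "SiteCounts":
        by_struct: Dict[str, int] = {}
        for site in sites:
            by_struct[site.struct_id] = by_struct.get(site.struct_id, 0) + 1
        per_k: Dict[int, int] = {}
        for k in by_struct.values():
            per_k[k] = per_k.get(k, 0) + k
        return cls(per_k=per_k, total_structures=len(by_struct))

    @property
    def total_sites(self) -> int:
        return sum(self.per_k.values())

    def denominator(self, m: int) -> float:
        """Number of sites identifiable when m predictions/structure are read."""
        return sum(n_sites * min(k, m) / k for k, n_sites in self.per_k.items())


@dataclass(frozen=True)
class MetricSet:
    precision_pct: float
    recall_pct: float
    r_top_pct: Mapping[int, float] = field(default_factory=dict)
    f1_pct: Optional[float] = None


# ---------------------------------------------------------------------------
# matching


def match_one(pred_residues: Set, site: ReferenceSite) -> bool:
    """TP criterion: at least n−1 of the site's n ligands are predicted."""
    n = site.n
    return len(frozenset(pred_residues) & site.ligand_set) >= n - 1


def classify(
    preds: Sequence[Prediction],
    sites: Sequence[ReferenceSite],
    nonredundant: bool = False,
) -> List[MatchRecord]:
    """Label best-first-ordered predictions against a structure's sites.

    The best-ranked match per reference site is its primary TP; later
    matches to the same site are RTPs.  A prediction matching several sites
    is assigned to the one sharing most ligands (ties: earlier site in
    input order).  ``nonredundant=True`` drops RTP records entirely,
    mimicking a user who collapses near-identical predictions.
    """
    site_ids = [s.site_id for s in sites]
    if len(set(site_ids)) != len(site_ids):
        raise MetricError("duplicate site_ids in reference list")
    records: List[MatchRecord] = []
    claimed: Set[str] = set()
    for pred in preds:
        if pred.residues is None:
            raise MetricError(
                "coordinate predictions must be attributed to residues before "
                "classification (see predictions.attribute_residues)"
            )
        best_site = None
        best_overlap = -1
        for site in sites:
            overlap = len(pred.residues & site.ligand_set)
            if overlap >= site.n - 1 and overlap > best_overlap:
                best_site, best_overlap = site, overlap
        if best_site is None:
            records.append(MatchRecord(pred, FP))
        elif best_site.site_id in claimed:
            if not nonredundant:
                records.append(MatchRecord(pred, RTP, best_site.site_id))
        else:
            claimed.add(best_site.site_id)
            records.append(MatchRecord(pred, TP, best_site.site_id))
    return records


def tally(records: Sequence[MatchRecord]) -> EvalTally:
    n_tp = sum(1 for r in records if r.label in (TP, RTP))
    n_rtp = sum(1 for r in records if r.label == RTP)
    n_fp = sum(1 for r in records if r.label == FP)
    return EvalTally(n_outputs=len(records), n_tp=n_tp, n_rtp=n_rtp, n_fp=n_fp)


def unique_tp(records: Sequence[MatchRecord]) -> int:
    """Number of distinct reference sites identified (RTPs excluded)."""
    return len({r.matched_site_id for r in records if r.label == TP})


def hit_sites(records: Sequence[MatchRecord]) -> Set[str]:
    return {r.matched_site_id for r in records if r.label in (TP, RTP)}


# ---------------------------------------------------------------------------
# statistics


def precision(t: EvalTally) -> float:
    """Percentage of correct predictions (redundant TPs count as correct)."""
    if t.n_outputs == 0:
        raise MetricError("precision undefined: no outputs")
    return 100.0 * t.n_tp / t.n_outputs


def capped_recall(n_unique_tp: int, counts: SiteCounts, m: int) -> float:
    """Recall against the sites identifiable from m predictions/structure."""
    denom = counts.denominator(m)
    if denom <= 0:
        raise MetricError("capped recall undefined: empty site counts")
    return 100.0 * n_unique_tp / denom

def r_top(n_unique_tp: int, counts: SiteCounts, m: int) -> float:
    """R(top m): unique-TP recall with the capped denominator.

    For multi-site structures a TP on *any* of the structure's sites counts
    toward the numerator, which is why the numerator is the count of
    distinct identified sites rather than a per-structure indicator.
    """
    return capped_recall(n_unique_tp, counts, m)


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (both as percentages)."""
    if p < 0 or r < 0:
        raise MetricError("precision/recall must be non-negative")
    if p + r == 0:
        raise MetricError("F1 undefined: precision and recall both zero")
    return 2.0 * p * r / (p + r)


def cles_recall(
    per_site_hit: Mapping[str, bool],
    cles_list: Sequence[Cles],
) -> Tuple[Dict[str, bool], float]:
    """Per-family recall: a CLES counts identified at >= 50% member sites hit."""
    if not cles_list:
        raise MetricError("no CLES supplied")
    identified: Dict[str, bool] = {}
    for cles in cles_list:
        hits = 0
        for site_id in cles.site_ids:
            if site_id not in per_site_hit:
                raise MetricError(
                    f"site {site_id} of CLES {cles.cles_id} has no hit entry"
                )
            hits += bool(per_site_hit[site_id])
        identified[cles.cles_id] = hits / cles.n_sites >= 0.5
    pct = 100.0 * sum(identified.values()) / len(identified)
    return identified, pct
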