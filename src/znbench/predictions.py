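"""Normalisation of heterogeneous predictor outputs.

Structure-based zinc-site predictors come in two flavours: *site*
predictors emit a ranked list of residue sets, *location* predictors emit
ranked metal coordinates.  Both are normalised here into
:class:`Prediction` records; coordinate payloads are converted to residue
sets with :func:`attribute_residues` (non-hydrogen atoms within 3.8 Å of
the predicted metal position).  Each tool's score semantics live in a
:class:`ScoreConvention` (direction + optional pass threshold, inclusive
on the passing side).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .structures import ResidueKey, Structure, find_ligands, format_key, parse_key

ATTRIBUTION_CUTOFF = 3.8  # Å, predicted metal position -> attributed residues

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"


class PredictionError(ValueError):
    """Domain error for prediction handling."""


@dataclass(frozen=True)
class ScoreConvention:
    """Per-predictor score semantics.

    ``threshold`` is inclusive on the passing side: with ``higher_better``
    a score passes iff score >= threshold, with ``lower_better`` iff
    score <= threshold.  No threshold means every score passes.
    """

    predictor_id: str
    direction: str = HIGHER_BETTER
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER_BETTER, LOWER_BETTER):
            raise PredictionError(f"unknown score direction {self.direction!r}")

    def passes(self, score: float) -> bool:
        if self.threshold is None:
            return True
        if self.direction == HIGHER_BETTER:
            return score >= self.threshold
        return score <= self.threshold

    def sort_key(self, score: float) -> float:
        return -score if self.direction == HIGHER_BETTER else score


@dataclass(eq=False)
class Prediction:
    """One ranked predictor output: a residue set or a metal coordinate."""

    predictor_id: str
    struct_id: str
    rank: int
    score: float
    residues: Optional[frozenset] = None
    coordinate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if (self.residues is None) == (self.coordinate is None):
            raise PredictionError(
                "a prediction carries exactly one payload: residues or coordinate"
            )
        if self.residues is not None:
            self.residues = frozenset(self.residues)
        else:
            self.coordinate = np.asarray(self.coordinate, dtype=float)
            if self.coordinate.shape != (3,):
                raise PredictionError("coordinate payload must be a 3D point")

    @property
    def payload_type(self) -> str:
        return "residues" if self.residues is not None else "coordinate"


def attribute_residues(
    structure: Structure,
    metal_pos: Sequence[float],
    cutoff: float = ATTRIBUTION_CUTOFF,
) -> set:
    """Residues attributed to a predicted metal position (<= cutoff Å)."""
    if cutoff < 0:
        raise PredictionError("cutoff must be non-negative")
    return find_ligands(structure, metal_pos, cutoff=cutoff)


def select_top(
    preds: Sequence[Prediction],
    conv: ScoreConvention,
    m: int,
) -> List[Prediction]:
    """Threshold-filter, sort best-first and keep at most ``m`` predictions.

    Ties keep input order (stable sort).  The result may be shorter than
    ``m`` — or empty — when the threshold discards outputs.
    """
    preds = list(preds)
    if not preds:
        return []
    if len({p.predictor_id for p in preds}) > 1:
        raise PredictionError("select_top requires predictions from one predictor")
    if len({p.struct_id for p in preds}) > 1:
        raise PredictionError("select_top requires predictions for one structure")
    survivors = [p for p in preds if conv.passes(p.score)]
    survivors.sort(key=lambda p: conv.sort_key(p.score))
    return survivors[: max(m, 0)]


def is_negative_output(preds: Sequence[Prediction], conv: ScoreConvention) -> bool:
    """True iff no prediction passes the threshold (vacuously true if empty)."""
    return not any(conv.passes(p.score) for p in preds)


# ---------------------------------------------------------------------------
# interchange format

_PRED_COLUMNS = [
    "predictor_id", "struct_id", "rank", "score",
    "payload_type", "residues", "x", "y", "z",
]


def save_predictions(preds: Iterable[Prediction], path) -> None:
    rows = []
    for p in preds:
        rows.append(
            {
                "predictor_id": p.predictor_id,
                "struct_id": p.struct_id,
                "rank": p.rank,
                "score": p.score,
                "payload_type": p.payload_type,
                "residues": ";".join(sorted(format_key(k) for k in p.residues))
                if p.residues is not None
                else "",
                "x": None if p.coordinate is None else float(p.coordinate[0]),
                "y": None if p.coordinate is None else float(p.coordinate[1]),
                "z": None if p.coordinate is None else float(p.coordinate[2]),
            }
        )
    pd.DataFrame(rows, columns=_PRED_COLUMNS).to_csv(path, index=False)


def load_predictions(path) -> List[Prediction]:
    df = pd.read_csv(path)
    preds = []
    for row in df.itertuples(index=False):
        if row.payload_type == "residues":
            keys = frozenset(parse_key(t) for t in str(row.residues).split(";") if t)
            if not keys:
                raise PredictionError(
                    f"residue prediction without residues: {row.predictor_id} "
                    f"{row.struct_id} rank {row.rank}"
                )
            payload = {"residues": keys}
        elif row.payload_type == "coordinate":
            payload = {"coordinate": np.array([row.x, row.y, row.z], dtype=float)}
        else:
            raise PredictionError(f"unknown payload type {row.payload_type!r}")
        preds.append(
            Prediction(
                predictor_id=str(row.predictor_id),
                struct_id=str(row.struct_id),
                rank=int(row.rank),
                score=float(row.score),
                **payload,
            )
        )
    return preds


def save_conventions(convs: Dict[str, ScoreConvention], path) -> None:
    payload = {
        pid: {"direction": c.direction, "threshold": c.threshold}
        for pid, c in convs.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_conventions(path) -> Dict[str, ScoreConvention]:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return {
        pid: ScoreConvention(
            predictor_id=pid,
            direction=spec.get("direction", HIGHER_BETTER),
            threshold=spec.get("threshold"),
        )
        for pid, spec in payload.items()
    }
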