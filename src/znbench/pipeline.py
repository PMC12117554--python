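"""End-to-end orchestration: files in, metric tables out.

``run_benchmark`` reproduces the reference-benchmark bookkeeping (per
predictor and per top-m cut: outputs / TP / redundant / FP, precision,
capped recall R(top m), F1, per-CLES recall, optional non-redundant
variant).  ``run_consensus`` implements the proteome-screen analysis
(consensus sites, per-predictor confusion matrices, Venn partition).
``run_variability`` builds per-CLES donor-distance tensors and outlier
reports.  Outputs are deterministic: re-running with identical inputs
yields byte-identical CSV/JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import consensus as cons
from .predictions import (
    ATTRIBUTION_CUTOFF,
    Prediction,
    ScoreConvention,
    attribute_residues,
    load_conventions,
    load_predictions,
    select_top,
)
from .scoring import (
    MetricError,
    SiteCounts,
    classify,
    cles_recall,
    f1,
    hit_sites,
    precision,
    r_top,
    round_pct,
    tally,
    unique_tp,
)
from .structures import (
    Cles,
    ReferenceSite,
    Structure,
    StructureError,
    group_cles,
    load_reference_table,
    parse_structure,
)
from .variability import (
    build_tensor,
    cooccurrence_groups,
    flag_outliers,
    outlier_report_json,
    pair_spread_frame,
)

log = logging.getLogger("znbench")


@dataclass
class RunConfig:
    structures_dir: Optional[str] = None
    reference_table: Optional[str] = None
    predictions: Optional[str] = None
    conventions: Optional[str] = None
    output_dir: str = "znbench-out"
    ligand_cutoff: float = 3.0
    shell_cutoff: float = 5.0
    attribution_cutoff: float = ATTRIBUTION_CUTOFF
    top_m: Tuple[int, ...] = (1, 3, 5, 10)
    cles_threshold: float = 0.5
    outlier_k_sd: float = 2.0
    outlier_min_entries: int = 2
    consensus_min_support: int = 2
    consensus_top_m: int = 5
    nonredundant: bool = False
    bfactor_is_plddt: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for cutoff in (self.ligand_cutoff, self.shell_cutoff, self.attribution_cutoff):
            if cutoff <= 0:
                raise StructureError("cutoffs must be positive")
        self.top_m = tuple(sorted(int(m) for m in self.top_m))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


# ---------------------------------------------------------------------------
# loading helpers


def load_structures(directory, bfactor_is_plddt: bool = False) -> Dict[str, Structure]:
    structures = {}
    for path in sorted(Path(directory).glob("*.pdb")):
        struct_id = path.stem
        structures[struct_id] = parse_structure(
            path.read_text(), struct_id=struct_id, bfactor_is_plddt=bfactor_is_plddt
        )
        log.info("loaded structure %s (%d residues)", struct_id, len(structures[struct_id].residues))
    return structures


def _check_cross_references(
    structures: Mapping[str, Structure], sites: Sequence[ReferenceSite]
) -> None:
    missing = sorted({s.struct_id for s in sites} - set(structures))
    if missing:
        raise StructureError(f"sites reference missing structures: {missing}")


def _resolve_payloads(
    preds: Sequence[Prediction],
    structures: Mapping[str, Structure],
    cutoff: float,
) -> List[Prediction]:
    """Convert coordinate payloads to residue sets; empty sets stay (they FP)."""
    out = []
    for p in preds:
        if p.coordinate is not None:
            residues = attribute_residues(structures[p.struct_id], p.coordinate, cutoff)
            out.append(
                Prediction(
                    predictor_id=p.predictor_id,
                    struct_id=p.struct_id,
                    rank=p.rank,
                    score=p.score,
                    residues=frozenset(residues),  # may be empty: matches nothing, counts FP
                )
            )
        else:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# benchmark evaluation


def evaluate_benchmark(
    structures: Mapping[str, Structure],
    sites: Sequence[ReferenceSite],
    predictions: Sequence[Prediction],
    conventions: Mapping[str, ScoreConvention],
    top_m: Sequence[int] = (1, 3, 5, 10),
    attribution_cutoff: float = ATTRIBUTION_CUTOFF,
    nonredundant: bool = False,
    cles_list: Optional[Sequence[Cles]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Core benchmark: returns (metric rows, per-CLES recall rows)."""
    _check_cross_references(structures, sites)
    counts = SiteCounts.from_sites(sites)
    sites_by_struct: Dict[str, List[ReferenceSite]] = {}
    for site in sites:
        sites_by_struct.setdefault(site.struct_id, []).append(site)
    if cles_list is None:
        cles_list = group_cles(sites)

    preds_by: Dict[Tuple[str, str], List[Prediction]] = {}
    skipped = 0
    for p in predictions:
        if p.struct_id not in structures:
            log.warning(
                "discarding prediction for unknown structure %s (%s rank %d)",
                p.struct_id, p.predictor_id, p.rank,
            )
            skipped += 1
            continue
        preds_by.setdefault((p.predictor_id, p.struct_id), []).append(p)
    if skipped:
        log.warning("discarded %d predictions with unknown structures", skipped)

    predictors = sorted({pid for pid, _ in preds_by})
    rows = []
    cles_rows = []
    for pid in predictors:
        conv = conventions.get(pid, ScoreConvention(predictor_id=pid))
        struct_ids = sorted(sid for p, sid in preds_by if p == pid)
        for m in top_m:
            records = []
            for sid in struct_ids:
                top = select_top(preds_by[(pid, sid)], conv, m)
                top = _resolve_payloads(top, structures, attribution_cutoff)
                records.extend(classify(top, sites_by_struct.get(sid, []), nonredundant))
            t = tally(records)
            utp = unique_tp(records)
            prec = precision(t) if t.n_outputs else float("nan")
            rec = r_top(utp, counts, m)
            f1v = f1(prec, rec) if (t.n_outputs and prec + rec > 0) else float("nan")
            rows.append(
                {
                    "evaluated_m": m,
                    "predictor": pid,
                    "n_outputs": t.n_outputs,
                    "n_tp": t.n_tp,
                    "n_redundant": t.n_rtp,
                    "n_fp": t.n_fp,
                    "precision_pct": round_pct(prec) if t.n_outputs else float("nan"),
                    "recall_pct": round_pct(rec),
                    "f1_pct": round_pct(f1v) if f1v == f1v else float("nan"),
                }
            )
            if cles_list:
                hits = hit_sites(records)
                per_site_hit = {s.site_id: (s.site_id in hits) for s in sites}
                identified, pct = cles_recall(per_site_hit, cles_list)
                cles_rows.append(
                    {
                        "evaluated_m": m,
                        "predictor": pid,
                        "n_cles": len(identified),
                        "n_identified": sum(identified.values()),
                        "cles_recall_pct": round_pct(pct),
                    }
                )
    metrics = pd.DataFrame(rows).sort_values(["predictor", "evaluated_m"]).reset_index(drop=True)
    cles_df = pd.DataFrame(cles_rows)
    if not cles_df.empty:
        cles_df = cles_df.sort_values(["predictor", "evaluated_m"]).reset_index(drop=True)
    return metrics, cles_df


def run_benchmark(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """File-based benchmark run; writes CSV reports under output_dir."""
    structures = load_structures(config.structures_dir, config.bfactor_is_plddt)
    sites = load_reference_table(config.reference_table)
    predictions = load_predictions(config.predictions)
    conventions = load_conventions(config.conventions) if config.conventions else {}
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    bundles = {}
    for label, flag in (("metrics", False), ("metrics_nonredundant", True)):
        if flag and not config.nonredundant:
            continue
        metrics, cles_df = evaluate_benchmark(
            structures,
            sites,
            predictions,
            conventions,
            top_m=config.top_m,
            attribution_cutoff=config.attribution_cutoff,
            nonredundant=flag,
        )
        _write_csv(metrics, out_dir / f"{label}.csv")
        bundles[label] = metrics
        if not flag:
            _write_csv(cles_df, out_dir / "cles_recall.csv")
            bundles["cles_recall"] = cles_df
    return bundles


# ---------------------------------------------------------------------------
# variability


def run_variability(
    structures: Mapping[str, Structure],
    sites: Sequence[ReferenceSite],
    k_sd: float = 2.0,
    min_entries: int = 2,
    output_dir: Optional[str] = None,
) -> Dict[str, Dict]:
    """Per-CLES donor-distance tensors, outlier flags, subcluster groups."""
    _check_cross_references(structures, sites)
    by_cles: Dict[str, List[ReferenceSite]] = {}
    for site in sites:
        if site.cles_id:
            by_cles.setdefault(site.cles_id, []).append(site)
    results = {}
    violin_frames = []
    for cles_id in sorted(by_cles):
        members = [(s, structures[s.struct_id]) for s in by_cles[cles_id]]
        tensor = build_tensor(members, cles_id=cles_id)
        reports = flag_outliers(tensor, k_sd=k_sd, min_entries=min_entries)
        groups = cooccurrence_groups(reports, tensor)
        results[cles_id] = {
            "tensor": tensor,
            "reports": reports,
            "groups": groups,
        }
        violin_frames.append(pair_spread_frame(tensor))
    if output_dir is not None:
        out_dir = Path(output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_csv(pd.concat(violin_frames, ignore_index=True), out_dir / "violin_data.csv")
        payload = {
            cles_id: {
                "outliers": outlier_report_json(res["reports"]),
                "groups": res["groups"],
            }
            for cles_id, res in results.items()
        }
        (out_dir / "outliers.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return results


# ---------------------------------------------------------------------------
# consensus


def run_consensus(
    structures: Mapping[str, Structure],
    predictions: Sequence[Prediction],
    conventions: Mapping[str, ScoreConvention],
    min_support: int = 2,
    top_m: int = 5,
    attribution_cutoff: float = ATTRIBUTION_CUTOFF,
    predictor_order: Optional[Sequence[str]] = None,
    output_dir: Optional[str] = None,
) -> Dict:
    """Consensus calling + per-predictor confusion matrices + Venn cells."""
    predictors = sorted({p.predictor_id for p in predictions})
    if len(predictors) < 2:
        raise cons.ConsensusError("consensus analysis needs >= 2 predictors")
    order = list(predictor_order) if predictor_order else predictors

    by_struct_pred: Dict[str, Dict[str, List[Prediction]]] = {}
    for p in predictions:
        if p.struct_id not in structures:
            log.warning("discarding prediction for unknown structure %s", p.struct_id)
            continue
        by_struct_pred.setdefault(p.struct_id, {}).setdefault(p.predictor_id, []).append(p)

    universe = sorted(structures)
    all_sites: List[cons.ConsensusSite] = []
    resolved: Dict[str, Dict[str, List[Prediction]]] = {}
    for sid in universe:
        per_pred = by_struct_pred.get(sid, {})
        passing_sets = {}
        resolved[sid] = {}
        for pid in order:
            conv = conventions.get(pid, ScoreConvention(predictor_id=pid))
            top = select_top(per_pred.get(pid, []), conv, top_m)
            top = _resolve_payloads(top, structures, attribution_cutoff)
            resolved[sid][pid] = top
            passing_sets[pid] = [p.residues for p in top]
        all_sites.extend(
            cons.call_consensus(passing_sets, sid, min_support=min_support, predictor_order=order)
        )

    matrices = {}
    for pid in order:
        conv = conventions.get(pid, ScoreConvention(predictor_id=pid))
        preds_by_structure = {sid: resolved[sid][pid] for sid in universe}
        matrices[pid] = cons.confusion(
            pid, preds_by_structure, conv, all_sites, universe, top_m=top_m
        )
    venn_counts, venn_pcts = cons.venn_partition(all_sites) if all_sites else ({}, {})

    result = {
        "sites": all_sites,
        "confusion": matrices,
        "venn_counts": venn_counts,
        "venn_pcts": venn_pcts,
        "n_sites": len(all_sites),
    }
    if output_dir is not None:
        out_dir = Path(output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_consensus_reports(result, order, out_dir)
    return result


def _write_consensus_reports(result: Dict, order: Sequence[str], out_dir: Path) -> None:
    from .structures import format_key

    sites_payload = [
        {
            "struct_id": s.struct_id,
            "residues": sorted(format_key(k) for k in s.residues),
            "supporters": sorted(s.supporters),
        }
        for s in result["sites"]
    ]
    (out_dir / "consensus_sites.json").write_text(
        json.dumps(sites_payload, indent=1, sort_keys=True)
    )
    total = result["n_sites"]
    rows = []
    for pid in order:
        cm = result["confusion"][pid]
        rows.append(
            {
                "predictor": pid,
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "recall_pct": round_pct(cm.recall_pct(total)) if total else float("nan"),
                "precision_pct": round_pct(cm.precision_pct()) if cm.tp + cm.fp else float("nan"),
            }
        )
    _write_csv(pd.DataFrame(rows), out_dir / "confusion.csv")
    venn_rows = [
        {
            "supporters": "+".join(sorted(subset)),
            "count": count,
            "pct": result["venn_pcts"][subset],
        }
        for subset, count in sorted(
            result["venn_counts"].items(), key=lambda kv: "+".join(sorted(kv[0]))
        )
    ]
    _write_csv(pd.DataFrame(venn_rows), out_dir / "venn.csv")


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")
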