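#!/usr/bin/env python
"""Recompute every published benchmark metric from its printed counts.

Feeds the stored count tables (apo benchmark tallies, consensus confusion
counts, Venn cells) through this package's metric functions and tabulates
recomputed vs printed values side by side in results/.
"""

from pathlib import Path

import pandas as pd

from znbench import datasets
from znbench.consensus import ConfusionMatrix
from znbench.scoring import precision, round_pct

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for (m, predictor), (t, printed_p, printed_r) in sorted(
        datasets.APO_BENCHMARK.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        rows.append(
            {
                "evaluated_m": m,
                "predictor": predictor,
                "n_outputs": t.n_outputs,
                "n_tp": t.n_tp,
                "n_redundant": t.n_rtp,
                "n_fp": t.n_fp,
                "precision_recomputed": round_pct(precision(t)),
                "precision_printed": printed_p,
                "recall_printed": printed_r,
            }
        )
    apo = pd.DataFrame(rows)
    apo["delta"] = (apo.precision_recomputed - apo.precision_printed).round(2)
    apo.to_csv(RESULTS / "reference_apo_precision.csv", index=False)
    print(apo.to_string(index=False))
    print(f"\nmax |recomputed - printed| precision: {apo.delta.abs().max():.2f} pts")

    rows = []
    for predictor, (tp, fp, tn, fn, printed_r, printed_p) in sorted(
        datasets.CONSENSUS_BENCHMARK.items()
    ):
        cm = ConfusionMatrix(predictor, tp=tp, fp=fp, tn=tn, fn=fn)
        rows.append(
            {
                "predictor": predictor,
                "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                "recall_recomputed": round_pct(
                    cm.recall_pct(datasets.CONSENSUS_TOTAL_SITES)
                ),
                "recall_printed": printed_r,
                "precision_recomputed": round_pct(cm.precision_pct()),
                "precision_printed": printed_p,
            }
        )
    cons = pd.DataFrame(rows)
    cons.to_csv(RESULTS / "reference_consensus_metrics.csv", index=False)
    print("\n" + cons.to_string(index=False))

    rows = []
    for label, (count, printed_pct) in datasets.VENN_CELLS.items():
        rows.append(
            {
                "cell": label,
                "count": count,
                "pct_recomputed": round_pct(
                    100.0 * count / datasets.CONSENSUS_TOTAL_SITES, 0
                ),
                "pct_printed": printed_pct,
            }
        )
    venn = pd.DataFrame(rows)
    venn.to_csv(RESULTS / "reference_venn.csv", index=False)
    print("\n" + venn.to_string(index=False))


if __name__ == "__main__":
    main()
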