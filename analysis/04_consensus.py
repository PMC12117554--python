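#!/usr/bin/env python
"""Consensus zinc-protein calling across the simulated predictors.

Without reference sites, a structure is called a zinc protein when at
least two tools propose the same site (n-1 residue agreement).  Emits the
consensus sites, per-predictor confusion matrices (negative-output FN/TN
convention) and the Venn partition of supporter subsets to results/.
"""

import importlib
from pathlib import Path

from znbench.pipeline import run_consensus

sim = importlib.import_module("01_simulate")

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    dataset, _, preds, convs = sim.build_world()
    structures = {ss.struct_id: ss.structure for ss in dataset}
    result = run_consensus(
        structures, preds, convs, output_dir=str(RESULTS / "consensus")
    )
    total = result["n_sites"]
    print(f"{total} consensus sites across {len(structures)} structures")
    for pid, cm in result["confusion"].items():
        print(
            f"{pid:>8s}: tp={cm.tp:3d} fp={cm.fp:3d} tn={cm.tn:2d} fn={cm.fn:2d} "
            f"recall {cm.recall_pct(total):5.1f}%  precision {cm.precision_pct():5.1f}%"
        )
    for subset, pct in sorted(result["venn_pcts"].items(), key=lambda kv: -kv[1]):
        print(f"  {'+'.join(sorted(subset)):>22s}: {result['venn_counts'][subset]:3d} sites ({pct:.0f}%)")


if __name__ == "__main__":
    main()
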