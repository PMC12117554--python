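#!/usr/bin/env python
"""Quantify apo-site side-chain spread and recover planted subclusters.

Builds a CLES whose apo copies mix a dominant conformation with a planted
minority rearrangement mode (two donors displaced by 2.5 Å), computes the
donor-distance tensor, flags rearranged sites (>= 2 entries beyond 2 SD)
and groups them by co-occurring displacements.  Violin-plot data and the
outlier report go to results/.
"""

import json
from pathlib import Path

import numpy as np

from znbench.pipeline import run_variability
from znbench.synthetic import ApoNoiseModel, SiteTemplate, make_cles, mode_assignment

SEED = 21
N_SITES = 40

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    mode = np.zeros((4, 3))
    mode[0] = [2.5, 0, 0]
    mode[1] = [0, -2.5, 0]
    noise = ApoNoiseModel(
        sigma_iso=0.05,
        subcluster_modes=((np.zeros((4, 3)), 0.85), (mode, 0.15)),
    )
    _, sites, structures = make_cles(
        SiteTemplate(), N_SITES, noise, seed=SEED, cles_id="CLES-planted"
    )
    out_dir = RESULTS / "variability"
    results = run_variability(
        {s.struct_id: s for s in structures}, sites, output_dir=str(out_dir)
    )
    res = results["CLES-planted"]
    flagged = [r.site_id for r in res["reports"] if r.flagged]
    planted = {
        s.site_id
        for s, m in zip(sites, mode_assignment(noise, N_SITES, SEED))
        if m == 1
    }
    print(f"{N_SITES} apo sites, {len(planted)} carry the planted rearrangement")
    print(f"flagged: {sorted(flagged)}")
    print(f"planted: {sorted(planted)}")
    print(f"subcluster groups: {res['groups']}")
    recovered = set(flagged) == planted and [set(g) for g in res["groups"]] == [planted]
    print("planted subcluster recovered exactly" if recovered else "MISMATCH")
    (RESULTS / "variability" / "recovery.json").write_text(
        json.dumps(
            {
                "planted": sorted(planted),
                "flagged": sorted(flagged),
                "groups": res["groups"],
                "recovered": recovered,
            },
            indent=1,
        )
    )


if __name__ == "__main__":
    main()
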