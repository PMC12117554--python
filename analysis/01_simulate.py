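#!/usr/bin/env python
"""Generate the synthetic benchmark world used by the downstream analyses.

Writes PDB structures, the reference-site table and normalised predictor
outputs for three behaviourally distinct simulated tools (a precise
low-output one, a noisy high-output one, and a coordinate-emitting one)
under scratch/simulated/, and a small dataset summary under results/.
"""

from pathlib import Path

import pandas as pd

from znbench.predictions import save_conventions, save_predictions
from znbench.synthetic import (
    ApoNoiseModel,
    PredictorProfile,
    make_benchmark,
    simulate_predictor,
    write_dataset,
)

SEED = 20
N_STRUCTURES = 60
PROFILES = [
    PredictorProfile("precise", 0.85, 0.1, 0.3, 0.1, 0.95),
    PredictorProfile("noisy", 0.9, 0.3, 2.0, 0.3, 0.5),
    PredictorProfile("coords", 0.7, 0.0, 0.5, 0.0, 0.9, emit_coordinates=True),
]

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"


def build_world(seed: int = SEED, n_structures: int = N_STRUCTURES):
    dataset, cles_list = make_benchmark(
        n_structures, seed=seed, noise=ApoNoiseModel(sigma_iso=0.3)
    )
    preds, convs = [], {}
    for profile in PROFILES:
        preds.extend(simulate_predictor(dataset, profile, seed))
        convs[profile.predictor_id] = profile.get_convention()
    return dataset, cles_list, preds, convs


def main() -> None:
    dataset, cles_list, preds, convs = build_world()
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    structures_dir, table_path = write_dataset(dataset, SCRATCH)
    save_predictions(preds, SCRATCH / "predictions.csv")
    save_conventions(convs, SCRATCH / "conventions.yaml")

    n_sites = sum(len(ss.sites) for ss in dataset)
    summary = pd.DataFrame(
        [
            {
                "n_structures": len(dataset),
                "n_sites": n_sites,
                "n_cles": len(cles_list),
                "n_predictions": len(preds),
                "seed": SEED,
            }
        ]
    )
    summary.to_csv(RESULTS / "simulated_world_summary.csv", index=False)
    print(f"world: {len(dataset)} structures, {n_sites} sites, {len(cles_list)} CLES")
    print(f"structures -> {structures_dir}")
    print(f"reference table -> {table_path}")
    print(f"{len(preds)} predictions from {len(PROFILES)} simulated tools")


if __name__ == "__main__":
    main()
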