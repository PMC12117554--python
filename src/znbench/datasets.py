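"""Published count tables used as regression fixtures.

These are the raw tallies of a published comparative benchmark of five
structure-based zinc-site predictors (apo-structure benchmark and
AlphaFold-model consensus benchmark).  Only the *counts* are recorded;
every derived percentage in the tests is recomputed by this package's
metric functions and compared against the printed value at ±0.1
(the published rounding is occasionally half-down).
"""

from __future__ import annotations

from .scoring import EvalTally

#: apo-structure benchmark: (top-m cut, predictor) -> printed counts + metrics.
#: Tallies are (outputs, TP incl. redundant, redundant TP, FP); the last two
#: entries are the printed precision % and recall %.
APO_BENCHMARK = {
    (1, "M1D"): (EvalTally(385, 91, 0, 294), 23.6, 21.6),
    (1, "BioMetAll"): (EvalTally(338, 52, 0, 286), 15.4, 12.1),
    (1, "GASS"): (EvalTally(411, 143, 0, 268), 34.8, 34.5),
    (1, "MoM"): (EvalTally(238, 221, 0, 17), 92.8, 53.4),
    (1, "M3D"): (EvalTally(239, 154, 0, 85), 64.4, 36.9),
    (3, "M1D"): (EvalTally(759, 126, 2, 633), 16.6, 16.2),
    (3, "BioMetAll"): (EvalTally(1013, 159, 57, 854), 15.7, 13.3),
    (3, "GASS"): (EvalTally(1206, 416, 106, 790), 34.5, 40.5),
    (3, "MoM"): (EvalTally(521, 467, 134, 54), 89.6, 43.5),
    (3, "M3D"): (EvalTally(455, 260, 26, 195), 57.1, 30.5),
    (5, "M1D"): (EvalTally(844, 129, 2, 715), 15.3, 15.4),
    (5, "BioMetAll"): (EvalTally(1687, 260, 116, 1427), 15.4, 17.5),
    (5, "GASS"): (EvalTally(1981, 626, 236, 1355), 31.6, 47.3),
    (5, "MoM"): (EvalTally(693, 609, 237, 84), 87.9, 45.1),
    (5, "M3D"): (EvalTally(503, 272, 27, 231), 54.1, 29.7),
    (10, "M1D"): (EvalTally(854, 129, 2, 725), 15.1, 15.2),
    (10, "BioMetAll"): (EvalTally(4030, 654, 381, 3376), 16.2, 32.7),
    (10, "GASS"): (EvalTally(3897, 1061, 576, 2836), 27.2, 58.0),
    (10, "MoM"): (EvalTally(868, 726, 331, 142), 83.6, 47.2),
    (10, "M3D"): (EvalTally(527, 279, 28, 248), 52.9, 30.0),
}

#: apo benchmark dataset shape: 412 structures holding 840 sites in 87 CLES
APO_N_STRUCTURES = 412
APO_N_SITES = 840
APO_N_CLES = 87

#: AlphaFold-model consensus benchmark: predictor -> (tp, fp, tn, fn,
#: printed recall %, printed precision %); recall denominator is the
#: 62 consensus sites.
CONSENSUS_BENCHMARK = {
    "GASS": (55, 24, 0, 0, 88.7, 69.6),
    "MoM": (52, 7, 12, 8, 83.8, 88.1),
    "M3D": (50, 4, 14, 13, 80.6, 92.5),
    "AF3": (42, 17, 8, 12, 67.7, 71.1),
}
CONSENSUS_TOTAL_SITES = 62

#: Venn partition of the 62 consensus sites: supporter count -> (sites,
#: printed integer percent).  Only the cells the study reports.
VENN_CELLS = {
    "all_four": (27, 44),
    "three_tools": (21, 34),
    "mom_gass_only": (8, 13),
}
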