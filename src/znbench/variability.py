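"""Apo-site side-chain variability within a CLES.

Without the metal, side chains of equivalent sites relax into different
local minima; donor atoms can move by several Å between crystal forms.
The spread is quantified without superposition: for every apo site the
n×n matrix of pairwise donor-proxy distances is computed, the N matrices
of a CLES are stacked into an N×n×n tensor, and mean/SD matrices are taken
elementwise along N (population SD).  Sites whose matrix deviates from the
mean by more than k·SD in at least two upper-triangle entries are flagged
as rearranged; flagged sites are then grouped into subclusters (the
candidate alternative minima) by single linkage on the Frobenius distance
between their full distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structures import ReferenceSite, Structure, StructureError, donor_proxy, format_key


@dataclass(eq=False)
class DistanceTensor:
    cles_id: str
    ligand_order: Tuple[str, ...]  # one label per ligand role, length n
    site_ids: Tuple[str, ...]  # length N, aligned with stack
    stack: np.ndarray  # (N, n, n)
    mean_mat: np.ndarray  # (n, n)
    sd_mat: np.ndarray  # (n, n)

    @property
    def n_sites(self) -> int:
        return self.stack.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.stack.shape[1]


@dataclass(eq=False)
class OutlierReport:
    site_id: str
    deviant_pairs: List[Tuple[int, int]]
    flagged: bool


def build_tensor(
    cles_sites: Sequence[Tuple[ReferenceSite, Structure]],
    cles_id: Optional[str] = None,
) -> DistanceTensor:
    """Stack donor-proxy distance matrices of a CLES's apo sites.

    Ligand correspondence across sites is positional: the i-th ligand key
    of every site refers to the same ligand role (the reference table's
    equivalence ordering).
    """
    if not cles_sites:
        raise StructureError("build_tensor needs at least one site")
    n = cles_sites[0][0].n
    if cles_id is None:
        cles_id = cles_sites[0][0].cles_id or "CLES"
    matrices = []
    site_ids = []
    for site, structure in cles_sites:
        if site.n != n:
            raise StructureError(
                f"site {site.site_id} has {site.n} ligands, expected {n}"
            )
        proxies = np.array(
            [donor_proxy(structure.residue(key)) for key in site.ligands]
        )
        diff = proxies[:, None, :] - proxies[None, :, :]
        matrices.append(np.sqrt((diff ** 2).sum(axis=-1)))
        site_ids.append(site.site_id)
    stack = np.stack(matrices)
    first = cles_sites[0][0]
    roles = tuple(
        f"{cles_sites[0][1].residues[key].res_name}-{format_key(key)}"
        for key in first.ligands
    )
    return DistanceTensor(
        cles_id=cles_id,
        ligand_order=roles,
        site_ids=tuple(site_ids),
        stack=stack,
        mean_mat=stack.mean(axis=0),
        sd_mat=stack.std(axis=0),  # population SD (ddof=0)
    )


def pair_spread(t: DistanceTensor) -> List[Dict]:
    """Per donor pair: the N distances plus median and quartiles.

    One series per upper-triangle pair (i<j), row-major — the data behind
    one violin each in the per-CLES spread plots.
    """
    out = []
    n = t.n_ligands
    for i in range(n):
        for j in range(i + 1, n):
            values = t.stack[:, i, j]
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            out.append(
                {
                    "pair": (i, j),
                    "label": f"{t.ligand_order[i]}|{t.ligand_order[j]}",
                    "values": values.copy(),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                }
            )
    return out


def pair_spread_frame(t: DistanceTensor) -> pd.DataFrame:
    """Long-format (cles_id, pair, site_id, distance) table for plotting."""
    rows = []
    for series in pair_spread(t):
        i, j = series["pair"]
        for site_id, value in zip(t.site_ids, series["values"]):
            rows.append(
                {
                    "cles_id": t.cles_id,
                    "pair": f"{i}-{j}",
                    "site_id": site_id,
                    "distance": float(value),
                }
            )
    return pd.DataFrame(rows, columns=["cles_id", "pair", "site_id", "distance"])


def flag_outliers(
    t: DistanceTensor,
    k_sd: float = 2.0,
    min_entries: int = 2,
) -> List[OutlierReport]:
    """Flag sites with >= ``min_entries`` upper-triangle deviations beyond k·SD.

    Deviation is two-sided (|d − mean| > k·SD): contracted sites count as
    much as expanded ones.  Pairs with zero SD are never deviant.
    """
    iu = np.triu_indices(t.n_ligands, k=1)
    reports = []
    for s, site_id in enumerate(t.site_ids):
        dev = np.abs(t.stack[s] - t.mean_mat) > k_sd * t.sd_mat
        dev &= t.sd_mat > 0
        pairs = [
            (int(i), int(j)) for i, j in zip(*iu) if dev[i, j]
        ]
        reports.append(
            OutlierReport(site_id=site_id, deviant_pairs=pairs, flagged=len(pairs) >= min_entries)
        )
    return reports


def cooccurrence_groups(
    reports: Sequence[OutlierReport],
    t: DistanceTensor,
    threshold: Optional[float] = None,
) -> List[List[str]]:
    """Group flagged sites into subclusters of similar rearrangement.

    Single linkage on the Frobenius distance between full distance
    matrices, cut at ``threshold``.  Default threshold: twice the median
    Frobenius distance among the non-flagged (well-behaved) sites, i.e.
    groups split when they differ clearly more than the background spread.
    """
    flagged_ids = [r.site_id for r in reports if r.flagged]
    if not flagged_ids:
        return []
    index = {sid: k for k, sid in enumerate(t.site_ids)}

    def frob(a: str, b: str) -> float:
        return float(np.linalg.norm(t.stack[index[a]] - t.stack[index[b]]))

    if threshold is None:
        calm = [r.site_id for r in reports if not r.flagged]
        background = [
            frob(a, b) for ai, a in enumerate(calm) for b in calm[ai + 1:]
        ]
        if not background:
            background = [
                frob(a, b)
                for ai, a in enumerate(flagged_ids)
                for b in flagged_ids[ai + 1:]
            ]
        threshold = 2.0 * float(np.median(background)) if background else 0.0

    if len(flagged_ids) == 1:
        return [[flagged_ids[0]]]

    dist = np.array(
        [
            frob(a, b)
            for ai, a in enumerate(flagged_ids)
            for b in flagged_ids[ai + 1:]
        ]
    )
    labels = fcluster(linkage(dist, method="single"), t=threshold, criterion="distance")
    groups: Dict[int, List[str]] = {}
    for sid, lab in zip(flagged_ids, labels):
        groups.setdefault(int(lab), []).append(sid)
    return [groups[lab] for lab in sorted(groups)]


def outlier_report_json(reports: Sequence[OutlierReport]) -> List[Dict]:
    return [
        {
            "site_id": r.site_id,
            "deviant_pairs": [list(p) for p in r.deviant_pairs],
            "flagged": r.flagged,
        }
        for r in reports
    ]
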