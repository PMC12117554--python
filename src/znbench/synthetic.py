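"""Synthetic zinc-site worlds with known ground truth.

Three generators, all deterministic in a root seed (per-structure
substreams keep outputs stable when a data set is resized):

* :func:`build_holo` / :func:`make_cles` — geometric CLESs: a mononuclear
  zinc site with 3 (trigonal) or 4 (tetrahedral) CHED ligands, donor
  atoms 2.1 Å from the metal, minimal residues (Cα, Cβ, donor proxy) plus
  decoy residues kept >= 6 Å from the metal.  Apo copies displace side
  chains with isotropic Gaussian noise, optional discrete subcluster
  displacement modes (alternative energy minima), and an optional rigid
  translation of the whole site.
* :func:`make_benchmark` — many structures with 1..k sites each, for
  exercising the evaluation pipeline end to end (files included).
* :func:`make_abstract_dataset` — sites as bare residue-key sets, no
  coordinates; the fast path for statistical parameter-recovery tests.

:func:`simulate_predictor` emits predictions with controllable detection
rate, partial-match rate, Poisson false-positive rate, duplication rate
and score informativeness (the probability that a true positive outranks
any given false positive — realised exactly by a two-branch score draw).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .predictions import Prediction, ScoreConvention, select_top
from .scoring import SiteCounts, classify, tally, unique_tp
from .structures import (
    CHED,
    DONOR_PROXY_ATOM,
    Cles,
    Residue,
    ReferenceSite,
    ResidueKey,
    Structure,
    StructureError,
    format_key,
)

_TETRAHEDRAL = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)
_TRIGONAL = np.array(
    [[1, 0, 0], [-0.5, math.sqrt(3) / 2, 0], [-0.5, -math.sqrt(3) / 2, 0]],
    dtype=float,
)


@dataclass(frozen=True)
class SiteTemplate:
    """Idealised mononuclear zinc site: n CHED ligands around the metal."""

    n_ligands: int = 4
    composition: Tuple[str, ...] = ("CYS", "CYS", "CYS", "CYS")
    metal_ligand_dist: float = 2.1  # Å, typical Zn-donor bond length
    geometry: str = "tetrahedral"

    def __post_init__(self) -> None:
        if self.n_ligands not in (3, 4):
            raise StructureError("templates support 3 (trigonal) or 4 (tetrahedral) ligands")
        if len(self.composition) != self.n_ligands:
            raise StructureError("composition length must equal n_ligands")
        if any(r not in CHED for r in self.composition):
            raise StructureError(f"composition must be CHED residues, got {self.composition}")
        if self.geometry not in ("tetrahedral", "trigonal"):
            raise StructureError(f"unknown geometry {self.geometry!r}")
        if (self.geometry == "tetrahedral") != (self.n_ligands == 4):
            raise StructureError("tetrahedral needs 4 ligands, trigonal needs 3")

    @property
    def directions(self) -> np.ndarray:
        return _TETRAHEDRAL if self.geometry == "tetrahedral" else _TRIGONAL


@dataclass(frozen=True)
class ApoNoiseModel:
    """Displacement model for metal-free side chains.

    ``sigma_iso`` is the isotropic Gaussian SD per donor proxy (Å);
    ``subcluster_modes`` are discrete (displacement-vector-set, weight)
    alternatives emulating distinct crystallisation minima;
    ``rigid_jitter`` translates whole structures (distance matrices are
    invariant to it by construction).
    """

    sigma_iso: float = 0.3
    subcluster_modes: Tuple[Tuple[np.ndarray, float], ...] = ()
    rigid_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_iso < 0 or self.rigid_jitter < 0:
            raise StructureError("noise magnitudes must be non-negative")
        if self.subcluster_modes:
            weights = [w for _, w in self.subcluster_modes]
            if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
                raise StructureError("subcluster mode weights must be >= 0 and sum to 1")


@dataclass(frozen=True)
class PredictorProfile:
    """Behavioural knobs of a simulated predictor."""

    predictor_id: str = "sim"
    p_detect: float = 0.8
    p_partial: float = 0.2
    fp_rate: float = 1.0  # Poisson mean of decoy predictions per structure
    dup_rate: float = 0.1
    score_informativeness: float = 0.9
    convention: Optional[ScoreConvention] = None
    emit_coordinates: bool = False
    coordinate_jitter: float = 0.3  # Å around the true metal position

    def __post_init__(self) -> None:
        for p in (self.p_detect, self.p_partial, self.dup_rate, self.score_informativeness):
            if not 0.0 <= p <= 1.0:
                raise StructureError("probabilities must lie in [0, 1]")
        if self.fp_rate < 0:
            raise StructureError("fp_rate must be non-negative")

    def get_convention(self) -> ScoreConvention:
        return self.convention or ScoreConvention(predictor_id=self.predictor_id)


@dataclass(eq=False)
class StructureSites:
    """One structure's ground truth: its sites plus a decoy residue pool."""

    struct_id: str
    sites: List[ReferenceSite]
    decoy_keys: Tuple[ResidueKey, ...]
    structure: Optional[Structure] = None


def _sub_rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *path])


# ---------------------------------------------------------------------------
# geometric generators


def _decoy_directions(count: int) -> np.ndarray:
    """Deterministic quasi-uniform directions (golden spiral)."""
    k = np.arange(count, dtype=float) + 0.5
    phi = math.pi * (1 + math.sqrt(5)) * k
    cos_t = 1 - 2 * k / count
    sin_t = np.sqrt(np.clip(1 - cos_t ** 2, 0, 1))
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def _site_residues(
    template: SiteTemplate,
    center: np.ndarray,
    chain: str,
    seq_start: int,
) -> List[Residue]:
    residues = []
    d = template.metal_ligand_dist
    for i, res_name in enumerate(template.composition):
        u = template.directions[i]
        atoms = {
            "CA": center + (d + 3.0) * u,
            "CB": center + (d + 1.5) * u,
            DONOR_PROXY_ATOM[res_name]: center + d * u,
        }
        residues.append(
            Residue(chain_id=chain, seq_num=seq_start + i, res_name=res_name, atoms=atoms)
        )
    return residues


def _decoy_residues(
    center: np.ndarray,
    chain: str,
    seq_start: int,
    count: int,
) -> List[Residue]:
    dirs = _decoy_directions(max(count, 1))
    residues = []
    for j in range(count):
        r = 8.0 + 0.7 * j  # always >= 6 Å from the metal
        u = dirs[j]
        atoms = {"CA": center + r * u, "CB": center + (r + 1.5) * u}
        residues.append(
            Residue(chain_id=chain, seq_num=seq_start + j, res_name="ALA", atoms=atoms)
        )
    return residues


def build_holo(
    template: SiteTemplate,
    struct_id: str = "holo",
    n_decoys: int = 6,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> Structure:
    """Idealised holo structure: metal + ligand residues + decoys."""
    center = np.asarray(center, dtype=float)
    structure = Structure(struct_id=struct_id)
    for res in _site_residues(template, center, "A", 1):
        structure.add_residue(res)
    for res in _decoy_residues(center, "A", 101, n_decoys):
        structure.add_residue(res)
    structure.metals.append(("Zn", center.copy()))
    return structure


def mode_assignment(
    noise: ApoNoiseModel, n_sites: int, seed: int
) -> List[Optional[int]]:
    """Replayable subcluster-mode draw for each apo copy (ground truth)."""
    out: List[Optional[int]] = []
    for s in range(n_sites):
        if not noise.subcluster_modes:
            out.append(None)
        else:
            rng = _sub_rng(seed, s, 7)
            weights = np.array([w for _, w in noise.subcluster_modes])
            out.append(int(rng.choice(len(weights), p=weights)))
    return out


def _apo_displacements(
    template: SiteTemplate,
    noise: ApoNoiseModel,
    mode_idx: Optional[int],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """(per-ligand side-chain displacements, rigid translation)."""
    disp = rng.normal(0.0, noise.sigma_iso, size=(template.n_ligands, 3))
    if mode_idx is not None:
        vectors = np.asarray(noise.subcluster_modes[mode_idx][0], dtype=float)
        if vectors.shape != (template.n_ligands, 3):
            raise StructureError(
                f"subcluster mode shape {vectors.shape} does not match "
                f"{template.n_ligands} ligands"
            )
        disp = disp + vectors
    shift = (
        rng.normal(0.0, noise.rigid_jitter, size=3)
        if noise.rigid_jitter > 0
        else np.zeros(3)
    )
    return disp, shift


def make_cles(
    template: SiteTemplate,
    n_sites: int,
    noise: ApoNoiseModel,
    seed: int,
    cles_id: str = "CLES-1",
    n_decoys: int = 6,
) -> Tuple[Cles, List[ReferenceSite], List[Structure]]:
    """Generate a CLES: n apo copies of one holo site, noise applied.

    Returns the CLES descriptor, one reference site per apo structure
    (ligand keys in the apo structure's own numbering, metal position in
    the apo frame), and the apo structures themselves.  Deterministic per
    seed; per-copy substreams.
    """
    if n_sites < 1:
        raise StructureError("a CLES needs at least one site")
    holo = build_holo(template, struct_id=f"{cles_id}-holo", n_decoys=n_decoys)
    modes = mode_assignment(noise, n_sites, seed)
    sites: List[ReferenceSite] = []
    structures: List[Structure] = []
    ligand_keys = [("A", 1 + i, "") for i in range(template.n_ligands)]

    for s in range(n_sites):
        rng = _sub_rng(seed, s)
        disp, shift = _apo_displacements(template, noise, modes[s], rng)
        struct_id = f"{cles_id}-apo-{s:03d}"
        apo = Structure(struct_id=struct_id)
        for key, res in holo.residues.items():
            atoms = {name: xyz + shift for name, xyz in res.atoms.items()}
            if key in set(ligand_keys):
                i = ligand_keys.index(key)
                for name in atoms:
                    if name != "CA":  # side chain moves, backbone stays
                        atoms[name] = atoms[name] + disp[i]
            apo.add_residue(
                Residue(
                    chain_id=res.chain_id,
                    seq_num=res.seq_num,
                    res_name=res.res_name,
                    atoms=atoms,
                    icode=res.icode,
                )
            )
        structures.append(apo)
        sites.append(
            ReferenceSite(
                site_id=f"{cles_id}-s{s:03d}",
                struct_id=struct_id,
                ligands=tuple(ligand_keys),
                metal_element="Zn",
                metal_pos=holo.metals[0][1] + shift,
                cles_id=cles_id,
            )
        )
    cles = Cles(
        cles_id=cles_id,
        site_ids=tuple(site.site_id for site in sites),
        ligand_composition=tuple(sorted(template.composition)),
    )
    return cles, sites, structures


DEFAULT_TEMPLATES = (
    SiteTemplate(4, ("CYS", "CYS", "CYS", "CYS"), geometry="tetrahedral"),
    SiteTemplate(3, ("CYS", "ASP", "HIS"), geometry="trigonal"),
    SiteTemplate(4, ("CYS", "CYS", "HIS", "HIS"), geometry="tetrahedral"),
    SiteTemplate(3, ("HIS", "HIS", "GLU"), geometry="trigonal"),
)


def make_benchmark(
    n_structures: int,
    seed: int,
    noise: Optional[ApoNoiseModel] = None,
    max_sites: int = 4,
    templates: Sequence[SiteTemplate] = DEFAULT_TEMPLATES,
    n_decoys: int = 6,
) -> Tuple[List[StructureSites], List[Cles]]:
    """A benchmark world: structures with 1..max_sites sites, CLES-labelled.

    Site multiplicity follows a truncated geometric distribution (about
    40% single-site, mean near 2 — the regime a mixed apo data set shows).
    Each (template, slot) pair forms one CLES across the data set.
    """
    noise = noise or ApoNoiseModel()
    rng = _sub_rng(seed, 999)
    out: List[StructureSites] = []
    cles_members: Dict[str, List[str]] = {}
    cles_comp: Dict[str, SiteTemplate] = {}
    for s in range(n_structures):
        k = 1 + min(rng.geometric(0.5) - 1, max_sites - 1)
        struct_id = f"bench-{s:04d}"
        structure = Structure(struct_id=struct_id)
        sites: List[ReferenceSite] = []
        for j in range(k):
            template = templates[(s + j) % len(templates)]
            cles_id = f"CLES-T{(s + j) % len(templates)}-slot{j}"
            center = np.array([40.0 * j, 0.0, 0.0])
            site_rng = _sub_rng(seed, s, j)
            modes = mode_assignment(noise, 1, int(site_rng.integers(2 ** 20)))
            disp, shift = _apo_displacements(template, noise, modes[0], site_rng)
            seq_start = 1 + 10 * j
            ligand_keys = []
            for i, res in enumerate(_site_residues(template, center, "A", seq_start)):
                atoms = dict(res.atoms)
                for name in atoms:
                    if name != "CA":
                        atoms[name] = atoms[name] + disp[i]
                for name in atoms:
                    atoms[name] = atoms[name] + shift
                structure.add_residue(
                    Residue(res.chain_id, res.seq_num, res.res_name, atoms)
                )
                ligand_keys.append((res.chain_id, res.seq_num, ""))
            site_id = f"{struct_id}-site{j}"
            sites.append(
                ReferenceSite(
                    site_id=site_id,
                    struct_id=struct_id,
                    ligands=tuple(ligand_keys),
                    metal_pos=center + shift,
                    cles_id=cles_id,
                )
            )
            cles_members.setdefault(cles_id, []).append(site_id)
            cles_comp[cles_id] = template
            for res in _decoy_residues(center, "A", 1001 + 100 * j, n_decoys):
                structure.add_residue(res)
        decoys = tuple(
            key
            for key in structure.residues
            if key not in {k for site in sites for k in site.ligands}
        )
        out.append(StructureSites(struct_id, sites, decoys, structure))
    cles_list = [
        Cles(
            cles_id=cid,
            site_ids=tuple(members),
            ligand_composition=tuple(sorted(cles_comp[cid].composition)),
        )
        for cid, members in sorted(cles_members.items())
    ]
    return out, cles_list


def make_abstract_dataset(
    n_structures: int,
    seed: int,
    sites_per_structure: int = 1,
    n_ligands: int = 4,
    n_decoys: int = 8,
) -> List[StructureSites]:
    """Coordinate-free ground truth for fast statistical tests."""
    out = []
    for s in range(n_structures):
        struct_id = f"abs-{s:05d}"
        sites = []
        used = 0
        for j in range(sites_per_structure):
            keys = tuple(("A", used + i + 1, "") for i in range(n_ligands))
            used += n_ligands
            sites.append(
                ReferenceSite(
                    site_id=f"{struct_id}-site{j}",
                    struct_id=struct_id,
                    ligands=keys,
                    cles_id=f"absCLES-{j}",
                )
            )
        decoys = tuple(("D", i + 1, "") for i in range(n_decoys))
        out.append(StructureSites(struct_id, sites, decoys))
    return out


# ---------------------------------------------------------------------------
# predictor simulation


def _tp_residues(
    site: ReferenceSite, profile: PredictorProfile, rng: np.random.Generator
) -> frozenset:
    keys = list(site.ligands)
    if len(keys) > 1 and rng.random() < profile.p_partial:
        keys.pop(int(rng.integers(len(keys))))
    return frozenset(keys)


def simulate_predictor(
    dataset: Sequence[StructureSites],
    profile: PredictorProfile,
    seed: int,
) -> List[Prediction]:
    """Emit ranked predictions per structure with the profile's error modes.

    Scores (higher-better): a TP draws 1+U with probability
    ``score_informativeness`` (outranks every FP) and U−1 otherwise
    (outranked by every FP), FPs draw U in (0,1) — so a TP beats any given
    FP with exactly the requested probability.
    """
    predictions: List[Prediction] = []
    for s_idx, ss in enumerate(dataset):
        rng = _sub_rng(seed, s_idx, 101)
        entries: List[Tuple[dict, bool]] = []  # (payload kwargs, is_tp)

        def tp_payload(site: ReferenceSite) -> dict:
            if profile.emit_coordinates:
                if site.metal_pos is None:
                    raise StructureError(
                        f"site {site.site_id} has no metal position for "
                        "coordinate emission"
                    )
                jitter = rng.normal(0.0, profile.coordinate_jitter, size=3)
                return {"coordinate": site.metal_pos + jitter}
            return {"residues": _tp_residues(site, profile, rng)}

        for site in ss.sites:
            if rng.random() < profile.p_detect:
                entries.append((tp_payload(site), True))
                if rng.random() < profile.dup_rate:
                    entries.append((tp_payload(site), True))
        for _ in range(int(rng.poisson(profile.fp_rate))):
            if len(ss.decoy_keys) < 3:
                continue
            if profile.emit_coordinates and ss.structure is not None:
                key = ss.decoy_keys[int(rng.integers(len(ss.decoy_keys)))]
                entries.append(
                    ({"coordinate": ss.structure.residues[key].atoms["CA"].copy()}, False)
                )
            else:
                picks = rng.choice(len(ss.decoy_keys), size=3, replace=False)
                entries.append(
                    ({"residues": frozenset(ss.decoy_keys[i] for i in sorted(picks))}, False)
                )

        scored = []
        for payload, is_tp in entries:
            u = float(rng.random())
            if is_tp:
                score = 1.0 + u if rng.random() < profile.score_informativeness else u - 1.0
            else:
                score = u
            scored.append((score, payload))
        scored.sort(key=lambda t: -t[0])
        for rank, (score, payload) in enumerate(scored, start=1):
            predictions.append(
                Prediction(
                    predictor_id=profile.predictor_id,
                    struct_id=ss.struct_id,
                    rank=rank,
                    score=score,
                    **payload,
                )
            )
    return predictions


def recover_parameters(
    dataset: Sequence[StructureSites],
    profile: PredictorProfile,
    preds: Optional[Sequence[Prediction]] = None,
    seed: int = 0,
    m: int = 10,
    k_se: float = 3.0,
) -> Dict:
    """Compare measured precision/recall with the profile's analytic values.

    Expected recall is ``p_detect`` (a one-ligand partial drop still
    satisfies the n−1 rule, so ``p_partial`` does not reduce it).
    Expected precision is the ratio of expected correct outputs,
    ``p_detect * (1 + dup_rate)`` per site, to expected total outputs
    (adding ``fp_rate`` per structure).  Deviations beyond ``k_se``
    standard errors are flagged.
    """
    if not dataset:
        return {}
    if preds is None:
        preds = simulate_predictor(dataset, profile, seed)
    conv = profile.get_convention()
    by_struct: Dict[str, List[Prediction]] = {}
    for p in preds:
        by_struct.setdefault(p.struct_id, []).append(p)

    all_sites = [site for ss in dataset for site in ss.sites]
    counts = SiteCounts.from_sites(all_sites)
    records = []
    for ss in dataset:
        top = select_top(by_struct.get(ss.struct_id, []), conv, m)
        records.extend(classify(top, ss.sites))
    t = tally(records)
    utp = unique_tp(records)
    n_sites = counts.total_sites
    measured_recall = utp / n_sites
    measured_precision = (t.n_tp / t.n_outputs) if t.n_outputs else float("nan")

    etp_per_site = profile.p_detect * (1.0 + profile.dup_rate)
    e_outputs = etp_per_site * n_sites + profile.fp_rate * len(dataset)
    expected_precision = (etp_per_site * n_sites) / e_outputs if e_outputs else float("nan")
    se_recall = math.sqrt(profile.p_detect * (1 - profile.p_detect) / n_sites)
    se_precision = (
        math.sqrt(expected_precision * (1 - expected_precision) / e_outputs)
        if e_outputs
        else float("nan")
    )
    flags = []
    if se_recall and abs(measured_recall - profile.p_detect) > k_se * se_recall:
        flags.append("recall")
    if se_precision and abs(measured_precision - expected_precision) > k_se * se_precision:
        flags.append("precision")
    return {
        "measured": {"recall": measured_recall, "precision": measured_precision},
        "expected": {"recall": profile.p_detect, "precision": expected_precision},
        "se": {"recall": se_recall, "precision": se_precision},
        "tally": t,
        "unique_tp": utp,
        "n_sites": n_sites,
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# PDB output


def write_pdb(structure: Structure, path) -> None:
    """Write a minimal standard PDB file (ATOM/HETATM/END)."""
    lines = []
    serial = 1
    for res in structure.residues.values():
        for name, xyz in res.atoms.items():
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            element = name.strip().lstrip("0123456789")[:1]
            bfac = res.confidence if res.confidence is not None else 0.0
            lines.append(
                f"ATOM  {serial:5d} {pad_name:<4s}{'':1s}{res.res_name:>3s} "
                f"{res.chain_id:1s}{res.seq_num:4d}{res.icode or '':1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{bfac:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    for element, xyz in structure.metals:
        symbol = element.upper()
        lines.append(
            f"HETATM{serial:5d} {symbol:<4s}{'':1s}{symbol:>3s} "
            f"M{serial % 10000:4d}{'':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {symbol:>2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset(
    dataset: Sequence[StructureSites],
    out_dir,
) -> Tuple[Path, Path]:
    """Write PDB files + reference-site CSV; returns (structures dir, table path)."""
    from .structures import save_reference_table

    out_dir = Path(out_dir)
    structures_dir = out_dir / "structures"
    structures_dir.mkdir(parents=True, exist_ok=True)
    sites = []
    for ss in dataset:
        if ss.structure is None:
            raise StructureError(f"{ss.struct_id} has no coordinates to write")
        write_pdb(ss.structure, structures_dir / f"{ss.struct_id}.pdb")
        sites.extend(ss.sites)
    table_path = out_dir / "reference_sites.csv"
    save_reference_table(sites, table_path)
    return structures_dir, table_path
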