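"""Protein coordinates and reference zinc-site geometry.

A reference metal-binding site (MBS) is described the way metal-site
databases describe it: the *ligands* are the residues with at least one
non-hydrogen atom within 3.0 Å of the metal, and the site's environment
(*shell*) is every residue with at least one atom within 5.0 Å of a
ligand atom.  Equivalent mononuclear zinc sites observed across several
structures of the same protein are grouped into a CLES (cluster of
equivalent sites); site-to-site ligand correspondence inside a CLES is
taken from the reference table's ligand ordering, never recomputed.

Only the CHED residues (Cys, His, Glu, Asp) coordinate zinc in the data
this package targets.  For apo-state geometry each CHED residue is
summarised by a fixed side-chain *donor proxy* atom: Asp Cγ, Cys Sγ,
Glu Cδ, His Cε1.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from scipy.spatial import cKDTree

#: residue identity within one structure: (chain_id, seq_num, icode)
ResidueKey = Tuple[str, int, str]

LIGAND_CUTOFF = 3.0  # Å, metal -> ligand residue (inclusive)
SHELL_CUTOFF = 5.0  # Å, ligand atom -> shell residue (inclusive)

#: side-chain donor (or donor proxy) atom per CHED residue type
DONOR_PROXY_ATOM = {"ASP": "CG", "CYS": "SG", "GLU": "CD", "HIS": "CE1"}
CHED = tuple(DONOR_PROXY_ATOM)

_METAL_ELEMENTS = {
    "ZN", "FE", "CU", "MN", "NI", "CO", "MG", "CA", "NA", "K",
    "CD", "HG", "LI", "AG", "AU", "PT", "PB", "MO", "W", "V", "CR",
}


class StructureError(ValueError):
    """Domain error raised by structure/site operations."""


class ParseError(StructureError):
    """Raised when PDB content cannot be interpreted."""


def is_hydrogen(atom_name: str) -> bool:
    """Name-based hydrogen/deuterium test (element column may be absent)."""
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() in ("H", "D")


def format_key(key: ResidueKey) -> str:
    chain, seq, icode = key
    return f"{chain}:{seq}:{icode}" if icode else f"{chain}:{seq}"


def parse_key(text: str) -> ResidueKey:
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise StructureError(f"malformed residue key {text!r}")
    icode = parts[2] if len(parts) == 3 else ""
    return (parts[0], int(parts[1]), icode)


@dataclass(eq=False)
class Residue:
    chain_id: str
    seq_num: int
    res_name: str
    atoms: Dict[str, np.ndarray]
    icode: str = ""
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.res_name:
            raise StructureError("res_name must be non-empty")
        self.atoms = {name: np.asarray(xyz, dtype=float) for name, xyz in self.atoms.items()}
        for name, xyz in self.atoms.items():
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise StructureError(
                    f"non-finite or malformed coordinate for atom {name} of "
                    f"{self.res_name} {format_key(self.key)}"
                )

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def heavy_atoms(self) -> Iterator[Tuple[str, np.ndarray]]:
        for name, xyz in self.atoms.items():
            if not is_hydrogen(name):
                yield name, xyz


@dataclass(eq=False)
class Structure:
    struct_id: str
    residues: Dict[ResidueKey, Residue] = field(default_factory=dict)
    metals: List[Tuple[str, np.ndarray]] = field(default_factory=list)

    def add_residue(self, residue: Residue) -> None:
        if residue.key in self.residues:
            raise ParseError(
                f"duplicate residue {format_key(residue.key)} in {self.struct_id}"
            )
        self.residues[residue.key] = residue

    def residue(self, key: ResidueKey) -> Residue:
        try:
            return self.residues[key]
        except KeyError:
            raise StructureError(
                f"residue {format_key(key)} not in structure {self.struct_id}"
            ) from None


@dataclass(eq=False)
class ReferenceSite:
    """One mononuclear zinc site.

    ``ligands`` is an ordered tuple of residue keys: the order encodes the
    ligand correspondence across equivalent sites of the same CLES and is
    preserved from the reference table.  Matching logic only ever uses the
    set of keys.
    """

    site_id: str
    struct_id: str
    ligands: Tuple[ResidueKey, ...]
    metal_element: str = "Zn"
    metal_pos: Optional[np.ndarray] = None
    shell: frozenset = frozenset()
    cles_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.ligands = tuple(self.ligands)
        if len(self.ligands) < 1:
            raise StructureError(f"site {self.site_id} has no ligands")
        if self.metal_pos is not None:
            self.metal_pos = np.asarray(self.metal_pos, dtype=float)
        self.shell = frozenset(self.shell) | frozenset(self.ligands)

    @property
    def n(self) -> int:
        return len(self.ligands)

    @property
    def ligand_set(self) -> frozenset:
        return frozenset(self.ligands)


@dataclass(eq=False)
class Cles:
    """Cluster of equivalent mononuclear zinc sites (same site, many structures)."""

    cles_id: str
    site_ids: Tuple[str, ...]
    ligand_composition: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.site_ids) < 1:
            raise StructureError(f"CLES {self.cles_id} is empty")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)


# ---------------------------------------------------------------------------
# parsing


def parse_structure(
    text: str,
    struct_id: str = "structure",
    bfactor_is_plddt: bool = False,
) -> Structure:
    """Parse PDB-format content into a :class:`Structure`.

    HETATM records holding a lone metal ion are routed to ``Structure.metals``.
    When ``bfactor_is_plddt`` is set, the per-residue mean B-factor is stored
    as the residue's confidence (AlphaFold convention).  Altloc conformers
    collapse to the highest-occupancy one (ties broken by altloc letter).
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio_structure = parser.get_structure(struct_id, io.StringIO(text))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"cannot parse PDB content: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise ParseError("empty structure: no models")
    structure = Structure(struct_id=struct_id)

    for chain in models[0]:
        for bio_res in chain:
            if bio_res.is_disordered() == 2:  # point-mutation DisorderedResidue
                bio_res = bio_res.disordered_get_list()[0]
            hetfield, seq_num, icode = bio_res.id
            atoms: Dict[str, np.ndarray] = {}
            elements: Dict[str, str] = {}
            bfactors: List[float] = []
            for atom in bio_res:
                if atom.is_disordered():
                    children = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )
                    atom = children[0]
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
                elements[atom.get_name()] = (atom.element or "").upper()
                bfactors.append(float(atom.get_bfactor() or 0.0))

            heavy = [n for n in atoms if elements.get(n) not in ("H", "D")]
            if (
                hetfield.startswith("H_")
                and len(heavy) == 1
                and elements.get(heavy[0]) in _METAL_ELEMENTS
            ):
                structure.metals.append(
                    (elements[heavy[0]].capitalize(), atoms[heavy[0]])
                )
                continue

            confidence = float(np.mean(bfactors)) if (bfactor_is_plddt and bfactors) else None
            structure.add_residue(
                Residue(
                    chain_id=chain.id,
                    seq_num=seq_num,
                    icode=icode.strip(),
                    res_name=bio_res.get_resname().strip(),
                    atoms=atoms,
                    confidence=confidence,
                )
            )

    if not structure.residues and not structure.metals:
        raise ParseError("empty structure: no ATOM/HETATM records")
    return structure


# ---------------------------------------------------------------------------
# site geometry


def find_ligands(
    structure: Structure,
    metal_pos: Sequence[float],
    cutoff: float = LIGAND_CUTOFF,
) -> set:
    """Residues with >=1 non-hydrogen atom within ``cutoff`` Å of the metal."""
    metal_pos = np.asarray(metal_pos, dtype=float)
    if metal_pos.shape != (3,) or not np.all(np.isfinite(metal_pos)):
        raise StructureError("metal position must be a finite 3D coordinate")
    found = set()
    for key, res in structure.residues.items():
        for _, xyz in res.heavy_atoms():
            if float(np.linalg.norm(xyz - metal_pos)) <= cutoff:
                found.add(key)
                break
    return found


def build_reference_site(
    structure: Structure,
    metal: Tuple[str, Sequence[float]],
    site_id: Optional[str] = None,
    cles_id: Optional[str] = None,
    ligand_cutoff: float = LIGAND_CUTOFF,
    shell_cutoff: float = SHELL_CUTOFF,
) -> ReferenceSite:
    """Build a reference site around one metal: 3.0 Å ligands, 5.0 Å shell."""
    element, pos = metal
    pos = np.asarray(pos, dtype=float)
    ligand_keys = find_ligands(structure, pos, cutoff=ligand_cutoff)
    if not ligand_keys:
        raise StructureError(
            f"isolated metal {element} in {structure.struct_id}: "
            f"no residue within {ligand_cutoff} Å"
        )
    # tuple ordered by structure residue order for determinism
    ligands = tuple(k for k in structure.residues if k in ligand_keys)

    ligand_coords = np.array(
        [xyz for k in ligands for _, xyz in structure.residues[k].heavy_atoms()]
    )
    tree = cKDTree(ligand_coords)
    shell = set()
    for key, res in structure.residues.items():
        coords = np.array([xyz for _, xyz in res.heavy_atoms()])
        if coords.size and np.any(tree.query(coords, k=1)[0] <= shell_cutoff):
            shell.add(key)
    shell |= set(ligands)

    if site_id is None:
        site_id = f"{structure.struct_id}:{element}"
    return ReferenceSite(
        site_id=site_id,
        struct_id=structure.struct_id,
        ligands=ligands,
        metal_element=element,
        metal_pos=pos,
        shell=frozenset(shell),
        cles_id=cles_id,
    )


def donor_proxy(residue: Residue) -> np.ndarray:
    """Coordinate of the fixed donor-proxy atom of a CHED residue."""
    name = residue.res_name.upper()
    if name not in DONOR_PROXY_ATOM:
        raise StructureError(
            f"unsupported residue {name} at {format_key(residue.key)}: "
            f"donor proxies are defined for {'/'.join(CHED)} only"
        )
    atom = DONOR_PROXY_ATOM[name]
    if atom not in residue.atoms:
        raise StructureError(
            f"missing atom {atom} on {name} {format_key(residue.key)}"
        )
    return residue.atoms[atom]


def confidence_pass(
    structure: Structure,
    frac: float = 0.90,
    thr: Optional[float] = None,
) -> bool:
    """True iff >= ``frac`` of residues have confidence strictly above ``thr``.

    pLDDT scale is auto-detected when ``thr`` is None: if every value is
    <= 1.0 the 0-1 convention applies (threshold 0.7), otherwise the 0-100
    convention (threshold 70).
    """
    confs = []
    for key, res in structure.residues.items():
        if res.confidence is None:
            raise StructureError(
                f"residue {format_key(key)} of {structure.struct_id} "
                "has no confidence value"
            )
        confs.append(res.confidence)
    if not confs:
        raise StructureError(f"structure {structure.struct_id} has no residues")
    if thr is None:
        thr = 0.7 if max(confs) <= 1.0 else 70.0
    n_pass = sum(1 for c in confs if c > thr)
    return n_pass / len(confs) >= frac


# ---------------------------------------------------------------------------
# reference-table I/O

_TABLE_COLUMNS = [
    "site_id", "struct_id", "metal_element",
    "metal_x", "metal_y", "metal_z", "ligands", "composition", "cles_id",
]


def save_reference_table(sites: Iterable[ReferenceSite], path) -> None:
    rows = []
    for site in sites:
        pos = site.metal_pos
        rows.append(
            {
                "site_id": site.site_id,
                "struct_id": site.struct_id,
                "metal_element": site.metal_element,
                "metal_x": None if pos is None else float(pos[0]),
                "metal_y": None if pos is None else float(pos[1]),
                "metal_z": None if pos is None else float(pos[2]),
                "ligands": ";".join(format_key(k) for k in site.ligands),
                "composition": "",
                "cles_id": site.cles_id or "",
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def load_reference_table(path) -> List[ReferenceSite]:
    df = pd.read_csv(path, dtype={"cles_id": str, "composition": str})
    sites = []
    for row in df.itertuples(index=False):
        pos = None
        if pd.notna(getattr(row, "metal_x", None)):
            pos = np.array([row.metal_x, row.metal_y, row.metal_z], dtype=float)
        cles = getattr(row, "cles_id", "") or ""
        sites.append(
            ReferenceSite(
                site_id=str(row.site_id),
                struct_id=str(row.struct_id),
                ligands=tuple(parse_key(t) for t in str(row.ligands).split(";")),
                metal_element=str(row.metal_element),
                metal_pos=pos,
                cles_id=str(cles) if (cles and not pd.isna(cles)) else None,
            )
        )
    return sites


def group_cles(sites: Sequence[ReferenceSite]) -> List[Cles]:
    """Group sites into CLES objects by their cles_id (unlabelled sites skipped)."""
    by_cles: Dict[str, List[ReferenceSite]] = {}
    for site in sites:
        if site.cles_id is not None:
            by_cles.setdefault(site.cles_id, []).append(site)
    out = []
    for cles_id in sorted(by_cles):
        members = by_cles[cles_id]
        ns = {s.n for s in members}
        if len(ns) > 1:
            raise StructureError(
                f"CLES {cles_id} mixes ligand counts {sorted(ns)}"
            )
        out.append(Cles(cles_id=cles_id, site_ids=tuple(s.site_id for s in members)))
    return out


def sites_to_json(sites: Iterable[ReferenceSite], path) -> None:
    payload = []
    for site in sites:
        payload.append(
            {
                "site_id": site.site_id,
                "struct_id": site.struct_id,
                "metal_element": site.metal_element,
                "metal_pos": None if site.metal_pos is None else [float(v) for v in site.metal_pos],
                "ligands": [format_key(k) for k in site.ligands],
                "shell": sorted(format_key(k) for k in site.shell),
                "cles_id": site.cles_id,
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
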