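import numpy as np
import pytest

from znbench.structures import Residue, Structure, is_hydrogen

ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.155  -4.933  1.00  0.00           C
ATOM      4  O   ALA A   1      13.339   7.191  -3.889  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.541   6.214  -4.092  1.00  0.00           C
END
"""

ZN_CYS4_PDB = """\
ATOM      1  CA  CYS A   1       5.100   0.000   0.000  1.00  0.00           C
ATOM      2  CB  CYS A   1       3.600   0.000   0.000  1.00  0.00           C
ATOM      3  SG  CYS A   1       2.300   0.000   0.000  1.00  0.00           S
ATOM      4  CA  CYS A   2       0.000   5.100   0.000  1.00  0.00           C
ATOM      5  CB  CYS A   2       0.000   3.600   0.000  1.00  0.00           C
ATOM      6  SG  CYS A   2       0.000   2.300   0.000  1.00  0.00           S
ATOM      7  CA  CYS A   3       0.000   0.000   5.100  1.00  0.00           C
ATOM      8  CB  CYS A   3       0.000   0.000   3.600  1.00  0.00           C
ATOM      9  SG  CYS A   3       0.000   0.000   2.300  1.00  0.00           S
ATOM     10  CA  CYS A   4      -5.100   0.000   0.000  1.00  0.00           C
ATOM     11  CB  CYS A   4      -3.600   0.000   0.000  1.00  0.00           C
ATOM     12  SG  CYS A   4      -2.300   0.000   0.000  1.00  0.00           S
HETATM   13 ZN    ZN M   1       0.000   0.000   0.000  1.00  0.00          ZN
END
"""


@pytest.fixture
def zn_cys4_structure():
    from znbench.structures import parse_structure

    return parse_structure(ZN_CYS4_PDB, "zn_cys4")


def random_structure(seed: int, n_residues: int = 20, box: float = 12.0) -> Structure:
    """Random toy structure with occasional hydrogens, for distance oracles."""
    rng = np.random.default_rng(seed)
    structure = Structure(struct_id=f"rand-{seed}")
    names = ["N", "CA", "C", "O", "CB", "SG", "HB2"]
    res_names = ["ALA", "CYS", "HIS", "GLY", "SER"]
    for i in range(n_residues):
        n_atoms = int(rng.integers(2, len(names) + 1))
        atoms = {
            name: rng.uniform(-box, box, 3)
            for name in rng.permutation(names)[:n_atoms]
        }
        structure.add_residue(
            Residue(
                chain_id="A",
                seq_num=i + 1,
                res_name=str(rng.choice(res_names)),
                atoms=atoms,
            )
        )
    return structure


def brute_force_within(structure: Structure, point, cutoff: float) -> set:
    """Exhaustive all-pairs oracle: residues with a heavy atom <= cutoff of point."""
    point = np.asarray(point, float)
    hits = set()
    for key, res in structure.residues.items():
        for name, xyz in res.atoms.items():
            if is_hydrogen(name):
                continue
            if float(np.sqrt(((xyz - point) ** 2).sum())) <= cutoff:
                hits.add(key)
                break
    return hits
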