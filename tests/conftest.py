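import numpy as np
import pytest

from polyqppi.structure import Atom, ComplexStructure, Residue, assign_vdw_radii

GLY_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      12.429   7.227  -4.655  1.00  0.00           C
ATOM      4  O   GLY A   1      13.452   7.110  -3.966  1.00  0.00           O
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
TER
ATOM      3  CA  GLY B   1       0.000  20.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def gly_pdb(tmp_path):
    path = tmp_path / "gly.pdb"
    path.write_text(GLY_PDB)
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    path = tmp_path / "two_chain.pdb"
    path.write_text(TWO_CHAIN_PDB)
    return path


def make_structure(chain_atoms, res_names=None):
    """Build a structure from {chain_id: [(res_num, atom_name, element, xyz), ...]}.

    ``res_names`` optionally maps (chain_id, res_num) -> residue name
    (default GLY).  Radii are assigned from the default table.
    """
    chains = []
    serial = 0
    for chain_id, atom_specs in chain_atoms.items():
        residues = {}
        for res_num, atom_name, element, xyz in atom_specs:
            serial += 1
            res = residues.setdefault(
                res_num,
                Residue(
                    chain_id=chain_id,
                    number=res_num,
                    icode="",
                    res_name=(res_names or {}).get((chain_id, res_num), "GLY"),
                ),
            )
            res.atoms.append(
                Atom(
                    serial=serial,
                    name=atom_name,
                    element=element,
                    coords=np.asarray(xyz, dtype=float),
                    vdw_radius=None,
                    residue_key=(chain_id, res_num, ""),
                )
            )
        chains.append((chain_id, [residues[k] for k in sorted(residues)]))
    return assign_vdw_radii(ComplexStructure(chains=chains))
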