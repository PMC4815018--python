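"""Shared fixtures: idealised peptides, decoy structures, tiny PDB texts."""

import numpy as np
import pytest

from psychrodyn import build_peptide
from psychrodyn.structure import Structure


@pytest.fixture(scope="session")
def helix12():
    return build_peptide(12, "helix")


@pytest.fixture(scope="session")
def extended12():
    return build_peptide(12, "extended")


def make_structure(atom_rows, source_id="test"):
    """Build a Structure from (name, element, chain, resnum, resname, xyz) rows."""
    return Structure(
        serial=np.arange(1, len(atom_rows) + 1),
        name=np.array([r[0] for r in atom_rows]),
        element=np.array([r[1] for r in atom_rows]),
        chain_id=np.array([r[2] for r in atom_rows]),
        res_num=np.array([r[3] for r in atom_rows]),
        icode=np.array([""] * len(atom_rows)),
        res_name=np.array([r[4] for r in atom_rows]),
        coords=np.array([r[5] for r in atom_rows], dtype=float),
        source_id=source_id,
    )


def scattered_decoy(n_residues=50, seed=0, box=14.0):
    """Compact decoy: residues with charged/non-polar probes scattered in a box.

    Each residue keeps ideal internal geometry but is rigidly translated to a
    random point, producing many near-contacts for oracle comparisons.
    """
    rng = np.random.default_rng(seed)
    choices = ["LYS", "ARG", "GLU", "ASP", "LEU", "ALA", "SER"]
    subs = {
        i + 1: rng.choice(choices)
        for i in range(n_residues)
        if rng.random() < 0.8
    }
    pep = build_peptide(n_residues, "extended", substitutions=subs)
    coords = pep.coords.copy()
    for r in range(pep.n_residues):
        idx = pep.residue_atom_indices(r)
        centre = coords[idx].mean(axis=0)
        target = rng.uniform(0.0, box, size=3)
        coords[idx] += target - centre
    return pep.with_coords(coords)


MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1      11.104   6.134   1.711  1.00  0.00"
    "           C\n"
    "END\n"
)


def multi_model_pdb(n_models=3, drop_last_atom_in_model=None):
    """Handwritten multi-model PDB of a 2-atom peptide fragment."""
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        atoms = [
            ("N", "N", 0.0 + m, 0.0, 0.0),
            ("CA", "C", 1.458 + m, 0.0, 0.0),
        ]
        if drop_last_atom_in_model == m:
            atoms = atoms[:-1]
        for i, (name, elem, x, y, z) in enumerate(atoms, 1):
            lines.append(
                f"ATOM  {i:5d} {name:^4s}ALA A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
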