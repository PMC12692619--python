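"""Shared fixtures: small FASTA files and synthetic structure models.

All fixture data is generated programmatically; nothing binary is stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from allermap.seqio import ProteinRecord
from allermap.structure import Residue, StructureModel


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">a first\nMKV\n>b second\nPEPTIDE\n")
    return path


@pytest.fixture
def record_50mer():
    rng = np.random.default_rng(1234)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    seq = "".join(rng.choice(list(aas), size=50))
    return ProteinRecord("rand50", seq)


def extended_chain_pdb(n_res: int = 10, bfactor: float = 90.0,
                       spacing: float = 3.8) -> str:
    """CA-only poly-glycine extended chain as PDB text."""
    lines = []
    for i in range(n_res):
        x = i * spacing
        lines.append(
            f"ATOM  {i + 1:>5}  CA  GLY A{i + 1:>4}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{bfactor:6.2f}"
            f"           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def chain_pdb_file(tmp_path):
    path = tmp_path / "chain.pdb"
    path.write_text(extended_chain_pdb())
    return path


def single_atom_model(element: str = "C", bfactor: float = 50.0,
                      ) -> StructureModel:
    return StructureModel(
        chain_id="A",
        residues=(
            Residue(1, "G", (element,), np.zeros((1, 3)),
                    np.array([bfactor])),
        ),
    )


def ca_chain_model(coords: np.ndarray, bfactors=None,
                   name: str = "G") -> StructureModel:
    coords = np.asarray(coords, dtype=float)
    if bfactors is None:
        bfactors = np.full(len(coords), 90.0)
    residues = tuple(
        Residue(i + 1, name, ("C",), coords[i : i + 1],
                np.array([float(bfactors[i])]))
        for i in range(len(coords))
    )
    return StructureModel(chain_id="A", residues=residues)
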