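"""Shared fixtures: tiny alignments and programmatically built structures."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from selexp.msa_numbering import Alignment, SequenceRecord
from selexp.structure_annotation import Atom, StructureModel


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment(tuple(SequenceRecord(k, v) for k, v in rows.items()))


@pytest.fixture
def tiny_alignment() -> Alignment:
    return make_alignment({"seq1": "ACD-", "seq2": "ACDE"})


def pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resseq: int,
    x: float, y: float, z: float, element: str, hetatm: bool = False,
    occupancy: float = 1.0, altloc: str = " ",
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4s}{altloc}{resname:<3s} {chain}"
        f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00"
        f"          {element:>2s}"
    )


def write_pdb(path, lines: list[str]) -> None:
    path.write_text("\n".join(lines + ["END"]) + "\n")


def toy_receptor_ligand_model() -> StructureModel:
    """Three single-atom receptor residues at 3.9 / 4.1 / 100 Å from a ligand atom."""
    atoms = (
        Atom("A", 1, "", "ALA", "CA", "C", (3.9, 0.0, 0.0)),
        Atom("A", 2, "", "GLY", "CA", "C", (0.0, 4.1, 0.0)),
        Atom("A", 3, "", "SER", "CA", "C", (100.0, 0.0, 0.0)),
        Atom("A", 100, "", "LIG", "C1", "C", (0.0, 0.0, 0.0)),
    )
    return StructureModel(atoms, frozenset({"LIG"}))


@pytest.fixture
def toy_model() -> StructureModel:
    return toy_receptor_ligand_model()


def grid_points_model(n: int = 4) -> StructureModel:
    """n single-CA residues at distinct grid points (for superposition tests)."""
    rng = np.random.default_rng(42)
    xyz = rng.normal(0, 5, size=(n, 3))
    atoms = tuple(
        Atom("A", i + 1, "", "ALA", "CA", "C", tuple(xyz[i])) for i in range(n)
    )
    return StructureModel(atoms, frozenset())
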