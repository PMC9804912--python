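"""Shared fixtures: synthetic structures, alignments and sample tables.

Everything is generated programmatically at test time; no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from vgzinc.conservation import Alignment, SequenceRecord, compute_conservation, read_alignment
from vgzinc.structure import Residue, StructureModel, read_structure
from vgzinc.synthetic import make_msa, make_structure


def build_model(residues: list[tuple[int, str, dict[str, tuple[float, float, float]]]],
                domains: dict[str, tuple[int, int]] | None = None) -> StructureModel:
    """Assemble a StructureModel directly from (number, aa, atoms) triples."""
    return StructureModel(
        residues={
            num: Residue(
                number=num,
                aa=aa,
                chain="A",
                atoms={k: np.asarray(v, dtype=float) for k, v in atoms.items()},
            )
            for num, aa, atoms in residues
        },
        domain_boundaries=dict(domains or {}),
    )


@pytest.fixture(scope="session")
def planted_scene(tmp_path_factory):
    """Two planted tetrahedral sites plus decoys, with a matching MSA.

    Returns (structure, profile, truth): the parsed synthetic structure, the
    conservation profile of its sequence (planted columns fully conserved),
    and the generation ground truth.
    """
    tmp = tmp_path_factory.mktemp("scene")
    pdb_text, truth = make_structure(
        n_residues=60, sites=["CCCC", "HHDE"], n_decoys=4, seed=11
    )
    pdb_path = tmp / "scene.pdb"
    pdb_path.write_text(pdb_text)
    structure = read_structure(pdb_path)
    conserved = set().union(*truth.planted_sites)
    msa_text, _ = make_msa(
        structure.sequence, n_seqs=30, conserved_positions=conserved,
        sub_rate=0.7, seed=12,
    )
    msa_path = tmp / "scene.fasta"
    msa_path.write_text(msa_text)
    profile = compute_conservation(read_alignment(msa_path), "REF")
    return structure, profile, truth


@pytest.fixture
def toy_alignment() -> Alignment:
    """The hand-traceable two-record alignment A-CD / AXCD."""
    return Alignment(
        [
            SequenceRecord(id="r1", residues="A-CD"),
            SequenceRecord(id="r2", residues="AXCD"),
        ]
    )
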