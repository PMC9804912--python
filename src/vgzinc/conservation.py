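"""Alignment reading, per-column conservation scoring and position mapping.

Conservation is scored per column of a multiple sequence alignment (MSA),
projected onto the ungapped numbering of a chosen reference sequence.  The
score is the frequency of the reference residue (or its amino-acid exchange
class) among the non-gap symbols of the column, down-weighted by the
column's non-gap fraction so that sparse columns cannot appear conserved.
Scores are binned into the familiar nine-grade conservation scale
(9 = most conserved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .errors import EmptyInputError, MalformedAlignmentError, UnknownReferenceError

GAP = "-"

#: Marker returned by :func:`map_position` when the target sequence has a gap
#: in the queried alignment column.
GAP_MARKER = None

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Amino-acid exchange groups used by the similarity-class scoring mode.
EXCHANGE_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("AVLIM"),
    frozenset("FYW"),
    frozenset("ST"),
    frozenset("DE"),
    frozenset("NQ"),
    frozenset("KR"),
    frozenset("C"),
    frozenset("H"),
    frozenset("G"),
    frozenset("P"),
)

_CLASS_OF = {aa: grp for grp in EXCHANGE_GROUPS for aa in grp}


@dataclass(frozen=True)
class SequenceRecord:
    """A single (possibly gapped) amino-acid sequence."""

    id: str
    residues: str
    species: str = ""

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """An MSA: equal-length gapped records, order preserved."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("alignment contains no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise MalformedAlignmentError(
                f"records have unequal lengths: {sorted(lengths)}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, accession: str) -> SequenceRecord:
        for r in self.records:
            if r.id == accession:
                return r
        raise UnknownReferenceError(accession)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)


@dataclass
class ConservationProfile:
    """Per-residue conservation on the reference sequence's own numbering.

    ``positions`` are 1-based reference residue numbers; ``scores`` lie in
    [0, 1]; ``grades`` are a monotone 9-bin coarsening of the scores with
    grade 9 the most conserved.  ``low_confidence`` flags columns whose gap
    fraction exceeded 50%.
    """

    ref_id: str
    ref_seq: str
    scores: np.ndarray
    grades: np.ndarray
    gap_fraction: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.ref_seq) + 1)

    @property
    def low_confidence(self) -> np.ndarray:
        return self.gap_fraction > 0.5

    def score(self, position: int) -> float:
        return float(self.scores[position - 1])

    def grade(self, position: int) -> int:
        return int(self.grades[position - 1])

    def aa(self, position: int) -> str:
        return self.ref_seq[position - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "aa": list(self.ref_seq),
                "score": self.scores,
                "grade": self.grades,
                "gap_fraction": self.gap_fraction,
                "low_confidence": self.low_confidence,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_alignment(path: str | Path, format: str | None = None) -> Alignment:
    """Read a FASTA or Clustal alignment file.

    ``format`` is inferred from the filename when omitted (``.aln``/``.clustal``
    → clustal, otherwise fasta).
    """
    path = Path(path)
    if format is None:
        format = "clustal" if path.suffix.lower() in {".aln", ".clustal", ".clw"} else "fasta"
    if format not in {"fasta", "clustal"}:
        raise ValueError(f"unsupported alignment format: {format!r}")
    if path.stat().st_size == 0:
        raise EmptyInputError(f"empty alignment file: {path}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        msg = str(exc)
        if "equal length" in msg or "length" in msg.lower():
            raise MalformedAlignmentError(msg) from exc
        raise EmptyInputError(msg) from exc
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), species=rec.description)
        for rec in msa
    ]
    return Alignment(records)


def _symbol_class(aa: str, mode: str) -> frozenset[str]:
    if mode == "similarity-class":
        return _CLASS_OF.get(aa, frozenset(aa))
    return frozenset(aa)


def compute_conservation(
    aln: Alignment,
    ref_id: str,
    mode: Literal["identity", "similarity-class"] = "identity",
    grade_binning: Literal["linear", "quantile"] = "linear",
) -> ConservationProfile:
    """Score conservation of every reference residue from its MSA column.

    identity mode: frequency of the reference letter among non-gap symbols,
    multiplied by the column's non-gap fraction.  similarity-class mode pools
    amino-acid exchange groups before counting.  Grades are a monotone 9-bin
    coarsening of the scores: ``linear`` bins the absolute [0, 1] score into
    ninths; ``quantile`` ranks scores within the protein.
    """
    ref = aln[ref_id]
    n_rows = len(aln.records)
    scores: list[float] = []
    gap_fracs: list[float] = []
    for j, ref_aa in enumerate(ref.residues):
        if ref_aa == GAP:
            continue
        col = aln.column(j)
        non_gap = [a for a in col if a != GAP]
        non_gap_frac = len(non_gap) / n_rows
        cls = _symbol_class(ref_aa, mode)
        freq = sum(a in cls for a in non_gap) / len(non_gap)
        scores.append(freq * non_gap_frac)
        gap_fracs.append(1.0 - non_gap_frac)
    score_arr = np.asarray(scores, dtype=float)
    grades = _bin_grades(score_arr, grade_binning)
    return ConservationProfile(
        ref_id=ref_id,
        ref_seq=ref.ungapped(),
        scores=score_arr,
        grades=grades,
        gap_fraction=np.asarray(gap_fracs, dtype=float),
    )


def _bin_grades(scores: np.ndarray, binning: str) -> np.ndarray:
    if len(scores) == 0:
        return np.zeros(0, dtype=int)
    if binning == "linear":
        # grade k covers scores in [(k-1)/9, k/9); score 1.0 maps to 9
        grades = 1 + np.floor(scores * 9).astype(int)
        return np.clip(grades, 1, 9)
    if binning == "quantile":
        thresholds = np.quantile(scores, np.arange(1, 9) / 9.0)
        return 1 + np.searchsorted(thresholds, scores, side="right").astype(int)
    raise ValueError(f"unknown grade binning: {binning!r}")


def _column_of_position(record: SequenceRecord, pos: int) -> int:
    """Alignment column index (0-based) of 1-based ungapped position ``pos``."""
    if pos < 1:
        raise IndexError(f"position {pos} out of range")
    count = 0
    for j, aa in enumerate(record.residues):
        if aa != GAP:
            count += 1
            if count == pos:
                return j
    raise IndexError(
        f"position {pos} exceeds ungapped length {count} of {record.id!r}"
    )


def map_position(
    aln: Alignment, from_id: str, pos: int, to_id: str
) -> Optional[int]:
    """Map a 1-based residue index from one aligned sequence to another.

    Returns the residue index in ``to_id`` occupying the same alignment
    column, or :data:`GAP_MARKER` (``None``) when that column is a gap in the
    target sequence.
    """
    src = aln[from_id]
    dst = aln[to_id]
    col = _column_of_position(src, pos)
    if dst.residues[col] == GAP:
        return GAP_MARKER
    return sum(1 for a in dst.residues[: col + 1] if a != GAP)


def conserved_residues(
    profile: ConservationProfile,
    aa_set: Iterable[str],
    min_grade: int,
) -> list[tuple[int, str]]:
    """Reference positions whose residue is in ``aa_set`` at grade ≥ ``min_grade``."""
    if not 1 <= min_grade <= 9:
        raise ValueError("min_grade must be in 1..9")
    aa_set = set(aa_set)
    return [
        (int(p), profile.ref_seq[p - 1])
        for p in profile.positions
        if profile.ref_seq[p - 1] in aa_set and profile.grades[p - 1] >= min_grade
    ]
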