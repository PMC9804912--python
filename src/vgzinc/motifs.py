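"""Sequence-motif scanning and MSA ligand-column mapping.

Covers three needs: locating literal motifs (e.g. the DNA-binding SRSSTSR
stretch), matching the classical C2H2 zinc-finger consensus
``C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H``, and projecting annotated
zinc-ligand positions of C2H2-containing sequences through an alignment onto
a target sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .conservation import GAP_MARKER, Alignment, map_position

#: PROSITE-style C2H2 consensus; lazy spacers give leftmost-shortest matches.
C2H2_PATTERN = re.compile(r"C.{2,4}?C.{3}[LIVMFYWC].{8}H.{3,5}?H")


@dataclass(frozen=True)
class MotifHit:
    pattern_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    matched_text: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched_text):
            raise ValueError("hit span inconsistent with matched text")

    @property
    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval, for interoperability."""
        return self.start - 1, self.end


@dataclass(frozen=True)
class LigandAlignment:
    """One target residue aligned to an annotated zinc-ligand column."""

    position: int
    aa: str
    ligand_class: str  # "C", "H" or "D/E"


@dataclass
class LigandColumnMap:
    ref_id: str
    entries: list[LigandAlignment]

    @property
    def positions(self) -> set[int]:
        return {e.position for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"position": e.position, "aa": e.aa, "ligand_class": e.ligand_class}
                for e in self.entries
            ]
        )


def scan_literal(seq: str, motif: str, pattern_id: str | None = None) -> list[MotifHit]:
    """All (possibly overlapping) literal occurrences, ascending start."""
    if not motif:
        raise ValueError("motif must be non-empty")
    pattern_id = pattern_id or motif
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(
            MotifHit(pattern_id, start + 1, start + len(motif), motif)
        )
        start = seq.find(motif, start + 1)
    return hits


def scan_c2h2(seq: str) -> list[MotifHit]:
    """Leftmost non-overlapping matches of the C2H2 zinc-finger consensus."""
    return [
        MotifHit("C2H2", m.start() + 1, m.end(), m.group())
        for m in C2H2_PATTERN.finditer(seq)
    ]


def map_ligand_columns(
    aln: Alignment,
    target_id: str,
    motif_ids: Sequence[str],
    ligand_positions: dict[str, Iterable[tuple[int, str]]],
) -> LigandColumnMap:
    """Project annotated zinc-ligand positions onto the target sequence.

    ``ligand_positions`` maps each motif-carrying accession to its
    (1-based position, ligand class) annotations.  Positions whose column is
    gapped in the target are omitted.  Output is deduplicated and sorted by
    target position, so it is stable under permutation of alignment records.
    """
    target = aln[target_id]
    target_seq = target.ungapped()
    seen: set[tuple[int, str]] = set()
    entries: list[LigandAlignment] = []
    for motif_id in motif_ids:
        aln[motif_id]  # raises UnknownReferenceError early
        for pos, lig_class in ligand_positions.get(motif_id, ()):
            mapped = map_position(aln, motif_id, pos, target_id)
            if mapped is GAP_MARKER:
                continue
            key = (mapped, lig_class)
            if key in seen:
                continue
            seen.add(key)
            entries.append(
                LigandAlignment(mapped, target_seq[mapped - 1], lig_class)
            )
    entries.sort(key=lambda e: (e.position, e.ligand_class))
    return LigandColumnMap(ref_id=target_id, entries=entries)


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """BED-like table: 1-based inclusive plus 0-based half-open columns."""
    return pd.DataFrame(
        [
            {
                "pattern_id": h.pattern_id,
                "start": h.start,
                "end": h.end,
                "start0": h.interval0[0],
                "end0": h.interval0[1],
                "matched_text": h.matched_text,
            }
            for h in hits
        ]
    )
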