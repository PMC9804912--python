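"""Structure parsing and residue-level geometry.

Wraps a parsed PDB/mmCIF model in a light container exposing the side-chain
donor atoms relevant to Zn2+ coordination (His ND1/NE2, Cys SG, Asp OD1/OD2,
Glu OE1/OE2, Ser OG), minimum inter-residue donor distances, disulfide
detection, windowed residue censuses, and a neighbour-count burial proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.PDB.Polypeptide import protein_letters_3to1

from .errors import FormatError, MissingResidueError

#: Side-chain atoms that can donate a lone pair to a Zn2+ ion.
FUNCTIONAL_ATOMS: dict[str, tuple[str, ...]] = {
    "H": ("ND1", "NE2"),
    "C": ("SG",),
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
    "S": ("OG",),
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Residue:
    number: int
    aa: str
    chain: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def functional_coords(self) -> np.ndarray:
        """Coordinates used for coordination geometry, as an (n, 3) array.

        Fallback chain: declared functional atoms → any side-chain heavy
        atom → CA.  Predicted models with truncated side chains therefore
        still yield a usable (if coarser) position.
        """
        names = FUNCTIONAL_ATOMS.get(self.aa, ())
        coords = [self.atoms[n] for n in names if n in self.atoms]
        if not coords:
            coords = [v for k, v in self.atoms.items() if k not in BACKBONE_ATOMS]
        if not coords and "CA" in self.atoms:
            coords = [self.atoms["CA"]]
        if not coords:
            coords = list(self.atoms.values())
        return np.vstack(coords)

    def has_functional_atoms(self) -> bool:
        return any(n in self.atoms for n in FUNCTIONAL_ATOMS.get(self.aa, ()))

    def burial_anchor(self) -> np.ndarray | None:
        """CB coordinate (CA for Gly or CB-less residues)."""
        if "CB" in self.atoms:
            return self.atoms["CB"]
        if "CA" in self.atoms:
            return self.atoms["CA"]
        return None


@dataclass
class StructureModel:
    """A single-chain protein model with residue-indexed geometry access."""

    residues: dict[int, Residue]
    domain_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)
    source: str = ""

    @property
    def residue_numbers(self) -> list[int]:
        return sorted(self.residues)

    @property
    def sequence(self) -> str:
        """One-letter sequence over ascending residue numbers."""
        return "".join(self.residues[n].aa for n in self.residue_numbers)

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, number: int) -> bool:
        return number in self.residues

    def residue(self, number: int) -> Residue:
        try:
            return self.residues[number]
        except KeyError:
            raise MissingResidueError(f"residue {number} not in structure") from None

    def aa(self, number: int) -> str:
        return self.residue(number).aa


def read_structure(
    path: str | Path,
    format: str | None = None,
    chain: str | None = None,
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is used (a warning is emitted if more exist); the
    analysed chain defaults to the first one in the file.
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if path.stat().st_size == 0:
        raise FormatError(f"empty structure file: {path}")
    parser = MMCIFParser(QUIET=True) if format == "mmcif" else PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError, KeyError) as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    models = list(structure)
    if not models:
        raise FormatError(f"no models in {path}")
    if len(models) > 1:
        warnings.warn(f"{path} has {len(models)} models; using the first")
    model = models[0]
    chains = list(model)
    if not chains:
        raise FormatError(f"no chains in {path}")
    if chain is None:
        target = chains[0]
    else:
        try:
            target = model[chain]
        except KeyError:
            raise FormatError(f"chain {chain!r} not in {path}") from None
    residues: dict[int, Residue] = {}
    for res in target:
        hetflag, resseq, _icode = res.get_id()
        if hetflag.strip():
            continue
        aa = protein_letters_3to1.get(res.get_resname().upper(), "X")
        residues[resseq] = Residue(
            number=resseq,
            aa=aa,
            chain=target.id,
            atoms={a.get_name(): a.get_coord().astype(float) for a in res},
        )
    if not residues:
        raise FormatError(f"no amino-acid residues in chain {target.id} of {path}")
    return StructureModel(residues=residues, source=str(path))


def min_functional_distance(s: StructureModel, res_a: int, res_b: int) -> float:
    """Minimum distance (Å) between the donor atoms of two residues.

    Symmetric; 0.0 when ``res_a == res_b``.
    """
    if res_a == res_b:
        s.residue(res_a)
        return 0.0
    ca = s.residue(res_a).functional_coords()
    cb = s.residue(res_b).functional_coords()
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())


def detect_disulfides(
    s: StructureModel, sg_cutoff: float = 2.3
) -> list[tuple[int, int]]:
    """Cys pairs whose SG–SG distance is within ``sg_cutoff`` Å.

    Greedy nearest-first pairing: each Cys joins at most one bridge.
    """
    cys = [
        (n, r.atoms["SG"])
        for n, r in sorted(s.residues.items())
        if r.aa == "C" and "SG" in r.atoms
    ]
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i][1] - cys[j][1]))
            if d <= sg_cutoff:
                candidates.append((d, cys[i][0], cys[j][0]))
    candidates.sort()
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _d, a, b in candidates:
        if a not in used and b not in used:
            pairs.append((a, b))
            used.update((a, b))
    return sorted(pairs)


def residue_census(
    s: StructureModel, window: tuple[int, int], aa_set: set[str] | str
) -> tuple[int, list[int]]:
    """Count residues of the given types inside a closed residue-number window."""
    start, end = window
    if start > end or start < 1:
        raise ValueError(f"degenerate window {window}")
    aa_set = set(aa_set)
    positions = [
        n for n in s.residue_numbers if start <= n <= end and s.residues[n].aa in aa_set
    ]
    return len(positions), positions


def burial_score(s: StructureModel, res: int, radius: float = 10.0) -> int:
    """Number of other residues' CB atoms (CA for Gly) within ``radius`` Å.

    A cheap burial proxy: ≥ 18 neighbours within 10 Å is treated as buried
    elsewhere in the package.
    """
    anchor = s.residue(res).burial_anchor()
    if anchor is None:
        raise MissingResidueError(f"residue {res} has no CB/CA atom")
    count = 0
    for n, other in s.residues.items():
        if n == res:
            continue
        oa = other.burial_anchor()
        if oa is not None and float(np.linalg.norm(oa - anchor)) <= radius:
            count += 1
    return count
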