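"""Synthetic structures, alignments and ICP-MS tables with known truth.

Every pipeline stage is testable without downloads: the structure generator
plants tetrahedral coordination sites (donor atoms 2.1 Å from a virtual ion,
the canonical Zn–ligand bond length being ~2.0–2.4 Å) plus isolated His/Cys
decoys; the alignment generator plants fully conserved columns; the ICP-MS
generator draws measurements around a known true Zn:protein ratio with
multiplicative Gaussian noise.  All generators are byte-deterministic under
a fixed seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, StructureBuilder

from .cluster_search import CandidateCluster
from .errors import GenerationError
from .icpms import Constants
from .structure import FUNCTIONAL_ATOMS

AA_3LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: Unit vectors to the vertices of a regular tetrahedron.
TETRAHEDRAL = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)

OCTAHEDRAL = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)

ION_BOND = 2.1  # Å, donor-atom to virtual ion
SITE_SPACING = 60.0  # Å between planted ions
DECOY_MARGIN = 15.0  # Å minimum decoy separation guaranteed by layout


@dataclass
class SyntheticTruth:
    planted_sites: list[frozenset[int]] = field(default_factory=list)
    ion_positions: list[tuple[float, float, float]] = field(default_factory=list)
    conserved_columns: list[int] = field(default_factory=list)
    decoy_positions: list[int] = field(default_factory=list)
    true_ratio: float | None = None
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted_sites": [sorted(s) for s in self.planted_sites],
                    "ion_positions": self.ion_positions,
                    "conserved_columns": self.conserved_columns,
                    "decoy_positions": self.decoy_positions,
                    "true_ratio": self.true_ratio,
                    "seed": self.seed,
                },
                indent=2,
            )
        )


def _primary_atom(aa: str) -> str:
    return FUNCTIONAL_ATOMS[aa][-1] if aa == "H" else FUNCTIONAL_ATOMS[aa][0]


def make_structure(
    n_residues: int,
    sites: list[str],
    n_decoys: int = 0,
    seed: int = 0,
    hydrophobic_shell: bool = False,
) -> tuple[str, SyntheticTruth]:
    """Build a single-chain PDB with planted coordination sites.

    ``sites`` are residue-type strings over {H, C, D, E, S} (up to four
    residues per site); each site's donor atoms sit 2.1 Å from a virtual ion
    in tetrahedral directions.  Decoys are His/Cys placed ≥ 15 Å from every
    site and from each other.  Remaining residues are alanine filler laid
    out as a self-avoiding random walk well away from the sites.  With
    ``hydrophobic_shell`` each site is wrapped in six Leu/Ile/Phe/Val
    residues at 7.5 Å from the ion (a polar-inside / hydrophobic-outside
    arrangement).

    Returns the PDB text and the ground truth.
    """
    rng = np.random.default_rng(seed)
    for site_types in sites:
        if not set(site_types) <= set("HCDES"):
            raise ValueError(f"site residues must be from H/C/D/E/S: {site_types!r}")
        if not 1 <= len(site_types) <= 4:
            raise ValueError("each site must have 1..4 residues")
    n_shell = 6 * len(sites) if hydrophobic_shell else 0
    n_planted = sum(len(s) for s in sites) + n_decoys + n_shell
    if n_residues < n_planted:
        raise ValueError(
            f"n_residues={n_residues} cannot hold {n_planted} planted residues"
        )

    # residue_number -> (aa, {atom: coord})
    placed: dict[int, tuple[str, dict[str, np.ndarray]]] = {}
    next_num = 1
    truth = SyntheticTruth(seed=seed)

    for k, site_types in enumerate(sites):
        ion = np.array([SITE_SPACING * k, 0.0, 0.0])
        members = []
        for m, aa in enumerate(site_types):
            direction = TETRAHEDRAL[m]
            donor = ion + ION_BOND * direction
            atoms = {_primary_atom(aa): donor, "CA": ion + (ION_BOND + 2.4) * direction}
            placed[next_num] = (aa, atoms)
            members.append(next_num)
            next_num += 1
        truth.planted_sites.append(frozenset(members))
        truth.ion_positions.append(tuple(ion))
        if hydrophobic_shell:
            for m, direction in enumerate(OCTAHEDRAL):
                aa = "LIFVLI"[m]
                atoms = {"CA": ion + 7.5 * direction}
                placed[next_num] = (aa, atoms)
                next_num += 1

    for j in range(n_decoys):
        pos = np.array([20.0 * j, -60.0, 0.0])
        aa = "H" if j % 2 == 0 else "C"
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        placed[next_num] = (
            aa,
            {"CA": pos, _primary_atom(aa): pos + 1.5 * direction},
        )
        truth.decoy_positions.append(next_num)
        next_num += 1

    # alanine filler: self-avoiding random walk confined to y >= 40
    existing = [c for _, atoms in placed.values() for c in atoms.values()]
    current = np.array([0.0, 60.0, 0.0])
    while next_num <= n_residues:
        for attempt in range(200):
            step = rng.normal(size=3)
            step *= 3.8 / np.linalg.norm(step)
            candidate = current + step
            if candidate[1] < 40.0:
                continue
            if existing and np.min(
                np.linalg.norm(np.asarray(existing) - candidate, axis=1)
            ) < 3.0:
                continue
            break
        else:
            raise GenerationError(
                f"filler walk stuck at residue {next_num} after 200 retries"
            )
        placed[next_num] = ("A", {"CA": candidate.copy()})
        existing.append(candidate.copy())
        current = candidate
        next_num += 1

    return _to_pdb(placed), truth


def _to_pdb(placed: dict[int, tuple[str, dict[str, np.ndarray]]]) -> str:
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("synthetic")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    serial = 1
    for num in sorted(placed):
        aa, atoms = placed[num]
        builder.init_residue(AA_3LETTER[aa], " ", num, " ")
        for name in sorted(atoms):
            coord = np.asarray(atoms[name], dtype=float)
            fullname = name.center(4) if len(name) < 4 else name
            builder.init_atom(
                name, coord, 0.0, 1.0, " ", fullname,
                serial_number=serial, element=name[0],
            )
            serial += 1
    out = io.StringIO()
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    pdbio.save(out)
    return out.getvalue()


def make_msa(
    ref: str,
    n_seqs: int,
    conserved_positions: set[int],
    sub_rate: float,
    seed: int = 0,
    ref_id: str = "REF",
) -> tuple[str, SyntheticTruth]:
    """FASTA alignment text with planted fully conserved columns.

    The first record is the reference itself.  In every other sequence,
    conserved positions are copied verbatim and each remaining position is
    substituted independently with probability ``sub_rate`` (uniform over
    the other 19 residues).  No gaps are introduced.
    """
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must lie in [0, 1]")
    bad = [p for p in conserved_positions if not 1 <= p <= len(ref)]
    if bad:
        raise ValueError(f"conserved positions outside reference: {bad}")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    lines = [f">{ref_id}", ref]
    for i in range(1, n_seqs):
        seq = list(ref)
        for j in range(len(ref)):
            if (j + 1) in conserved_positions:
                continue
            if rng.random() < sub_rate:
                choices = alphabet[alphabet != ref[j]]
                seq[j] = str(rng.choice(choices))
        lines.append(f">S{i:03d}")
        lines.append("".join(seq))
    truth = SyntheticTruth(
        conserved_columns=sorted(conserved_positions), seed=seed
    )
    return "\n".join(lines) + "\n", truth


def make_icpms(
    true_ratio: float,
    protein_concs: tuple[float, ...] = (1.2, 1.6, 2.0, 2.4, 2.8),
    noise_sd_frac: float = 0.05,
    n_blanks: int = 5,
    blank_level: float = 5.0,
    seed: int = 0,
    dilution: float = 5.0,
    k: Constants | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Sample table emulating the study's measurement layout.

    Defaults mirror the published conditions: five analyte samples with
    protein at 1.2–2.8 g/L, five buffer blanks, 5× dilution.  Each analyte's
    instrument reading (μg/L) is the noise-free Zn mass concentration implied
    by ``true_ratio`` divided by the dilution factor, with multiplicative
    Gaussian noise; blanks are Normal(blank_level, blank_level/3) truncated
    at zero.
    """
    if true_ratio < 0:
        raise ValueError("true_ratio must be non-negative")
    k = k or Constants()
    rng = np.random.default_rng(seed)
    rows = []
    for i, protein in enumerate(protein_concs, start=1):
        zn_gL = true_ratio * (protein / k.mw_protein) * k.mw_zn
        eps = rng.normal(0.0, noise_sd_frac) if noise_sd_frac > 0 else 0.0
        zn_instrument = zn_gL * 1e6 * (1.0 + eps) / dilution
        rows.append(
            {
                "id": f"vg{i}",
                "group": "analyte",
                "zn_ugL": max(zn_instrument, 0.0),
                "dilution": dilution,
                "protein_gL": protein,
            }
        )
    for i in range(1, n_blanks + 1):
        level = max(rng.normal(blank_level, blank_level / 3.0), 0.0)
        rows.append(
            {
                "id": f"blank{i}",
                "group": "blank",
                "zn_ugL": level,
                "dilution": dilution,
                "protein_gL": 0.0,
            }
        )
    truth = SyntheticTruth(true_ratio=true_ratio, seed=seed)
    return pd.DataFrame(rows), truth


def score_recovery(
    clusters: list[CandidateCluster],
    truth: SyntheticTruth,
    min_size: int = 4,
) -> tuple[float, float]:
    """Precision and recall of planted sites among reported clusters.

    A cluster counts as a true positive when its member set equals a planted
    site exactly; only clusters with at least ``min_size`` members (i.e. not
    sub-minimal) enter the precision denominator.
    """
    planted = set(truth.planted_sites)
    reported = [frozenset(cl.positions) for cl in clusters if cl.size >= min_size]
    tp = sum(1 for r in reported if r in planted)
    precision = tp / len(reported) if reported else (1.0 if not planted else 0.0)
    recall = tp / len(planted) if planted else 1.0
    return precision, recall


def write_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialise a versioned synthetic test set (structure, MSA, ICP-MS)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pdb_text, struct_truth = make_structure(
        n_residues=60, sites=["CCCC", "HHDE"], n_decoys=4, seed=seed
    )
    n_res = 60
    ref = _sequence_from_pdb_text(pdb_text, n_res)
    conserved = sorted(set().union(*struct_truth.planted_sites))
    msa_text, msa_truth = make_msa(
        ref, n_seqs=30, conserved_positions=set(conserved), sub_rate=0.7, seed=seed
    )
    icpms_df, icpms_truth = make_icpms(true_ratio=3.0, seed=seed)
    paths = {
        "structure": outdir / "synthetic_structure.pdb",
        "alignment": outdir / "synthetic_msa.fasta",
        "icpms": outdir / "synthetic_icpms.csv",
        "truth": outdir / "synthetic_truth.json",
    }
    paths["structure"].write_text(pdb_text)
    paths["alignment"].write_text(msa_text)
    icpms_df.to_csv(paths["icpms"], index=False)
    merged = SyntheticTruth(
        planted_sites=struct_truth.planted_sites,
        ion_positions=struct_truth.ion_positions,
        conserved_columns=msa_truth.conserved_columns,
        decoy_positions=struct_truth.decoy_positions,
        true_ratio=icpms_truth.true_ratio,
        seed=seed,
    )
    merged.to_json(paths["truth"])
    return paths


def _sequence_from_pdb_text(pdb_text: str, n_residues: int) -> str:
    three_to_one = {v: k for k, v in AA_3LETTER.items()}
    seq = {}
    for line in pdb_text.splitlines():
        if line.startswith("ATOM"):
            num = int(line[22:26])
            seq[num] = three_to_one[line[17:20].strip()]
    return "".join(seq[n] for n in sorted(seq))
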