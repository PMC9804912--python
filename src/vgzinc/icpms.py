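"""ICP-MS data reduction to a Zn:protein molar stoichiometry.

Instrument readings (μg/L Zn on the diluted scale) are corrected for
dilution, converted to molarity with the molecular weights of the protein
and of Zn2+, and divided by the protein molarity to give a per-sample
mol Zn / mol protein ratio.  Detection limits follow the blank-SD
convention: LOD = 3×SD(blanks), LOQ = 10×SD(blanks).  Group differences are
assessed with the Kruskal–Wallis rank test.

Defaults reproduce the published honey bee vitellogenin (Vg) study
conditions: 5× dilution, Vg molecular weight 201147.7 g/mol and Zn
65.30 g/mol.  Readings are assumed to be internal-standard-corrected
concentrations (Rh normalisation done by the instrument); any isobaric
64Ni correction is likewise assumed upstream, with the mass-66 channel as
the clean default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, InsufficientBlanksError

UG_PER_G = 1e6


@dataclass(frozen=True)
class Constants:
    """Molecular weights (g/mol) used for the molar conversion."""

    mw_protein: float = 201147.7
    mw_zn: float = 65.30

    def __post_init__(self) -> None:
        if self.mw_protein <= 0 or self.mw_zn <= 0:
            raise ValueError("molecular weights must be positive")


@dataclass(frozen=True)
class IcpmsSample:
    id: str
    group: str  # "analyte" or "blank"
    zn_measured: float  # μg/L, instrument (post-dilution) scale
    dilution_factor: float = 5.0
    protein_conc: float = 0.0  # g/L, undiluted sample scale
    ni_signal: float | None = None  # carried as metadata only

    def __post_init__(self) -> None:
        if self.zn_measured < 0 or self.protein_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be ≥ 1")


@dataclass(frozen=True)
class DetectionLimits:
    lod: float  # μg/L
    loq: float  # μg/L


@dataclass
class StoichiometryResult:
    samples: pd.DataFrame  # per-sample table incl. ratio and below-LOD flags
    mean: float
    min: float
    max: float
    n_used: int
    limits: DetectionLimits | None = None

    @property
    def ratios(self) -> np.ndarray:
        return self.samples.loc[self.samples["used"], "ratio"].to_numpy()


def corrected_zn(sample: IcpmsSample) -> float:
    """Zn concentration (μg/L) on the undiluted sample scale."""
    return sample.zn_measured * sample.dilution_factor


def detection_limits(blanks: list[IcpmsSample]) -> DetectionLimits:
    """LOD/LOQ = 3×/10× the sample SD (n−1 denominator) of the blanks."""
    if len(blanks) < 2:
        raise InsufficientBlanksError(
            f"need ≥ 2 blank samples, got {len(blanks)}"
        )
    values = np.array([b.zn_measured for b in blanks], dtype=float)
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        warnings.warn("blank readings are identical; LOD/LOQ degenerate to 0")
    return DetectionLimits(lod=3.0 * sd, loq=10.0 * sd)


def molar_ratio(zn_conc: float, protein_conc: float, k: Constants | None = None) -> float:
    """mol Zn per mol protein from mass concentrations in g/L."""
    k = k or Constants()
    if protein_conc <= 0:
        raise ValueError("protein concentration must be positive")
    return (zn_conc / k.mw_zn) / (protein_conc / k.mw_protein)


def summarize(
    samples: list[IcpmsSample],
    k: Constants | None = None,
    exclude_below_lod: bool = True,
) -> StoichiometryResult:
    """Per-sample Zn:protein molar ratios with mean/min/max over analytes.

    Detection limits are derived from the blank samples in the input (when
    at least two are present); analytes whose corrected Zn falls below the
    LOD are flagged and, by default, excluded from the summary statistics.
    Note the LOD is defined on the instrument scale, so the comparison uses
    the dilution-corrected LOD.
    """
    k = k or Constants()
    analytes = [s for s in samples if s.group == "analyte"]
    blanks = [s for s in samples if s.group == "blank"]
    if not analytes:
        raise EmptyInputError("no analyte samples")
    limits = detection_limits(blanks) if len(blanks) >= 2 else None
    rows = []
    for s in analytes:
        zn_undiluted_ugL = corrected_zn(s)
        ratio = molar_ratio(zn_undiluted_ugL / UG_PER_G, s.protein_conc, k)
        below_lod = (
            limits is not None
            and zn_undiluted_ugL < limits.lod * s.dilution_factor
        )
        below_loq = (
            limits is not None
            and zn_undiluted_ugL < limits.loq * s.dilution_factor
        )
        rows.append(
            {
                "id": s.id,
                "zn_measured_ugL": s.zn_measured,
                "zn_corrected_ugL": zn_undiluted_ugL,
                "protein_gL": s.protein_conc,
                "ratio": ratio,
                "below_lod": below_lod,
                "below_loq": below_loq,
                "used": not (below_lod and exclude_below_lod),
            }
        )
    table = pd.DataFrame(rows)
    used = table.loc[table["used"], "ratio"]
    if used.empty:
        raise EmptyInputError("all analyte samples fell below the LOD")
    return StoichiometryResult(
        samples=table,
        mean=float(used.mean()),
        min=float(used.min()),
        max=float(used.max()),
        n_used=int(used.size),
        limits=limits,
    )


def kruskal_wallis(groups: list[list[float]]) -> tuple[float, int, float]:
    """Kruskal–Wallis H (tie-corrected), degrees of freedom, and p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("each group needs at least one value")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least three values in total")
    df = len(groups) - 1
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def read_icpms_table(path: str | Path) -> list[IcpmsSample]:
    """Read a delimited-text or spreadsheet sample table.

    Expected columns: ``id``, ``group`` (analyte/blank), ``zn_ugL``,
    ``dilution``, ``protein_gL``; ``ni_signal`` is optional.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep)
    required = {"id", "group", "zn_ugL", "dilution", "protein_gL"}
    missing = required - set(df.columns)
    if missing:
        raise EmptyInputError(f"sample table missing columns: {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            IcpmsSample(
                id=str(row["id"]),
                group=str(row["group"]),
                zn_measured=float(row["zn_ugL"]),
                dilution_factor=float(row["dilution"]),
                protein_conc=float(row["protein_gL"]),
                ni_signal=float(row["ni_signal"]) if "ni_signal" in df.columns and pd.notna(row.get("ni_signal")) else None,
            )
        )
    return samples
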