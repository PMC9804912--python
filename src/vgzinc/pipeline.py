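"""End-to-end orchestration: conservation → clusters → contrast → motifs → stoichiometry.

A single :class:`RunConfig` (loadable from YAML) drives all stages and every
output is written alongside a machine-readable run log that echoes the full
configuration, so calibrated thresholds are auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .cluster_search import SearchConfig, clusters_to_frame, clusters_to_json, search_clusters
from .conservation import compute_conservation, read_alignment
from .contrast import load_eisenberg_scale, score_clusters
from .errors import PipelineError, VgZincError
from .icpms import Constants, kruskal_wallis, read_icpms_table, summarize
from .motifs import hits_to_frame, scan_c2h2, scan_literal
from .structure import read_structure


@dataclass
class RunConfig:
    structure_path: str
    alignment_path: str
    ref_id: str
    outdir: str
    icpms_path: str | None = None
    domain_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)
    search: SearchConfig = field(default_factory=SearchConfig)
    conservation_mode: str = "identity"
    r_inner: float = 5.0
    r_outer: float = 10.0
    literal_motifs: list[str] = field(default_factory=lambda: ["SRSSTSR"])
    scan_c2h2: bool = True
    constants: Constants = field(default_factory=Constants)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        search = SearchConfig(**raw.pop("search", {}))
        constants = Constants(**raw.pop("constants", {}))
        boundaries = {
            k: tuple(v) for k, v in raw.pop("domain_boundaries", {}).items()
        }
        return cls(
            search=search, constants=constants, domain_boundaries=boundaries, **raw
        )

    def to_dict(self) -> dict:
        return {
            "structure_path": self.structure_path,
            "alignment_path": self.alignment_path,
            "ref_id": self.ref_id,
            "outdir": self.outdir,
            "icpms_path": self.icpms_path,
            "domain_boundaries": {k: list(v) for k, v in self.domain_boundaries.items()},
            "search": self.search.to_dict(),
            "conservation_mode": self.conservation_mode,
            "r_inner": self.r_inner,
            "r_outer": self.r_outer,
            "literal_motifs": self.literal_motifs,
            "scan_c2h2": self.scan_c2h2,
            "constants": {
                "mw_protein": self.constants.mw_protein,
                "mw_zn": self.constants.mw_zn,
            },
            "seed": self.seed,
        }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages, write the report bundle, and return a summary dict.

    Any stage failure aborts with a stage-tagged :class:`PipelineError` and
    removes partial outputs.
    """
    for required in (cfg.structure_path, cfg.alignment_path):
        if not Path(required).exists():
            raise PipelineError("config", f"input not found: {required}")
    if cfg.icpms_path is not None and not Path(cfg.icpms_path).exists():
        raise PipelineError("config", f"input not found: {cfg.icpms_path}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"stages": []}

    def _stage(name: str, fn):
        try:
            result = fn()
        except VgZincError as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError(name, str(exc)) from exc
        summary["stages"].append(name)
        return result

    structure = _stage("structure", lambda: read_structure(cfg.structure_path))
    structure.domain_boundaries = dict(cfg.domain_boundaries)
    aln = _stage("alignment", lambda: read_alignment(cfg.alignment_path))
    profile = _stage(
        "conservation",
        lambda: compute_conservation(aln, cfg.ref_id, mode=cfg.conservation_mode),
    )
    profile_path = outdir / "conservation.tsv"
    profile.to_tsv(profile_path)
    written.append(profile_path)

    clusters = _stage("clusters", lambda: search_clusters(structure, profile, cfg.search))
    scale = load_eisenberg_scale()
    _stage("contrast", lambda: score_clusters(clusters, structure, scale, cfg.r_inner, cfg.r_outer))
    cluster_tsv = outdir / "clusters.tsv"
    clusters_to_frame(clusters).to_csv(cluster_tsv, sep="\t", index=False)
    clusters_to_json(clusters, outdir / "clusters.json")
    written += [cluster_tsv, outdir / "clusters.json"]
    summary["n_clusters"] = len(clusters)
    summary["n_clusters_min4"] = sum(
        1 for cl in clusters if cl.size >= cfg.search.min_coordinators
    )

    def _motifs():
        hits = []
        seq = structure.sequence
        for motif in cfg.literal_motifs:
            hits += scan_literal(seq, motif)
        if cfg.scan_c2h2:
            hits += scan_c2h2(seq)
        return hits

    hits = _stage("motifs", _motifs)
    motif_tsv = outdir / "motifs.tsv"
    hits_to_frame(hits).to_csv(motif_tsv, sep="\t", index=False)
    written.append(motif_tsv)
    summary["n_motif_hits"] = len(hits)

    if cfg.icpms_path is not None:
        def _stoich():
            samples = read_icpms_table(cfg.icpms_path)
            result = summarize(samples, cfg.constants)
            analyte = [
                s.zn_measured for s in samples if s.group == "analyte"
            ]
            blank = [s.zn_measured for s in samples if s.group == "blank"]
            kw = (
                kruskal_wallis([analyte, blank])
                if len(analyte) >= 1 and len(blank) >= 1
                else None
            )
            return result, kw

        result, kw = _stage("stoichiometry", _stoich)
        stoich_tsv = outdir / "stoichiometry.tsv"
        result.samples.to_csv(stoich_tsv, sep="\t", index=False)
        written.append(stoich_tsv)
        summary["zn_ratio_mean"] = result.mean
        summary["zn_ratio_min"] = result.min
        summary["zn_ratio_max"] = result.max
        if result.limits is not None:
            summary["lod_ugL"] = result.limits.lod
            summary["loq_ugL"] = result.limits.loq
        if kw is not None:
            summary["kruskal_wallis"] = {"H": kw[0], "df": kw[1], "p": kw[2]}

    log = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "version": __version__,
        "config": cfg.to_dict(),
        "summary": {k: v for k, v in summary.items() if k != "stages"},
        "stages": summary["stages"],
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return summary
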