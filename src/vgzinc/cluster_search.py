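"""Candidate zinc-coordination cluster search.

The procedure formalises a structure-plus-conservation walk used to locate
putative Zn2+ sites on an apo model:

1. seed with conserved His/Cys residues (conservation grade ≥ threshold);
2. group seeds into connected components of the proximity graph whose edges
   join residues with donor atoms within ``d_pair`` Å;
3. components smaller than the minimum coordination number (four, the most
   common Zn2+ ligand count) are augmented with conserved Asp/Glu/Ser
   residues adjacent in space (``d_aux``) or sequence (``seq_adjacency``);
4. crossing disulfide-bridge pairs are reported as candidate ZnC4 redox
   switches;
5. each cluster is classified (structural-like / catalytic-like /
   redox-switch-like / sub-minimal) and assigned a domain label.

Distances are taken between side-chain donor atoms on a static model, so the
pairing radius ``d_pair`` is deliberately looser (default 8 Å) than the
~2.0–2.4 Å ligand–ion bond length: two ligands of one ion may sit ~4.8 Å
apart when bound, and apo side chains need slack to rearrange.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .conservation import ConservationProfile, conserved_residues
from .errors import AlignmentMismatchError
from .structure import StructureModel, detect_disulfides, min_functional_distance, burial_score

PRIMARY_AA = frozenset("HC")
AUXILIARY_AA = frozenset("DES")

CLASS_REDOX = "redox-switch-like"
CLASS_STRUCTURAL = "structural-like"
CLASS_CATALYTIC = "catalytic-like"
CLASS_SUBMINIMAL = "sub-minimal"


@dataclass(frozen=True)
class CandidateResidue:
    position: int
    aa: str
    role: str  # "primary" (H/C) or "auxiliary" (D/E/S)
    conservation_grade: int

    def __post_init__(self) -> None:
        if self.role == "primary" and self.aa not in PRIMARY_AA:
            raise ValueError(f"primary residue must be H or C, got {self.aa}")
        if self.role == "auxiliary" and self.aa not in AUXILIARY_AA:
            raise ValueError(f"auxiliary residue must be D/E/S, got {self.aa}")


@dataclass
class CandidateCluster:
    id: str
    members: list[CandidateResidue]
    domain: str = "unassigned"
    classification: str = CLASS_SUBMINIMAL
    contrast: float | None = None
    from_znc4: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def positions(self) -> set[int]:
        return {m.position for m in self.members}

    @property
    def min_position(self) -> int:
        return min(m.position for m in self.members)

    def sorted_members(self) -> list[CandidateResidue]:
        return sorted(self.members, key=lambda m: m.position)


@dataclass
class SearchConfig:
    """Tunable thresholds of the cluster search."""

    min_grade: int = 7
    d_pair: float = 8.0
    d_aux: float = 8.0
    seq_adjacency: int = 2
    min_coordinators: int = 4
    buried_neighbors: int = 18
    burial_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.min_coordinators < 2:
            raise ValueError("min_coordinators must be ≥ 2")
        for name in ("d_pair", "d_aux", "seq_adjacency", "min_grade"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "min_grade": self.min_grade,
            "d_pair": self.d_pair,
            "d_aux": self.d_aux,
            "seq_adjacency": self.seq_adjacency,
            "min_coordinators": self.min_coordinators,
            "buried_neighbors": self.buried_neighbors,
            "burial_radius": self.burial_radius,
        }


def _check_numbering(s: StructureModel, profile: ConservationProfile) -> None:
    """Structure and profile must describe the same sequence numbering."""
    shared = [n for n in s.residue_numbers if 1 <= n <= len(profile.ref_seq)]
    if not shared:
        raise AlignmentMismatchError("no overlap between structure and profile numbering")
    mismatches = sum(1 for n in shared if s.aa(n) != profile.ref_seq[n - 1])
    if mismatches / len(shared) > 0.05:
        raise AlignmentMismatchError(
            f"structure sequence disagrees with profile at "
            f"{mismatches}/{len(shared)} positions"
        )


def find_primary_candidates(
    s: StructureModel, profile: ConservationProfile, cfg: SearchConfig | None = None
) -> list[CandidateResidue]:
    """All His/Cys residues at conservation grade ≥ ``cfg.min_grade``."""
    cfg = cfg or SearchConfig()
    _check_numbering(s, profile)
    out = []
    for pos, aa in conserved_residues(profile, PRIMARY_AA, cfg.min_grade):
        if pos in s and s.aa(pos) == aa:
            out.append(
                CandidateResidue(pos, aa, "primary", profile.grade(pos))
            )
    return out


def build_clusters(
    candidates: list[CandidateResidue],
    s: StructureModel,
    cfg: SearchConfig | None = None,
) -> list[CandidateCluster]:
    """Connected components of the donor-atom proximity graph.

    Residues are linked when their minimum donor-atom distance is at most
    ``cfg.d_pair`` Å.  Singletons are retained (reported as sub-minimal).
    Clusters are ordered, and provisionally named, by their lowest member
    position.
    """
    cfg = cfg or SearchConfig()
    if not candidates:
        return []
    positions = [c.position for c in candidates]
    n = len(positions)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if min_functional_distance(s, positions[i], positions[j]) <= cfg.d_pair:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[CandidateResidue]] = {}
    for i, cand in enumerate(candidates):
        groups.setdefault(find(i), []).append(cand)
    clusters = [
        CandidateCluster(id="", members=sorted(g, key=lambda m: m.position))
        for g in groups.values()
    ]
    clusters.sort(key=lambda c: c.min_position)
    for k, cl in enumerate(clusters, start=1):
        cl.id = f"c{k}"
        cl.classification = (
            CLASS_SUBMINIMAL if cl.size < cfg.min_coordinators else cl.classification
        )
    return clusters


def augment_cluster(
    cl: CandidateCluster,
    s: StructureModel,
    profile: ConservationProfile,
    cfg: SearchConfig | None = None,
) -> CandidateCluster:
    """Add conserved Asp/Glu/Ser near a cluster that lacks four coordinators.

    Every conserved auxiliary residue within ``d_aux`` Å of a member's donor
    atoms, or within ``seq_adjacency`` in sequence of a member, is added.
    Clusters that already have at least ``min_coordinators`` members are
    returned unchanged.
    """
    cfg = cfg or SearchConfig()
    if cl.size >= cfg.min_coordinators:
        return cl
    members = list(cl.members)
    taken = {m.position for m in members}
    aux = []
    for pos, aa in conserved_residues(profile, AUXILIARY_AA, cfg.min_grade):
        if pos in taken or pos not in s or s.aa(pos) != aa:
            continue
        near = any(
            abs(pos - m.position) <= cfg.seq_adjacency
            or min_functional_distance(s, pos, m.position) <= cfg.d_aux
            for m in members
        )
        if near:
            aux.append(CandidateResidue(pos, aa, "auxiliary", profile.grade(pos)))
    new = replace(
        cl,
        members=sorted(members + aux, key=lambda m: m.position),
    )
    new.classification = (
        CLASS_SUBMINIMAL if new.size < cfg.min_coordinators else new.classification
    )
    return new


def detect_znc4(
    s: StructureModel,
    profile: ConservationProfile | None = None,
    cfg: SearchConfig | None = None,
) -> list[CandidateCluster]:
    """Crossing disulfide-bridge pairs reported as candidate ZnC4 redox switches.

    Two bridges form a candidate when all four SG atoms are mutually within
    ``cfg.d_pair`` Å — the geometry that could collapse onto a tetrahedral
    four-cysteine zinc site under reducing conditions.
    """
    cfg = cfg or SearchConfig()
    bridges = detect_disulfides(s)
    clusters = []
    for i in range(len(bridges)):
        for j in range(i + 1, len(bridges)):
            quad = sorted(bridges[i] + bridges[j])
            close = all(
                min_functional_distance(s, a, b) <= cfg.d_pair
                for x, a in enumerate(quad)
                for b in quad[x + 1 :]
            )
            if close:
                members = [
                    CandidateResidue(
                        p, "C", "primary",
                        profile.grade(p) if profile is not None and p <= len(profile.ref_seq) else 9,
                    )
                    for p in quad
                ]
                clusters.append(
                    CandidateCluster(
                        id="",
                        members=members,
                        classification=CLASS_REDOX,
                        from_znc4=True,
                    )
                )
    clusters.sort(key=lambda c: c.min_position)
    return clusters


def classify_cluster(
    cl: CandidateCluster, s: StructureModel, cfg: SearchConfig | None = None
) -> str:
    """Structural-like / catalytic-like / redox-switch-like / sub-minimal.

    Redox-switch candidates keep their label.  Otherwise: fewer than the
    minimum coordination number → sub-minimal; at least three His/Cys members
    and mean burial at or above the buried threshold → structural-like (the
    buried, H/C-dominated archetype); any other mixed or exposed arrangement
    → catalytic-like.
    """
    cfg = cfg or SearchConfig()
    if not cl.members:
        raise ValueError("cannot classify an empty cluster")
    if cl.from_znc4 and all(m.aa == "C" for m in cl.members):
        return CLASS_REDOX
    if cl.size < cfg.min_coordinators:
        return CLASS_SUBMINIMAL
    n_hc = sum(1 for m in cl.members if m.aa in PRIMARY_AA)
    mean_burial = float(
        np.mean([burial_score(s, m.position, cfg.burial_radius) for m in cl.members])
    )
    if n_hc >= 3 and mean_burial >= cfg.buried_neighbors:
        return CLASS_STRUCTURAL
    return CLASS_CATALYTIC


def assign_domain(cl: CandidateCluster, s: StructureModel) -> str:
    """Domain label containing the majority of members; ties break to the
    domain of the lowest-numbered member; members outside every window count
    toward "unassigned"."""
    votes: dict[str, list[int]] = {}
    for m in cl.sorted_members():
        label = "unassigned"
        for name, (start, end) in s.domain_boundaries.items():
            if start <= m.position <= end:
                label = name
                break
        votes.setdefault(label, []).append(m.position)
    best = max(votes.items(), key=lambda kv: (len(kv[1]), -min(kv[1])))
    return best[0]


def _abbreviate(domain: str) -> str:
    words = domain.replace("-", " ").replace("_", " ").split()
    if not words or domain == "unassigned":
        return "un"
    return "".join(w[0].lower() for w in words[:2])


def search_clusters(
    s: StructureModel,
    profile: ConservationProfile,
    cfg: SearchConfig | None = None,
) -> list[CandidateCluster]:
    """Run the full search: seed, group, augment, add ZnC4, classify, name."""
    cfg = cfg or SearchConfig()
    primaries = find_primary_candidates(s, profile, cfg)
    clusters = build_clusters(primaries, s, cfg)
    clusters = [augment_cluster(cl, s, profile, cfg) for cl in clusters]
    covered = [cl.positions for cl in clusters]
    for znc4 in detect_znc4(s, profile, cfg):
        overlap = [i for i, pos in enumerate(covered) if pos & znc4.positions]
        if overlap:
            # An existing cluster already holds (some of) these cysteines:
            # flag it rather than duplicating members.
            i = overlap[0]
            if znc4.positions <= clusters[i].positions:
                clusters[i].from_znc4 = True
        else:
            clusters.append(znc4)
            covered.append(znc4.positions)
    clusters.sort(key=lambda c: c.min_position)
    for cl in clusters:
        cl.classification = classify_cluster(cl, s, cfg)
        cl.domain = assign_domain(cl, s)
    counters: dict[str, int] = {}
    for cl in clusters:
        abbr = _abbreviate(cl.domain)
        counters[abbr] = counters.get(abbr, 0) + 1
        cl.id = f"{abbr}.{counters[abbr]}"
    return clusters


def clusters_to_frame(clusters: list[CandidateCluster]) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        rows.append(
            {
                "id": cl.id,
                "domain": cl.domain,
                "classification": cl.classification,
                "size": cl.size,
                "members": ";".join(
                    f"{m.aa}{m.position}" for m in cl.sorted_members()
                ),
                "roles": ";".join(m.role for m in cl.sorted_members()),
                "grades": ";".join(
                    str(m.conservation_grade) for m in cl.sorted_members()
                ),
                "contrast": cl.contrast,
            }
        )
    return pd.DataFrame(rows)


def clusters_to_json(clusters: list[CandidateCluster], path: str | Path) -> None:
    payload = [
        {
            "id": cl.id,
            "domain": cl.domain,
            "classification": cl.classification,
            "contrast": cl.contrast,
            "members": [
                {
                    "position": m.position,
                    "aa": m.aa,
                    "role": m.role,
                    "grade": m.conservation_grade,
                }
                for m in cl.sorted_members()
            ],
        }
        for cl in clusters
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
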