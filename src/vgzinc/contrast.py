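"""Hydrophobic contrast of candidate clusters.

Productive metal sites juxtapose a polar inner coordination shell against a
hydrophobic outer shell.  The statistic computed here is the difference of
mean Eisenberg consensus hydrophobicities between an outer and an inner
spherical shell centred on the cluster's donor-atom centroid:

    delta = mean(outer shell) - mean(inner shell)

so a positive delta is the favourable contrast (hydrophobic exterior around
a polar core).  Shell membership is by residue: each residue joins the shell
of its nearest qualifying atom (donor atoms where present, else CB/CA), and
is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .cluster_search import CandidateCluster
from .structure import StructureModel


def load_eisenberg_scale() -> dict[str, float]:
    """The packaged Eisenberg normalized consensus scale."""
    scale: dict[str, float] = {}
    text = resources.files("vgzinc.data").joinpath("eisenberg.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        aa, value = line.split("\t")
        scale[aa] = float(value)
    return scale


@dataclass
class ContrastScore:
    cluster_id: str
    inner_mean: float | None
    outer_mean: float | None
    delta: float | None
    inner_n: int
    outer_n: int

    @property
    def undefined(self) -> bool:
        return self.delta is None


def cluster_contrast(
    cl: CandidateCluster,
    s: StructureModel,
    scale: dict[str, float] | None = None,
    r_inner: float = 5.0,
    r_outer: float = 10.0,
) -> ContrastScore:
    """Shell-mean hydrophobicity difference around a cluster centroid.

    The centroid is the mean of all member donor-atom coordinates.  Residues
    whose nearest qualifying atom lies within ``r_inner`` form the inner
    shell; those in (``r_inner``, ``r_outer``] form the outer shell.  An
    empty outer shell leaves the contrast undefined (``delta`` is None).
    """
    if r_inner >= r_outer:
        raise ValueError("r_inner must be smaller than r_outer")
    if not cl.members:
        raise ValueError("cannot score an empty cluster")
    scale = scale if scale is not None else load_eisenberg_scale()
    member_coords = np.vstack(
        [s.residue(m.position).functional_coords() for m in cl.members]
    )
    centroid = member_coords.mean(axis=0)
    inner: list[float] = []
    outer: list[float] = []
    for n in s.residue_numbers:
        res = s.residues[n]
        coords = [res.functional_coords()]
        anchor = res.burial_anchor()
        if anchor is not None:
            coords.append(anchor[None, :])
        allc = np.vstack(coords)
        d = float(np.sqrt(((allc - centroid) ** 2).sum(axis=1)).min())
        value = scale.get(res.aa)
        if value is None:
            continue
        if d <= r_inner:
            inner.append(value)
        elif d <= r_outer:
            outer.append(value)
    inner_mean = float(np.mean(inner)) if inner else None
    outer_mean = float(np.mean(outer)) if outer else None
    delta = (
        outer_mean - inner_mean
        if inner_mean is not None and outer_mean is not None
        else None
    )
    return ContrastScore(
        cluster_id=cl.id,
        inner_mean=inner_mean,
        outer_mean=outer_mean,
        delta=delta,
        inner_n=len(inner),
        outer_n=len(outer),
    )


def score_clusters(
    clusters: list[CandidateCluster],
    s: StructureModel,
    scale: dict[str, float] | None = None,
    r_inner: float = 5.0,
    r_outer: float = 10.0,
) -> list[ContrastScore]:
    """Score every cluster and write the delta back onto it."""
    scale = scale if scale is not None else load_eisenberg_scale()
    out = []
    for cl in clusters:
        cs = cluster_contrast(cl, s, scale, r_inner, r_outer)
        cl.contrast = cs.delta
        out.append(cs)
    return out
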