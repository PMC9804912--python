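"""Cluster seeding, proximity grouping, augmentation, ZnC4, classification."""

import itertools

import numpy as np
import pytest

from conftest import build_model
from vgzinc.cluster_search import (
    CLASS_CATALYTIC,
    CLASS_REDOX,
    CLASS_STRUCTURAL,
    CLASS_SUBMINIMAL,
    CandidateCluster,
    CandidateResidue,
    SearchConfig,
    assign_domain,
    augment_cluster,
    build_clusters,
    classify_cluster,
    detect_znc4,
    find_primary_candidates,
    search_clusters,
)
from vgzinc.conservation import ConservationProfile
from vgzinc.errors import AlignmentMismatchError
from vgzinc.structure import min_functional_distance
from vgzinc.synthetic import score_recovery


def profile_for(sequence: str, grades: dict[int, int]) -> ConservationProfile:
    """A profile over ``sequence`` with explicit grades (default 1)."""
    g = np.array([grades.get(i + 1, 1) for i in range(len(sequence))])
    return ConservationProfile(
        ref_id="REF",
        ref_seq=sequence,
        scores=g / 9.0,
        grades=g,
        gap_fraction=np.zeros(len(sequence)),
    )


def brute_force_components(positions, structure, d_pair):
    """Independent oracle: BFS over the all-pairs adjacency matrix."""
    adj = {
        p: {
            q
            for q in positions
            if q != p and min_functional_distance(structure, p, q) <= d_pair
        }
        for p in positions
    }
    seen, comps = set(), []
    for p in positions:
        if p in seen:
            continue
        comp, queue = set(), [p]
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestFindPrimaryCandidates:
    def test_planted_seeds_only(self, planted_scene):
        structure, profile, truth = planted_scene
        cands = find_primary_candidates(structure, profile)
        expected_hc = {
            p for p in set().union(*truth.planted_sites)
            if structure.aa(p) in "HC"
        }
        assert {c.position for c in cands} == expected_hc
        assert all(c.role == "primary" for c in cands)

    def test_min_grade_one_returns_every_hc(self, planted_scene):
        structure, profile, _ = planted_scene
        cands = find_primary_candidates(
            structure, profile, SearchConfig(min_grade=1)
        )
        every_hc = {
            n for n in structure.residue_numbers if structure.aa(n) in "HC"
        }
        assert {c.position for c in cands} == every_hc

    def test_no_hc_structure(self):
        s = build_model([(1, "A", {"CA": (0, 0, 0)})])
        profile = profile_for("A", {})
        assert find_primary_candidates(s, profile) == []

    def test_numbering_mismatch_detected(self, planted_scene):
        structure, profile, _ = planted_scene
        shuffled = profile_for("W" * len(profile.ref_seq), {})
        with pytest.raises(AlignmentMismatchError):
            find_primary_candidates(structure, shuffled)


class TestBuildClusters:
    def geom(self, coords, aa="H"):
        atom = {"H": "NE2", "C": "SG"}[aa]
        return build_model(
            [(i + 1, aa, {atom: c, "CA": c}) for i, c in enumerate(coords)]
        )

    def cands(self, structure):
        return [
            CandidateResidue(n, structure.aa(n), "primary", 9)
            for n in structure.residue_numbers
        ]

    def test_tight_quad_is_one_cluster(self):
        s = self.geom([(0, 0, 0), (4, 0, 0), (0, 4, 0), (4, 4, 0)])
        out = build_clusters(self.cands(s), s)
        assert len(out) == 1 and out[0].size == 4

    def test_far_apart_all_singletons(self):
        s = self.geom([(0, 0, 0), (25, 0, 0), (50, 0, 0)])
        out = build_clusters(self.cands(s), s)
        assert [c.size for c in out] == [1, 1, 1]
        assert all(c.classification == CLASS_SUBMINIMAL for c in out)

    def test_two_planted_tetrads(self, planted_scene):
        structure, profile, truth = planted_scene
        cands = find_primary_candidates(structure, profile)
        # restrict to the all-H/C site for a pure-primary check
        out = build_clusters(cands, structure)
        quads = [c for c in out if c.size == 4]
        assert frozenset(quads[0].positions) in set(truth.planted_sites)

    def test_empty_candidates(self, planted_scene):
        structure, _, _ = planted_scene
        assert build_clusters([], structure) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 30, size=(20, 3))
        s = self.geom([tuple(c) for c in coords])
        cands = self.cands(s)
        for d_pair in (4.0, 8.0, 12.0):
            out = build_clusters(cands, s, SearchConfig(d_pair=d_pair))
            got = {frozenset(c.positions) for c in out}
            want = brute_force_components(
                list(range(1, 21)), s, d_pair
            )
            assert got == want

    def test_monotone_in_d_pair(self):
        rng = np.random.default_rng(3)
        s = self.geom([tuple(c) for c in rng.uniform(0, 40, size=(15, 3))])
        cands = self.cands(s)
        counts = [
            len(build_clusters(cands, s, SearchConfig(d_pair=d)))
            for d in (4.0, 6.0, 8.0, 10.0, 12.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self, planted_scene):
        structure, profile, _ = planted_scene
        cands = find_primary_candidates(structure, profile)
        a = build_clusters(cands, structure)
        b = build_clusters(cands, structure)
        assert [(c.id, sorted(c.positions)) for c in a] == [
            (c.id, sorted(c.positions)) for c in b
        ]


class TestAugmentCluster:
    def scene(self):
        """Three His near the origin, one conserved Asp and Glu within reach,
        and an unconserved Ser decoy also within reach."""
        s = build_model(
            [
                (20, "H", {"NE2": (0, 0, 0), "CA": (0, 0, 0)}),
                (113, "H", {"NE2": (4, 0, 0), "CA": (4, 0, 0)}),
                (265, "H", {"NE2": (0, 4, 0), "CA": (0, 4, 0)}),
                (143, "D", {"OD1": (2, 2, 3), "CA": (2, 2, 3)}),
                (147, "E", {"OE1": (2, 2, -3), "CA": (2, 2, -3)}),
                (150, "S", {"OG": (3, 3, 0), "CA": (3, 3, 0)}),
            ]
        )
        seq = ["A"] * 265
        for n in (20, 113, 265):
            seq[n - 1] = "H"
        seq[142], seq[146], seq[149] = "D", "E", "S"
        profile = profile_for(
            "".join(seq), {20: 9, 113: 9, 265: 9, 143: 8, 147: 8, 150: 2}
        )
        return s, profile

    def test_adds_all_qualifying_auxiliaries(self):
        s, profile = self.scene()
        cl = CandidateCluster(
            id="c1",
            members=[CandidateResidue(p, "H", "primary", 9) for p in (20, 113, 265)],
        )
        out = augment_cluster(cl, s, profile)
        assert out.positions == {20, 113, 143, 147, 265}
        roles = {m.position: m.role for m in out.members}
        assert roles[143] == roles[147] == "auxiliary"

    def test_cluster_already_complete_unchanged(self):
        s, profile = self.scene()
        cl = CandidateCluster(
            id="c1",
            members=[
                CandidateResidue(p, "H", "primary", 9)
                for p in (20, 113, 265)
            ]
            + [CandidateResidue(143, "D", "auxiliary", 8)],
        )
        out = augment_cluster(cl, s, profile)
        assert out.positions == {20, 113, 143, 265}

    def test_pair_with_no_auxiliaries_stays_subminimal(self):
        s = build_model(
            [
                (1, "H", {"NE2": (0, 0, 0), "CA": (0, 0, 0)}),
                (2, "C", {"SG": (3, 0, 0), "CA": (3, 0, 0)}),
            ]
        )
        profile = profile_for("HC", {1: 9, 2: 9})
        cl = CandidateCluster(
            id="c1",
            members=[
                CandidateResidue(1, "H", "primary", 9),
                CandidateResidue(2, "C", "primary", 9),
            ],
        )
        out = augment_cluster(cl, s, profile)
        assert out.positions == {1, 2}
        assert out.classification == CLASS_SUBMINIMAL

    def test_sequence_adjacency_route(self):
        # auxiliary 30 Å away in space but adjacent in sequence
        s = build_model(
            [
                (10, "H", {"NE2": (0, 0, 0), "CA": (0, 0, 0)}),
                (11, "D", {"OD1": (30, 0, 0), "CA": (30, 0, 0)}),
            ]
        )
        seq = ["A"] * 11
        seq[9], seq[10] = "H", "D"
        profile = profile_for("".join(seq), {10: 9, 11: 9})
        cl = CandidateCluster(
            id="c1", members=[CandidateResidue(10, "H", "primary", 9)]
        )
        out = augment_cluster(cl, s, profile)
        assert 11 in out.positions


class TestDetectZnc4:
    def crossing_bridges(self, gap=4.0):
        # two disulfide bridges whose four SG atoms are mutually close
        return build_model(
            [
                (1, "C", {"SG": (0, 0, 0)}),
                (2, "C", {"SG": (2.05, 0, 0)}),
                (3, "C", {"SG": (0, gap, 0)}),
                (4, "C", {"SG": (2.05, gap, 0)}),
            ]
        )

    def test_crossing_bridges_found(self):
        out = detect_znc4(self.crossing_bridges())
        assert len(out) == 1
        assert out[0].positions == {1, 2, 3, 4}
        assert out[0].classification == CLASS_REDOX

    def test_distant_bridges_ignored(self):
        out = detect_znc4(self.crossing_bridges(gap=40.0))
        assert out == []

    def test_classification_preserved_through_classify(self):
        s = self.crossing_bridges()
        cl = detect_znc4(s)[0]
        assert classify_cluster(cl, s) == CLASS_REDOX


class TestClassifyCluster:
    def buried_tetrad(self):
        """An H/H/H/D tetrad wrapped in enough lattice residues to be buried."""
        residues = [
            (1, "H", {"NE2": (0, 0, 0), "CA": (0, 0, 0), "CB": (0, 0, 0)}),
            (2, "H", {"NE2": (3, 0, 0), "CA": (3, 0, 0), "CB": (3, 0, 0)}),
            (3, "H", {"NE2": (0, 3, 0), "CA": (0, 3, 0), "CB": (0, 3, 0)}),
            (4, "D", {"OD1": (3, 3, 0), "CA": (3, 3, 0), "CB": (3, 3, 0)}),
        ]
        num = 5
        for x in range(-1, 3):
            for y in range(-1, 3):
                for z in (-4, 4):
                    residues.append(
                        (num, "A", {"CB": (4.0 * x, 4.0 * y, float(z))})
                    )
                    num += 1
        return build_model(residues)

    def test_buried_hhd_tetrad_structural(self):
        s = self.buried_tetrad()
        cl = CandidateCluster(
            id="x",
            members=[
                CandidateResidue(1, "H", "primary", 9),
                CandidateResidue(2, "H", "primary", 9),
                CandidateResidue(3, "H", "primary", 9),
                CandidateResidue(4, "D", "auxiliary", 9),
            ],
        )
        assert classify_cluster(cl, s) == CLASS_STRUCTURAL

    def test_exposed_mixed_catalytic(self):
        s = build_model(
            [
                (1, "H", {"NE2": (0, 0, 0), "CB": (0, 0, 0)}),
                (2, "E", {"OE1": (3, 0, 0), "CB": (3, 0, 0)}),
                (3, "S", {"OG": (0, 3, 0), "CB": (0, 3, 0)}),
                (4, "D", {"OD1": (3, 3, 0), "CB": (3, 3, 0)}),
            ]
        )
        cl = CandidateCluster(
            id="x",
            members=[
                CandidateResidue(1, "H", "primary", 9),
                CandidateResidue(2, "E", "auxiliary", 9),
                CandidateResidue(3, "S", "auxiliary", 9),
                CandidateResidue(4, "D", "auxiliary", 9),
            ],
        )
        assert classify_cluster(cl, s) == CLASS_CATALYTIC


class TestAssignDomain:
    def test_majority_and_tie_break(self, planted_scene):
        import dataclasses

        base, _, truth = planted_scene
        structure = dataclasses.replace(
            base,
            domain_boundaries={"beta barrel": (1, 4), "alpha helical": (5, 60)},
        )
        cl = CandidateCluster(
            id="x",
            members=[
                CandidateResidue(p, structure.aa(p), "primary", 9)
                for p in sorted(truth.planted_sites[0])
            ],
        )
        assert assign_domain(cl, structure) == "beta barrel"
        mixed = CandidateCluster(
            id="y",
            members=[
                CandidateResidue(3, structure.aa(3), "primary", 9),
                CandidateResidue(4, structure.aa(4), "primary", 9),
                CandidateResidue(5, structure.aa(5), "primary", 9),
                CandidateResidue(6, structure.aa(6), "primary", 9),
            ],
        )
        # 2-2 tie: domain of the lowest member wins
        assert assign_domain(mixed, structure) == "beta barrel"

    def test_unassigned_outside_windows(self, planted_scene):
        import dataclasses

        base, _, _ = planted_scene
        structure = dataclasses.replace(base, domain_boundaries={"core": (55, 60)})
        cl = CandidateCluster(
            id="z", members=[CandidateResidue(1, structure.aa(1), "primary", 9)]
        )
        label = assign_domain(cl, structure)
        assert label == "unassigned"


class TestSearchClusters:
    def test_planted_recovery_default_config(self, planted_scene):
        structure, profile, truth = planted_scene
        clusters = search_clusters(structure, profile)
        precision, recall = score_recovery(clusters, truth)
        assert precision == 1.0 and recall == 1.0

    def test_member_types_are_conserved_hcdes_only(self, planted_scene):
        structure, profile, _ = planted_scene
        for cl in search_clusters(structure, profile):
            for m in cl.members:
                assert m.aa in "HCDES"
                assert m.conservation_grade >= SearchConfig().min_grade
                assert (m.role == "primary") == (m.aa in "HC")
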