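"""Mapping scores: per-residue distances, additional/neighbor matching, selection."""

from itertools import permutations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from siteseek.candidate_search import AnchorMapping
from siteseek.scoring import (
    MappedResidue,
    combine_score,
    match_additional,
    match_neighbors,
    residue_distance,
    score_mapping,
    select_best,
)
from siteseek.seed_model import build_seed_site
from siteseek.structure_io import Residue, StructureModel
from siteseek.superposition import RigidTransform
from siteseek import fixtures

from conftest import make_model


IDENTITY = RigidTransform.identity()


class TestResidueDistance:
    def test_identical_residues_zero(self):
        r = Residue(1, "SER", (0, 0, 0), (0, 0, 1.5))
        assert residue_distance(r, r, IDENTITY) == 0.0

    def test_mean_of_ca_and_cb_distances(self):
        a = Residue(1, "SER", (0, 0, 0), (0, 0, 1.5))
        b = Residue(2, "SER", (1.0, 0, 0), (2.0, 0, 1.5))
        assert residue_distance(a, b, IDENTITY) == pytest.approx(1.5)

    def test_glycine_falls_back_to_ca(self):
        a = Residue(1, "GLY", (0, 0, 0), None)
        b = Residue(2, "SER", (0.7, 0, 0), (5.0, 5.0, 5.0))
        assert residue_distance(a, b, IDENTITY) == pytest.approx(0.7)


class TestCombineScore:
    def test_three_anchor_worked_case(self):
        assert combine_score([0.3, 0.6, 0.9]) == pytest.approx(0.2, abs=1e-12)

    def test_matched_additional_lowers_score(self):
        assert combine_score([0.3, 0.6, 0.9, 0.6]) == pytest.approx(0.15, abs=1e-12)

    def test_sum_over_n_variant_is_plain_mean(self):
        assert combine_score([0.3, 0.6, 0.9], formula="sum_over_n") == pytest.approx(0.6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_score([])


def site_with_additional(extra_types=("TRP",), subs=None):
    """Seed with SER/ASP/HIS anchors and additional residues on a plane."""
    entries = [
        (10, "SER", (0.0, 0.0, 0.0), (0.0, 0.0, 1.5)),
        (20, "ASP", (8.0, 0.0, 0.0), (8.0, 0.0, 1.5)),
        (30, "HIS", (0.0, 6.0, 0.0), (0.0, 6.0, 1.5)),
    ]
    extra_positions = []
    for k, aa3 in enumerate(extra_types):
        pos = 40 + 10 * k
        entries.append((pos, aa3, (4.0 + k, 3.0, 0.0), (4.0 + k, 3.0, 1.5)))
        extra_positions.append(pos)
    seed = make_model(entries, id="seed")
    return seed, build_seed_site(
        seed, [10, 20, 30], additional_positions=extra_positions, substitutions=subs or []
    )


class TestMatchAdditional:
    def test_nearby_allowed_type_included(self):
        seed, site = site_with_additional(("TRP",))
        query = make_model(
            [(1, "TRP", (4.0, 3.4, 0.0), (4.0, 3.4, 1.5))], id="q"
        )
        matched = match_additional(query, site, IDENTITY)
        assert len(matched) == 1
        assert matched[0].query_position == 1
        assert matched[0].distance == pytest.approx(0.4)

    def test_no_allowed_type_within_radius_excluded(self):
        seed, site = site_with_additional(("TRP",))
        query = make_model(
            [(1, "TRP", (9.0, 9.0, 0.0), (9.0, 9.0, 1.5)),  # too far
             (2, "ALA", (4.0, 3.1, 0.0), (4.0, 3.1, 1.5))], id="q"  # wrong type
        )
        assert match_additional(query, site, IDENTITY) == []

    def test_competition_resolved_greedily_matches_brute_force(self):
        # two seed additionals at 4,3 and 5,3; one query TRP between them plus
        # a farther TRP: closer pair wins, loser takes the next candidate
        seed, site = site_with_additional(("TRP", "TRP"))
        query = make_model(
            [(1, "TRP", (4.1, 3.0, 0.0), (4.1, 3.0, 1.5)),
             (2, "TRP", (5.8, 3.0, 0.0), (5.8, 3.0, 1.5))], id="q"
        )
        matched = match_additional(query, site, IDENTITY)
        got = {(m.seed_position, m.query_position) for m in matched}
        # brute-force optimal one-to-one assignment by total distance
        def dist(spos, qpos):
            return residue_distance(
                seed.residue_at(spos), query.residue_at(qpos), IDENTITY
            )

        best, best_total = None, np.inf
        for perm in permutations([1, 2]):
            pairs = [
                (s, q) for s, q in zip([40, 50], perm) if dist(s, q) < 2.0
            ]
            total = sum(dist(s, q) for s, q in pairs) - 10 * len(pairs)
            if total < best_total:
                best, best_total = set(pairs), total
        assert got == best

    def test_anchor_positions_excluded_from_candidates(self):
        seed, site = site_with_additional(("SER",))
        # the only query SER is the one used as an anchor
        query = make_model(
            [(1, "SER", (4.0, 3.0, 0.0), (4.0, 3.0, 1.5))], id="q"
        )
        assert match_additional(query, site, IDENTITY, exclude_positions=[1]) == []


class TestMatchNeighbors:
    def make_pair(self, seed_len=9, query_len=9, query_offset=100):
        seed = make_model(
            [(i + 1, "ALA", (3.8 * i, 0.0, 0.0), None) for i in range(seed_len)],
            id="seed",
        )
        site = build_seed_site(seed, [1, 5, 9] if seed_len >= 9 else [1, 2, 3])
        query = make_model(
            [(query_offset + i + 1, "ALA", (3.8 * i, 0.5, 0.0), None)
             for i in range(query_len)],
            id="q",
        )
        return seed, site, query

    def test_window_zero_is_empty(self):
        seed, site, query = self.make_pair()
        core = [MappedResidue(5, 105, 0.5, "anchor")]
        assert match_neighbors(query, site, core, IDENTITY, w=0) == []

    def test_window_one_gives_two_pairs(self):
        seed, site, query = self.make_pair()
        core = [MappedResidue(5, 105, 0.5, "anchor")]
        got = match_neighbors(query, site, core, IDENTITY, w=1)
        assert {(m.seed_position, m.query_position) for m in got} == {
            (4, 104), (6, 106)
        }
        assert all(m.kind == "neighbor" for m in got)

    def test_window_truncated_at_termini(self):
        seed, site, query = self.make_pair()
        core = [MappedResidue(1, 101, 0.5, "anchor")]
        got = match_neighbors(query, site, core, IDENTITY, w=4)
        assert {m.seed_position for m in got} == {2, 3, 4, 5}

    def test_overlapping_windows_counted_once(self):
        seed, site, query = self.make_pair()
        core = [
            MappedResidue(4, 104, 0.5, "anchor"),
            MappedResidue(5, 105, 0.5, "additional"),
        ]
        got = match_neighbors(query, site, core, IDENTITY, w=2)
        pairs = [(m.seed_position, m.query_position) for m in got]
        assert len(pairs) == len(set(pairs))
        # (6,106) reachable from both cores, present once; cores not repeated
        assert (6, 106) in pairs
        assert (4, 104) not in pairs and (5, 105) not in pairs

    def test_types_ignored(self):
        seed, site, query = self.make_pair()
        query = make_model(
            [(101 + i, "TRP", (3.8 * i, 0.5, 0.0), None) for i in range(9)],
            id="q",
        )
        core = [MappedResidue(5, 105, 0.5, "anchor")]
        assert len(match_neighbors(query, site, core, IDENTITY, w=1)) == 2


class TestScoreMapping:
    def test_seed_against_itself_scores_zero(self, planted_seed):
        model, site, positions = planted_seed
        scored = score_mapping(model, site, AnchorMapping(positions))
        assert scored.score == pytest.approx(0.0, abs=1e-9)
        assert scored.n_mapped >= 3
        assert all(m.distance <= 1e-9 for m in scored.mapped)

    def test_score_matches_formula(self, planted_seed):
        model, site, positions = planted_seed
        spec = fixtures.FixtureSpec(
            n_residues=60,
            planted_site=fixtures.PlantedSite(("SER", "ASP", "HIS"), (9.3, 6.8, 6.2), 0.4),
            rng_seed=5,
        )
        query, qpos = fixtures.make_fixture(spec, id="q")
        scored = score_mapping(query, site, AnchorMapping(qpos))
        mean_d = np.mean([m.distance for m in scored.mapped])
        assert scored.score == pytest.approx(mean_d / scored.n_mapped, abs=1e-9)
        assert scored.n_mapped == len(scored.mapped)

    def test_score_non_negative_and_anchors_always_counted(self, planted_seed):
        model, site, positions = planted_seed
        scored = score_mapping(model, site, AnchorMapping(positions), neighbor_window=0)
        assert scored.score >= 0
        kinds = [m.kind for m in scored.mapped]
        assert kinds.count("anchor") == 3

    def test_rigid_motion_invariance(self, planted_seed):
        model, site, positions = planted_seed
        scored = score_mapping(model, site, AnchorMapping(positions))
        rng = np.random.default_rng(9)
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-10, 10, 3)
        moved = StructureModel(
            id="moved",
            residues=[
                Residue(
                    r.position, r.aa3, rot @ r.ca + shift,
                    None if r.cb is None else rot @ r.cb + shift,
                )
                for r in model.residues
            ],
        )
        scored2 = score_mapping(moved, site, AnchorMapping(positions))
        assert scored2.score == pytest.approx(scored.score, abs=1e-6)


class TestSelectBest:
    def mk(self, score, qpos=(1, 2, 3)):
        from siteseek.scoring import ScoredMapping

        return ScoredMapping(AnchorMapping(qpos), IDENTITY, [], 3, score)

    def test_lowest_below_threshold_selected(self):
        best = select_best([self.mk(0.4), self.mk(0.9)], threshold=1.0)
        assert best.score == 0.4

    def test_none_when_all_above_threshold(self):
        assert select_best([self.mk(1.2), self.mk(3.0)], threshold=1.0) is None

    def test_threshold_is_strict(self):
        assert select_best([self.mk(1.0)], threshold=1.0) is None

    def test_empty_list_gives_none(self):
        assert select_best([], threshold=1.0) is None

    def test_ties_broken_by_query_positions(self):
        a = self.mk(0.5, qpos=(4, 5, 6))
        b = self.mk(0.5, qpos=(1, 9, 9))
        assert select_best([a, b]).mapping.query_positions == (1, 9, 9)
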