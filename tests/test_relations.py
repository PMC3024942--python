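"""Relation typing, symmetry, and contradiction signals."""

import pytest

from orthopair.blast_io import BlastHit, HitIndex
from orthopair.errors import UnknownAccessionError
from orthopair.inparalog_core import ValidatedGroup, build_validated_groups
from orthopair.relations import (
    MANY_TO_MANY,
    ONE_TO_MANY,
    ONE_TO_ONE,
    best_cross_hits,
    detect_pair_relations,
    flag_contradictions,
)

ACC_ORG = {
    "A1": "a", "A2": "a", "A3": "a",
    "B1": "b", "B2": "b", "B9": "b",
    "C1": "c",
}


def _index(rows, acc_org=None):
    return HitIndex(
        [BlastHit(q, s, e, b) for q, s, e, b in rows],
        acc_org or ACC_ORG,
    )


class TestBestCrossHits:
    def test_top_ranked_subject(self):
        index = _index([("A1", "B1", 1e-50, 100.0), ("A1", "B2", 1e-30, 100.0)])
        assert best_cross_hits("A1", "b", index) == {"B1"}

    def test_no_hits_in_target(self):
        index = _index([("A1", "B1", 1e-50, 100.0)])
        assert best_cross_hits("A1", "c", index) == frozenset()

    def test_tie_surfacing_returns_all_co_ranked(self):
        rows = [("A1", "B1", 0.0, 900.0), ("A1", "B2", 0.0, 900.0),
                ("A1", "B9", 0.0, 500.0)]
        index = _index(rows)
        assert best_cross_hits("A1", "b", index) == {"B1"}
        assert best_cross_hits("A1", "b", index, surface_ties=True) == {"B1", "B2"}
        # independent oracle: exhaustive scan of the co-ranked top
        hits = index.hits_in("A1", "b")
        top = min((h.evalue, -h.bitscore) for h in hits)
        expected = {h.subject_acc for h in hits if (h.evalue, -h.bitscore) == top}
        assert best_cross_hits("A1", "b", index, surface_ties=True) == expected

    def test_unknown_protein_rejected(self):
        with pytest.raises(UnknownAccessionError):
            best_cross_hits("ZZ", "b", _index([("A1", "B1", 1e-9, 10.0)]))


def _pipeline(rows, acc_org=None):
    index = _index(rows, acc_org)
    groups = build_validated_groups(index)
    return index, groups


class TestDetectPairRelations:
    def test_mutual_best_hits_give_one_to_one(self):
        index, groups = _pipeline(
            [("A1", "B1", 1e-50, 100.0), ("B1", "A1", 1e-50, 100.0)]
        )
        (rel,) = detect_pair_relations("a", "b", groups, index)
        assert rel.type == ONE_TO_ONE
        assert rel.side_a.members == {"A1"}
        assert rel.side_b.members == {"B1"}
        # every 1-to-1 is an RBH, checkable directly against the index
        assert best_cross_hits("A1", "b", index) == {"B1"}
        assert best_cross_hits("B1", "a", index) == {"A1"}

    def test_one_sided_best_hit_is_not_a_relation(self):
        # A1's best hit is B1, but B1's best hit is A2 (which never hits back)
        index, groups = _pipeline(
            [("A1", "B1", 1e-50, 100.0), ("B1", "A2", 1e-60, 100.0),
             ("B1", "A1", 1e-50, 100.0)]
        )
        assert detect_pair_relations("a", "b", groups, index) == []

    def _group_vs_singleton(self):
        # A1,A2 form a validated group w.r.t. b; B1 is the partner singleton
        rows = [
            ("A1", "A2", 1e-80, 100.0), ("A1", "B1", 1e-50, 100.0),
            ("A2", "A1", 1e-80, 100.0), ("A2", "B1", 1e-50, 100.0),
            ("B1", "A1", 1e-50, 100.0),
        ]
        return _pipeline(rows)

    def test_group_vs_singleton_gives_one_to_many(self):
        index, groups = self._group_vs_singleton()
        (rel,) = detect_pair_relations("a", "b", groups, index)
        assert rel.type == ONE_TO_MANY
        assert rel.side_a.members == {"A1", "A2"}
        assert rel.side_b.members == {"B1"}

    def test_two_groups_linked_by_one_hit_each_way(self):
        rows = [
            # validated group {A1,A2} w.r.t. b
            ("A1", "A2", 1e-80, 100.0), ("A1", "B1", 1e-50, 100.0),
            ("A2", "A1", 1e-80, 100.0), ("A2", "B2", 1e-50, 100.0),
            # validated group {B1,B2} w.r.t. a
            ("B1", "B2", 1e-80, 100.0), ("B1", "A9", 1e-50, 100.0),
            ("B2", "B1", 1e-80, 100.0), ("B2", "A2", 1e-50, 100.0),
        ]
        acc_org = {"A1": "a", "A2": "a", "A9": "a", "B1": "b", "B2": "b"}
        index, groups = _pipeline(rows, acc_org)
        rels = detect_pair_relations("a", "b", groups, index)
        (mm,) = [r for r in rels if r.type == MANY_TO_MANY]
        assert mm.side_a.members == {"A1", "A2"}
        assert mm.side_b.members == {"B1", "B2"}
        # independent check of the two existential conditions
        assert any(
            best_cross_hits(x, "b", index) & mm.side_b.members
            for x in mm.side_a.members
        )
        assert any(
            best_cross_hits(y, "a", index) & mm.side_a.members
            for y in mm.side_b.members
        )

    def test_symmetry_under_organism_swap(self):
        rows = [
            ("A1", "A2", 1e-80, 100.0), ("A1", "B1", 1e-50, 100.0),
            ("A2", "A1", 1e-80, 100.0), ("A2", "B1", 1e-45, 100.0),
            ("B1", "A1", 1e-50, 100.0), ("B2", "A3", 1e-30, 100.0),
            ("A3", "B2", 1e-30, 100.0),
        ]
        index, groups = _pipeline(rows)
        fwd = detect_pair_relations("a", "b", groups, index)
        rev = detect_pair_relations("b", "a", groups, index)
        as_set = lambda rels, flip: {
            (r.type, r.side_b.members, r.side_a.members)
            if flip
            else (r.type, r.side_a.members, r.side_b.members)
            for r in rels
        }
        assert as_set(fwd, False) == as_set(rev, True)

    def test_accession_pair_covered_at_most_once(self):
        index, groups = self._group_vs_singleton()
        rels = detect_pair_relations("a", "b", groups, index)
        pairs = [
            (a, b)
            for r in rels
            for a in r.side_a.members
            for b in r.side_b.members
        ]
        assert len(pairs) == len(set(pairs))


class TestFlagContradictions:
    def _contradicted(self, b9_back_to="A2"):
        # group {A1,A2} vs singleton B1; A2's best b-hit escapes to B9
        rows = [
            ("A1", "A2", 1e-80, 100.0), ("A1", "B1", 1e-50, 100.0),
            ("A2", "A1", 1e-80, 100.0), ("A2", "B9", 1e-55, 100.0),
            ("A2", "B1", 1e-50, 100.0),
            ("B1", "A1", 1e-50, 100.0),
            ("B9", b9_back_to, 1e-55, 100.0),
        ]
        index, groups = _pipeline(rows)
        rels = detect_pair_relations("a", "b", groups, index)
        (rel,) = [r for r in rels if r.side_b.members == {"B1"}]
        return flag_contradictions(rel, index)

    def test_reciprocal_escape_is_red(self):
        rel = self._contradicted(b9_back_to="A2")
        (sig,) = rel.signals
        assert (sig.color, sig.member, sig.outside_hit) == ("red", "A2", "B9")

    def test_simple_escape_is_orange(self):
        rel = self._contradicted(b9_back_to="A1")
        (sig,) = rel.signals
        assert (sig.color, sig.member, sig.outside_hit) == ("orange", "A2", "B9")

    def test_outside_hit_never_inside_either_entity(self):
        rel = self._contradicted()
        inside = rel.side_a.members | rel.side_b.members
        assert all(s.outside_hit not in inside for s in rel.signals)

    def test_contained_best_hits_give_no_signals(self):
        rows = [
            ("A1", "A2", 1e-80, 100.0), ("A1", "B1", 1e-50, 100.0),
            ("A2", "A1", 1e-80, 100.0), ("A2", "B1", 1e-50, 100.0),
            ("B1", "A1", 1e-50, 100.0),
        ]
        index, groups = _pipeline(rows)
        (rel,) = detect_pair_relations("a", "b", groups, index)
        assert flag_contradictions(rel, index).signals == ()

    def test_singleton_relations_receive_no_signals(self):
        rows = [("A1", "B1", 1e-50, 100.0), ("B1", "A1", 1e-50, 100.0)]
        index, groups = _pipeline(rows)
        (rel,) = detect_pair_relations("a", "b", groups, index)
        assert flag_contradictions(rel, index).signals == ()
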