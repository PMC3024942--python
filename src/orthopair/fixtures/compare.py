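"""Canonical forms for comparing pipeline output against oracle and truth."""

from __future__ import annotations

from typing import Mapping

from ..inparalog_core import ValidatedGroup
from ..relations import OrthologyRelation
from .oracle import OracleResult


def canonical_groups(
    groups: Mapping[tuple[str, str], list[ValidatedGroup]],
) -> dict[tuple[str, str], frozenset[tuple[frozenset[str], str]]]:
    """Validated groups as (organism, target) -> {(members, provenance)}."""
    return {
        key: frozenset((g.members, g.provenance) for g in glist)
        for key, glist in groups.items()
        if glist
    }


def canonical_relations(
    relations: Mapping[tuple[str, str], list[OrthologyRelation]],
) -> tuple[
    frozenset[tuple[str, str, str, frozenset[str], frozenset[str]]],
    dict[tuple, frozenset[tuple[str, str, str]]],
]:
    """Relations as oracle-comparable keys, plus the per-relation signals."""
    keys = set()
    signals: dict[tuple, frozenset[tuple[str, str, str]]] = {}
    for (org_a, org_b), rels in relations.items():
        for rel in rels:
            key = (org_a, org_b, rel.type, rel.side_a.members, rel.side_b.members)
            keys.add(key)
            signals[key] = frozenset(
                (s.color, s.member, s.outside_hit) for s in rel.signals
            )
    return frozenset(keys), signals


def pipeline_as_oracle_result(
    groups: Mapping[tuple[str, str], list[ValidatedGroup]],
    relations: Mapping[tuple[str, str], list[OrthologyRelation]],
) -> OracleResult:
    keys, signals = canonical_relations(relations)
    return OracleResult(
        groups=canonical_groups(groups), relations=keys, signals=signals
    )


def truth_group_sets(
    groups: Mapping[tuple[str, str], list[ValidatedGroup]],
) -> dict[tuple[str, str], frozenset[frozenset[str]]]:
    """Member sets only (provenance dropped), for TruthSet comparison."""
    return {
        key: frozenset(g.members for g in glist)
        for key, glist in groups.items()
        if glist
    }


def relation_type_triples(
    relations: Mapping[tuple[str, str], list[OrthologyRelation]],
) -> dict[tuple[str, str], frozenset[tuple[str, frozenset[str], frozenset[str]]]]:
    """Relations as (type, members_a, members_b) triples per organism pair."""
    return {
        key: frozenset(
            (rel.type, rel.side_a.members, rel.side_b.members) for rel in rels
        )
        for key, rels in relations.items()
    }
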