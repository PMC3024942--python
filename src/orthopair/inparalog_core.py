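"""Organism-pair-relative inparalog group formation and validation.

Inparalogs are paralogs produced by duplication(s) *after* a given speciation
event; the concept is therefore relative to the pair of organisms compared.
Given the ranked BLAST output of a protein of organism A, every protein of A
scoring strictly better (lower E-value) than the best hit in organism B forms,
together with the query, a *putative* inparalog group of A with respect to B.
A putative group is *validated* when the same hypothesis is confirmed by the
BLAST output of every member: each member's own putative group with respect
to B must contain exactly the same member set (order-insensitive).

When full validation fails, a pair fallback rescues two-member subgroups:
every unordered pair of members that mutually contain each other in their
putative groups becomes a candidate, candidates are ranked by the strength of
the mutual similarity (minimal max of the two cross E-values, ties broken
lexicographically) and accepted greedily so that accepted pairs stay
disjoint.  Members caught in no accepted pair fall back to singleton
entities.

Conventions (documented design choices):

* "E-value inferior" is read as strict ``<`` — a same-organism protein tying
  the boundary E-value is excluded from the group;
* putative groups are deduplicated by member set before validation, so two
  queries defining the same set validate it once;
* a fully validated group always wins over fallback pairs touching its
  members (the fallback only runs for sets that failed full validation).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import inf
from typing import Mapping

from .blast_io import HitIndex
from .errors import ConfigurationError, UnknownAccessionError

PROVENANCE_FULL = "full"
PROVENANCE_PAIR = "pair_fallback"


@dataclass(frozen=True)
class PutativeGroup:
    """A candidate inparalog set defined by one query's BLAST output.

    ``members`` lists the defining query first, then every same-organism
    protein ranked strictly better than the best hit in the target organism,
    in hit-list order.  ``boundary_evalue`` is the E-value of that best hit.
    """

    organism_id: str
    target_organism_id: str
    defining_query: str
    members: tuple[str, ...]
    boundary_evalue: float

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass(frozen=True)
class ValidatedGroup:
    """A confirmed inparalog group of ``organism_id`` w.r.t. the target."""

    organism_id: str
    target_organism_id: str
    members: frozenset[str]
    provenance: str  # PROVENANCE_FULL or PROVENANCE_PAIR


def putative_groups_for_query(query: str, index: HitIndex) -> list[PutativeGroup]:
    """All putative groups defined by one query's BLAST output.

    One group per other organism in which the query has at least one hit; an
    organism without hits yields no group (the group is undefined w.r.t. it).
    Groups are returned in sorted target-organism order.
    """
    hits = index.hits_for(query)  # raises for unknown accessions
    organism = index.organism_of(query)
    targets = sorted(
        {index.organism_of(h.subject_acc) for h in hits} - {organism}
    )
    groups: list[PutativeGroup] = []
    for target in targets:
        boundary = index.hits_in(query, target)[0]
        members = [query]
        for hit in hits:
            if (
                hit.subject_acc != query
                and index.organism_of(hit.subject_acc) == organism
                and hit.evalue < boundary.evalue
            ):
                members.append(hit.subject_acc)
        groups.append(
            PutativeGroup(
                organism_id=organism,
                target_organism_id=target,
                defining_query=query,
                members=tuple(members),
                boundary_evalue=boundary.evalue,
            )
        )
    return groups


PutativeMap = Mapping[tuple[str, str], PutativeGroup | None]


def _member_putative_set(
    member: str, target: str, all_putatives: PutativeMap
) -> frozenset[str] | None:
    key = (member, target)
    if key not in all_putatives:
        raise UnknownAccessionError(
            f"no putative-group record for member {member!r} "
            f"w.r.t. organism {target!r} (protein without a BLAST hit list?)"
        )
    group = all_putatives[key]
    return None if group is None else group.member_set


def _pair_priority(
    pair: tuple[str, str], index: HitIndex | None
) -> tuple[float, str, str]:
    x, y = pair
    if index is None:
        return (0.0, x, y)
    ex = index.evalue_of(x, y)
    ey = index.evalue_of(y, x)
    worst = max(ex if ex is not None else inf, ey if ey is not None else inf)
    return (worst, x, y)


def validate_group(
    p: PutativeGroup,
    all_putatives: PutativeMap,
    index: HitIndex | None = None,
) -> list[ValidatedGroup]:
    """Validate one putative group against its members' own groups.

    ``all_putatives`` maps ``(accession, target_organism)`` to that protein's
    putative group w.r.t. the target, or ``None`` when the protein has a hit
    list but no hits in the target organism.  A member with no record at all
    is an error (its BLAST output is missing from the dataset).

    Returns one fully validated group, or the disjoint fallback pairs, or an
    empty list when nothing survives.  ``index`` is only used to rank
    fallback pairs by mutual similarity; without it the ranking degrades to
    the lexicographic tie-break.
    """
    if len(p.members) < 2:
        raise ConfigurationError(
            "validate_group requires a putative group of at least 2 members"
        )
    target = p.target_organism_id
    member_sets = {
        m: _member_putative_set(m, target, all_putatives) for m in p.members
    }
    full_set = p.member_set
    if all(member_sets[m] == full_set for m in p.members):
        return [
            ValidatedGroup(p.organism_id, target, full_set, PROVENANCE_FULL)
        ]
    candidates: set[tuple[str, str]] = set()
    for x, y in combinations(sorted(p.members), 2):
        sx, sy = member_sets[x], member_sets[y]
        if sx is not None and sy is not None and y in sx and x in sy:
            candidates.add((x, y))
    accepted: list[ValidatedGroup] = []
    used: set[str] = set()
    for x, y in sorted(candidates, key=lambda c: _pair_priority(c, index)):
        if x in used or y in used:
            continue
        used.update((x, y))
        accepted.append(
            ValidatedGroup(
                p.organism_id, target, frozenset((x, y)), PROVENANCE_PAIR
            )
        )
    return accepted


def build_putative_map(index: HitIndex) -> dict[tuple[str, str], PutativeGroup | None]:
    """Putative groups of every protein w.r.t. every other organism.

    For proteins with a non-empty hit list, every (protein, other organism)
    key is present; the value is ``None`` when the protein has no hit in that
    organism.  Proteins with no hits at all contribute no keys.
    """
    organisms = index.organisms
    putatives: dict[tuple[str, str], PutativeGroup | None] = {}
    for acc in index.accessions():
        if not index.hits_for(acc):
            continue
        own = index.organism_of(acc)
        for target in organisms:
            if target != own:
                putatives[(acc, target)] = None
        for group in putative_groups_for_query(acc, index):
            putatives[(acc, group.target_organism_id)] = group
    return putatives


def build_validated_groups(
    index: HitIndex,
) -> dict[tuple[str, str], list[ValidatedGroup]]:
    """Validated inparalog groups for every ordered organism pair.

    Every protein's putative groups are computed once; per (organism,
    target) pair, each distinct member set of size >= 2 is validated exactly
    once.  Fully validated groups are emitted first; fallback pairs are then
    resolved greedily across *all* failed sets of the pair, skipping any pair
    touching a fully validated group, so the final groups per (organism,
    target) are pairwise disjoint.  The result is deterministic under
    permutation of the input hits.
    """
    putatives = build_putative_map(index)

    by_pair: dict[tuple[str, str], dict[frozenset[str], PutativeGroup]] = {}
    for group in putatives.values():
        if group is None or len(group.members) < 2:
            continue
        key = (group.organism_id, group.target_organism_id)
        by_pair.setdefault(key, {}).setdefault(group.member_set, group)

    result: dict[tuple[str, str], list[ValidatedGroup]] = {}
    for pair_key in sorted(by_pair):
        organism, target = pair_key
        distinct = by_pair[pair_key]
        full: list[ValidatedGroup] = []
        fallback_candidates: set[tuple[str, str]] = set()
        for member_set in sorted(distinct, key=lambda s: sorted(s)):
            outcome = validate_group(distinct[member_set], putatives, index)
            if outcome and outcome[0].provenance == PROVENANCE_FULL:
                full.append(outcome[0])
            else:
                for x, y in combinations(sorted(member_set), 2):
                    sx = _member_putative_set(x, target, putatives)
                    sy = _member_putative_set(y, target, putatives)
                    if sx is not None and sy is not None and y in sx and x in sy:
                        fallback_candidates.add((x, y))
        full_members = {m for g in full for m in g.members}
        used: set[str] = set(full_members)
        pairs: list[ValidatedGroup] = []
        for x, y in sorted(
            fallback_candidates, key=lambda c: _pair_priority(c, index)
        ):
            if x in used or y in used:
                continue
            used.update((x, y))
            pairs.append(
                ValidatedGroup(organism, target, frozenset((x, y)), PROVENANCE_PAIR)
            )
        groups = sorted(full + pairs, key=lambda g: sorted(g.members))
        if groups:
            result[pair_key] = groups
    return result


def groups_tsv(groups: Mapping[tuple[str, str], list[ValidatedGroup]]) -> str:
    """TSV export: organism, target_organism, provenance, sorted members."""
    lines = ["organism\ttarget_organism\tprovenance\tmembers\n"]
    for pair_key in sorted(groups):
        for g in groups[pair_key]:
            lines.append(
                f"{g.organism_id}\t{g.target_organism_id}\t{g.provenance}\t"
                + ",".join(sorted(g.members))
                + "\n"
            )
    return "".join(lines)
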