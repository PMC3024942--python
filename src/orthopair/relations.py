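"""Typing of orthology relations between entities, plus contradiction flags.

After inparalog grouping, each organism of a pair is partitioned into
*entities*: its validated inparalog groups w.r.t. the partner organism, and
every remaining protein as a singleton.  Relations between entities of two
organisms are typed from the plain best hits:

* ``ONE_TO_ONE`` — two singletons that are reciprocal best hits (RBH);
* ``ONE_TO_MANY`` — a singleton whose best hit lands inside a group of the
  partner organism, complemented by a returning best hit from any member of
  that group back to the singleton (lineage-specific expansion on one side);
* ``MANY_TO_MANY`` — two groups connected by one best hit in each direction
  (duplications in both lineages after the speciation).

"Best hit" throughout means the top-ranked cross-organism hit under the
module-wide ranking (E-value asc, bit score desc, accession asc).  By
default a single best hit is returned per target organism; setting
``surface_ties=True`` surfaces all subjects co-ranked at an identical
(E-value, bit score), which widens the existential checks — real BLAST
output routinely ties at E-value 0.0 and the switch makes results
independent of the accession tie-break in that situation.

Best hits leaving a group-side entity and landing outside both compared
entities contradict the inferred co-orthology; they are attached to the
relation as warning signals — red when the outside hit is reciprocal, orange
when it is a simple best hit.  Signals annotate, never veto: the relation is
kept and the discrimination is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .blast_io import HitIndex
from .inparalog_core import ValidatedGroup

ONE_TO_ONE = "ONE_TO_ONE"
ONE_TO_MANY = "ONE_TO_MANY"
MANY_TO_MANY = "MANY_TO_MANY"

SINGLETON = "singleton"
GROUP = "group"

_TYPE_ORDER = {ONE_TO_ONE: 0, ONE_TO_MANY: 1, MANY_TO_MANY: 2}


@dataclass(frozen=True)
class Entity:
    """A singleton protein or a validated inparalog group of one organism,
    relative to a partner organism."""

    organism_id: str
    kind: str  # SINGLETON or GROUP
    members: frozenset[str]
    relative_to: str

    def __post_init__(self) -> None:
        if self.kind == SINGLETON and len(self.members) != 1:
            raise ValueError("singleton entity must have exactly one member")


@dataclass(frozen=True)
class WarningSignal:
    """A best hit escaping the compared entities.

    ``member`` is the group member whose best hit contradicts; ``outside_hit``
    the protein outside both entities it points to.  ``color`` is ``red``
    when the outside hit is reciprocal, ``orange`` for a simple best hit.
    """

    color: str  # "red" | "orange"
    member: str
    outside_hit: str


@dataclass(frozen=True)
class OrthologyRelation:
    """A typed orthology link between two entities of two organisms."""

    type: str
    side_a: Entity
    side_b: Entity
    supporting_hits: tuple[tuple[str, str], ...]
    signals: tuple[WarningSignal, ...] = ()

    def side_in(self, organism_id: str) -> Entity:
        if self.side_a.organism_id == organism_id:
            return self.side_a
        if self.side_b.organism_id == organism_id:
            return self.side_b
        raise KeyError(organism_id)

    @property
    def n_red(self) -> int:
        return sum(1 for s in self.signals if s.color == "red")

    @property
    def n_orange(self) -> int:
        return sum(1 for s in self.signals if s.color == "orange")


def best_cross_hits(
    protein: str,
    target_organism: str,
    index: HitIndex,
    surface_ties: bool = False,
) -> frozenset[str]:
    """Subject(s) of the protein's top-ranked hit in one target organism.

    Empty set when the protein has no hit there.  With ``surface_ties`` all
    subjects sharing the top (E-value, bit score) are returned; otherwise
    exactly one (deterministic accession tie-break).
    """
    ranked = index.hits_in(protein, target_organism)  # raises if unknown
    if not ranked:
        return frozenset()
    top = ranked[0]
    if not surface_ties:
        return frozenset((top.subject_acc,))
    return frozenset(
        h.subject_acc
        for h in ranked
        if (h.evalue, h.bitscore) == (top.evalue, top.bitscore)
    )


GroupMap = Mapping[tuple[str, str], list[ValidatedGroup]]


def entities_of(
    organism_id: str, partner_id: str, groups: GroupMap, index: HitIndex
) -> list[Entity]:
    """Partition one organism into entities relative to a partner.

    Validated groups w.r.t. the partner come first (sorted by members), then
    all remaining proteins — including proteins without any BLAST hit — as
    singletons.  A protein in a validated group never simultaneously acts as
    a singleton for this organism pair.
    """
    entities: list[Entity] = []
    grouped: set[str] = set()
    for g in groups.get((organism_id, partner_id), []):
        entities.append(Entity(organism_id, GROUP, g.members, partner_id))
        grouped.update(g.members)
    for acc in index.accessions(organism_id):
        if acc not in grouped:
            entities.append(
                Entity(organism_id, SINGLETON, frozenset((acc,)), partner_id)
            )
    return entities


def detect_pair_relations(
    org_a: str,
    org_b: str,
    groups: GroupMap,
    index: HitIndex,
    surface_ties: bool = False,
) -> list[OrthologyRelation]:
    """Type all orthology relations between two organisms.

    Symmetric by construction: swapping ``org_a`` and ``org_b`` yields the
    same relations with sides swapped.  ``supporting_hits`` records the
    witnessing best-hit pairs (query, subject).
    """

    def bch(protein: str, target: str) -> frozenset[str]:
        return best_cross_hits(protein, target, index, surface_ties)

    ents_a = entities_of(org_a, org_b, groups, index)
    ents_b = entities_of(org_b, org_a, groups, index)
    groups_a = [e for e in ents_a if e.kind == GROUP]
    groups_b = [e for e in ents_b if e.kind == GROUP]
    singles_a = [e for e in ents_a if e.kind == SINGLETON]
    singles_b = [e for e in ents_b if e.kind == SINGLETON]
    single_accs_b = {next(iter(e.members)) for e in singles_b}

    relations: list[OrthologyRelation] = []

    for ea in groups_a:
        for eb in groups_b:
            forward = [
                (x, h)
                for x in sorted(ea.members)
                for h in sorted(bch(x, org_b) & eb.members)
            ]
            backward = [
                (y, h)
                for y in sorted(eb.members)
                for h in sorted(bch(y, org_a) & ea.members)
            ]
            if forward and backward:
                relations.append(
                    OrthologyRelation(
                        MANY_TO_MANY, ea, eb, tuple(forward + backward)
                    )
                )

    for single, group_entities, single_org, group_org in (
        (singles_a, groups_b, org_a, org_b),
        (singles_b, groups_a, org_b, org_a),
    ):
        for es in single:
            p = next(iter(es.members))
            p_best = bch(p, group_org)
            for eg in group_entities:
                forward = sorted(p_best & eg.members)
                backward = [m for m in sorted(eg.members) if p in bch(m, single_org)]
                if forward and backward:
                    side_a, side_b = (
                        (es, eg) if single_org == org_a else (eg, es)
                    )
                    supporting = tuple(
                        [(p, h) for h in forward] + [(m, p) for m in backward]
                    )
                    relations.append(
                        OrthologyRelation(ONE_TO_MANY, side_a, side_b, supporting)
                    )

    for es in singles_a:
        p = next(iter(es.members))
        for q in sorted(bch(p, org_b) & single_accs_b):
            if p in bch(q, org_a):
                eb = Entity(org_b, SINGLETON, frozenset((q,)), org_a)
                relations.append(
                    OrthologyRelation(ONE_TO_ONE, es, eb, ((p, q), (q, p)))
                )

    relations.sort(
        key=lambda r: (
            _TYPE_ORDER[r.type],
            sorted(r.side_a.members),
            sorted(r.side_b.members),
        )
    )
    return relations


def flag_contradictions(
    rel: OrthologyRelation, index: HitIndex, surface_ties: bool = False
) -> OrthologyRelation:
    """Attach red/orange warning signals to a relation.

    For each member of each group-side entity, every best cross hit landing
    outside both member sets becomes a signal: red when the outside protein's
    own best hit points straight back at the member (a reciprocal best hit),
    orange otherwise.  Relations between two singletons receive no signals —
    their RBH condition precludes an escaping best hit.
    """
    inside = rel.side_a.members | rel.side_b.members
    signals: list[WarningSignal] = []
    for side, other in ((rel.side_a, rel.side_b), (rel.side_b, rel.side_a)):
        if side.kind != GROUP:
            continue
        for member in sorted(side.members):
            for outside in sorted(
                best_cross_hits(member, other.organism_id, index, surface_ties)
                - inside
            ):
                reciprocal = member in best_cross_hits(
                    outside, side.organism_id, index, surface_ties
                )
                signals.append(
                    WarningSignal(
                        "red" if reciprocal else "orange", member, outside
                    )
                )
    return replace(rel, signals=tuple(signals))


def detect_all_relations(
    groups: GroupMap,
    index: HitIndex,
    organisms: Iterable[str] | None = None,
    surface_ties: bool = False,
    flag: bool = True,
) -> dict[tuple[str, str], list[OrthologyRelation]]:
    """Relations for every unordered organism pair, keyed (min, max).

    ``side_a`` of every relation belongs to the first organism of the key.
    With ``flag`` (default) contradiction signals are attached.
    """
    orgs = sorted(organisms) if organisms is not None else index.organisms
    out: dict[tuple[str, str], list[OrthologyRelation]] = {}
    for i, org_a in enumerate(orgs):
        for org_b in orgs[i + 1 :]:
            rels = detect_pair_relations(org_a, org_b, groups, index, surface_ties)
            if flag:
                rels = [flag_contradictions(r, index, surface_ties) for r in rels]
            out[(org_a, org_b)] = rels
    return out
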