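"""Brute-force reference implementation of the whole inference chain.

This oracle re-derives putative groups, validation, relation typing and
warning signals by direct, unoptimized application of the rules — flat
dictionary scans, no indexes, no code shared with the main modules.  It is
deliberately quadratic/cubic and guarded to small instances; its only job is
to provide an independent answer for equivalence tests.

It encodes the same documented conventions as the pipeline (ranking by
E-value asc / bit score desc / accession asc; injected self-hits; strict-<
group boundary; set-level deduplication; greedy disjoint fallback pairs
ranked by the weaker of the two cross E-values; single best hit per target
organism, i.e. tie-surfacing off).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf
from typing import Iterable, Mapping

from ..errors import OracleSizeError

_RelKey = tuple[str, str, str, frozenset[str], frozenset[str]]


@dataclass(frozen=True)
class OracleResult:
    """Canonical forms directly comparable across implementations.

    ``groups``: (organism, target) -> set of (member frozenset, provenance).
    ``relations``: set of (org_a, org_b, type, members_a, members_b) with
    org_a < org_b.  ``signals``: relation key -> frozenset of
    (color, member, outside_hit).
    """

    groups: dict[tuple[str, str], frozenset[tuple[frozenset[str], str]]]
    relations: frozenset[_RelKey]
    signals: dict[_RelKey, frozenset[tuple[str, str, str]]]


def _as_rows(hits: Iterable) -> list[tuple[str, str, float, float]]:
    rows = []
    for h in hits:
        if hasattr(h, "query_acc"):
            rows.append((h.query_acc, h.subject_acc, h.evalue, h.bitscore))
        else:
            q, s, e, b = h[:4]
            rows.append((q, s, float(e), float(b)))
    return rows


def oracle_relations(
    accession_to_organism: Mapping[str, str],
    hits: Iterable,
    max_proteins: int = 60,
) -> OracleResult:
    """Exhaustively compute groups, relations and signals for one instance.

    ``hits`` may be BlastHit objects or (query, subject, evalue, bitscore)
    tuples.  Raises :class:`OracleSizeError` above ``max_proteins``.
    """
    acc_org = dict(accession_to_organism)
    if len(acc_org) > max_proteins:
        raise OracleSizeError(
            f"oracle limited to {max_proteins} proteins, got {len(acc_org)}"
        )
    organisms = sorted(set(acc_org.values()))

    # one score per ordered pair: min E-value, tie max bitscore
    score: dict[tuple[str, str], tuple[float, float]] = {}
    for q, s, e, b in _as_rows(hits):
        if q not in acc_org or s not in acc_org:
            raise KeyError(f"hit references unknown accession")
        prev = score.get((q, s))
        if prev is None or (e, -b) < (prev[0], -prev[1]):
            score[(q, s)] = (e, b)
    # synthetic self-hits for proteins that have at least one hit
    has_hits = {q for (q, _s) in score}
    for q in has_hits:
        if (q, q) not in score:
            score[(q, q)] = (0.0, inf)

    def ranked(q: str) -> list[str]:
        subjects = [s for (qq, s) in score if qq == q]
        subjects.sort(key=lambda s: (score[(q, s)][0], -score[(q, s)][1], s))
        return subjects

    def best_in(q: str, org: str) -> str | None:
        for s in ranked(q):
            if acc_org[s] == org:
                return s
        return None

    # putative member sets: (query, target organism) -> frozenset | None
    putative: dict[tuple[str, str], frozenset[str] | None] = {}
    for q in sorted(acc_org):
        if q not in has_hits:
            continue
        own = acc_org[q]
        for target in organisms:
            if target == own:
                continue
            boundary = best_in(q, target)
            if boundary is None:
                putative[(q, target)] = None
                continue
            cut = score[(q, boundary)][0]
            members = {q}
            for s in ranked(q):
                if s != q and acc_org[s] == own and score[(q, s)][0] < cut:
                    members.add(s)
            putative[(q, target)] = frozenset(members)

    # validation per (organism, target)
    groups: dict[tuple[str, str], set[tuple[frozenset[str], str]]] = {}
    for own in organisms:
        for target in organisms:
            if own == target:
                continue
            sets = set()
            for (q, t), members in putative.items():
                if (
                    t == target
                    and members is not None
                    and acc_org[q] == own
                    and len(members) >= 2
                ):
                    sets.add(members)
            full: list[frozenset[str]] = []
            failed: list[frozenset[str]] = []
            for members in sorted(sets, key=sorted):
                if all(putative.get((m, target)) == members for m in members):
                    full.append(members)
                else:
                    failed.append(members)
            candidates: set[tuple[str, str]] = set()
            for members in failed:
                ms = sorted(members)
                for i, x in enumerate(ms):
                    for y in ms[i + 1 :]:
                        sx = putative.get((x, target))
                        sy = putative.get((y, target))
                        if sx is not None and sy is not None and y in sx and x in sy:
                            candidates.add((x, y))
            full_members = {m for g in full for m in g}
            used = set(full_members)
            accepted: list[frozenset[str]] = []

            def pair_key(pair: tuple[str, str]) -> tuple[float, str, str]:
                x, y = pair
                ex = score.get((x, y), (inf, 0.0))[0]
                ey = score.get((y, x), (inf, 0.0))[0]
                return (max(ex, ey), x, y)

            for x, y in sorted(candidates, key=pair_key):
                if x in used or y in used:
                    continue
                used.update((x, y))
                accepted.append(frozenset((x, y)))
            result = {(g, "full") for g in full} | {
                (g, "pair_fallback") for g in accepted
            }
            if result:
                groups[(own, target)] = result

    # relations for every unordered organism pair
    relations: set[_RelKey] = set()
    signals: dict[_RelKey, frozenset[tuple[str, str, str]]] = {}

    def org_accessions(org: str) -> list[str]:
        return sorted(a for a, o in acc_org.items() if o == org)

    for i, org_a in enumerate(organisms):
        for org_b in organisms[i + 1 :]:
            groups_a = sorted(
                (g for g, _p in groups.get((org_a, org_b), ())), key=sorted
            )
            groups_b = sorted(
                (g for g, _p in groups.get((org_b, org_a), ())), key=sorted
            )
            grouped_a = {m for g in groups_a for m in g}
            grouped_b = {m for g in groups_b for m in g}
            singles_a = [a for a in org_accessions(org_a) if a not in grouped_a]
            singles_b = [b for b in org_accessions(org_b) if b not in grouped_b]

            pair_rels: list[tuple[str, frozenset[str], frozenset[str]]] = []
            for ga in groups_a:
                for gb in groups_b:
                    fwd = any(best_in(x, org_b) in gb for x in ga)
                    back = any(best_in(y, org_a) in ga for y in gb)
                    if fwd and back:
                        pair_rels.append(("MANY_TO_MANY", ga, gb))
            for p in singles_a:
                for gb in groups_b:
                    if best_in(p, org_b) in gb and any(
                        best_in(m, org_a) == p for m in gb
                    ):
                        pair_rels.append(
                            ("ONE_TO_MANY", frozenset((p,)), gb)
                        )
            for q in singles_b:
                for ga in groups_a:
                    if best_in(q, org_a) in ga and any(
                        best_in(m, org_b) == q for m in ga
                    ):
                        pair_rels.append(
                            ("ONE_TO_MANY", ga, frozenset((q,)))
                        )
            for p in singles_a:
                for q in singles_b:
                    if best_in(p, org_b) == q and best_in(q, org_a) == p:
                        pair_rels.append(
                            ("ONE_TO_ONE", frozenset((p,)), frozenset((q,)))
                        )

            for rel_type, sa, sb in pair_rels:
                key: _RelKey = (org_a, org_b, rel_type, sa, sb)
                relations.add(key)
                sigs: set[tuple[str, str, str]] = set()
                inside = sa | sb
                for side, side_org, other_org in (
                    (sa, org_a, org_b),
                    (sb, org_b, org_a),
                ):
                    if len(side) < 2:
                        continue
                    for m in side:
                        h = best_in(m, other_org)
                        if h is None or h in inside:
                            continue
                        reciprocal = best_in(h, side_org) == m
                        sigs.add(("red" if reciprocal else "orange", m, h))
                signals[key] = frozenset(sigs)

    return OracleResult(
        groups={k: frozenset(v) for k, v in groups.items()},
        relations=frozenset(relations),
        signals=signals,
    )
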