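"""Persisted results: the relation store, its queries and its exports.

A :class:`RelationStore` bundles the organisms, sequences, validated
inparalog groups and typed relations produced by one analysis and serves the
supported query classes:

* presence/absence constraints ("all proteins of X with orthologs in Y but
  not in Z") — any relation type counts as presence, including co-orthology
  through a group, since a lineage-specific expansion is still orthology;
* batch sequence queries (exact, case-insensitive sequence identity via
  digests);
* textual queries on accessions (exact) and descriptions (case-insensitive
  substring).

Persistence is a single-file JSON document (format ``orthopair-store``,
version 1) — a desk-scale embedded store with a byte-deterministic layout.
Exports cover CSV/XML relation and group tables, FASTA sequences, a
presence/absence CSV matrix (cells 0 / 1 / M / MM) and a graphML relation
network.
"""

from __future__ import annotations

import csv
import io
import json
from typing import Iterable, Mapping, Sequence, TextIO
from xml.etree import ElementTree

import networkx as nx

from . import preprocess
from .blast_io import (
    BlastHit,
    HitIndex,
    OrganismMeta,
    SequenceRecord,
    sequence_digest,
    write_fasta,
)
from .errors import (
    ConfigurationError,
    ExportError,
    UnknownAccessionError,
    UnknownOrganismError,
)
from .inparalog_core import ValidatedGroup, build_validated_groups
from .relations import (
    MANY_TO_MANY,
    ONE_TO_MANY,
    ONE_TO_ONE,
    SINGLETON,
    Entity,
    OrthologyRelation,
    WarningSignal,
    detect_all_relations,
)

PRESENCE = "presence"
ABSENCE = "absence"
UNCARING = "uncaring"

STORE_FORMAT = "orthopair-store"
STORE_VERSION = 1

#: Presence/absence matrix cell codes, strongest first.
_PA_PRECEDENCE = ((ONE_TO_ONE, "1"), (ONE_TO_MANY, "M"), (MANY_TO_MANY, "MM"))


class RelationStore:
    """Indexed collection of sequences, groups and relations."""

    def __init__(
        self,
        organisms: Sequence[OrganismMeta],
        sequences: Iterable[SequenceRecord],
        groups: Mapping[tuple[str, str], list[ValidatedGroup]],
        relations: Mapping[tuple[str, str], list[OrthologyRelation]],
    ) -> None:
        self.organisms = list(organisms)
        self.sequences: dict[str, SequenceRecord] = {}
        for rec in sequences:
            if rec.accession in self.sequences:
                raise ConfigurationError(
                    f"duplicate accession {rec.accession!r} in store"
                )
            self.sequences[rec.accession] = rec
        self.groups = {k: list(v) for k, v in groups.items()}
        self.relations = {k: list(v) for k, v in relations.items()}
        known_orgs = {m.organism_id for m in self.organisms}
        for rec in self.sequences.values():
            if rec.organism_id not in known_orgs:
                raise UnknownOrganismError(
                    f"sequence {rec.accession!r} references organism "
                    f"{rec.organism_id!r} absent from the manifest"
                )
        for glist in self.groups.values():
            for g in glist:
                for acc in g.members:
                    self._require_accession(acc)
        self._digest_index: dict[str, list[str]] = {}
        for rec in self.sequences.values():
            self._digest_index.setdefault(rec.digest, []).append(rec.accession)
        for accs in self._digest_index.values():
            accs.sort()
        # accession -> partner organism -> relation types
        self._acc_types: dict[str, dict[str, set[str]]] = {}
        for rels in self.relations.values():
            for rel in rels:
                for side, other in (
                    (rel.side_a, rel.side_b),
                    (rel.side_b, rel.side_a),
                ):
                    for acc in side.members:
                        self._require_accession(acc)
                        self._acc_types.setdefault(acc, {}).setdefault(
                            other.organism_id, set()
                        ).add(rel.type)

    def _require_accession(self, acc: str) -> None:
        if acc not in self.sequences:
            raise UnknownAccessionError(
                f"store references unknown accession {acc!r}"
            )

    @property
    def organism_ids(self) -> list[str]:
        return sorted(m.organism_id for m in self.organisms)

    def require_organism(self, organism_id: str) -> None:
        if organism_id not in {m.organism_id for m in self.organisms}:
            raise UnknownOrganismError(f"unknown organism {organism_id!r}")

    def proteome_size(self, organism_id: str) -> int:
        self.require_organism(organism_id)
        return sum(
            1 for r in self.sequences.values() if r.organism_id == organism_id
        )

    def accessions(self, organism_id: str | None = None) -> list[str]:
        if organism_id is None:
            return sorted(self.sequences)
        self.require_organism(organism_id)
        return sorted(
            a for a, r in self.sequences.items() if r.organism_id == organism_id
        )

    def partner_organisms(self, accession: str) -> set[str]:
        """Organisms with which the protein has at least one relation."""
        self._require_accession(accession)
        return set(self._acc_types.get(accession, ()))

    def relation_types_with(self, accession: str, organism_id: str) -> set[str]:
        self._require_accession(accession)
        return set(self._acc_types.get(accession, {}).get(organism_id, ()))

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        def entity_dict(e: Entity) -> dict:
            return {
                "organism_id": e.organism_id,
                "kind": e.kind,
                "members": sorted(e.members),
                "relative_to": e.relative_to,
            }

        return {
            "format": STORE_FORMAT,
            "version": STORE_VERSION,
            "organisms": [
                {
                    "organism_id": m.organism_id,
                    "name": m.name,
                    "source": m.source,
                    "taxid": m.taxid,
                }
                for m in self.organisms
            ],
            "sequences": [
                {
                    "accession": r.accession,
                    "description": r.description,
                    "organism_id": r.organism_id,
                    "sequence": r.sequence,
                }
                for r in sorted(
                    self.sequences.values(),
                    key=lambda r: (r.organism_id, r.accession),
                )
            ],
            "groups": [
                {
                    "organism_id": g.organism_id,
                    "target_organism_id": g.target_organism_id,
                    "members": sorted(g.members),
                    "provenance": g.provenance,
                }
                for key in sorted(self.groups)
                for g in self.groups[key]
            ],
            "relations": [
                {
                    "type": rel.type,
                    "side_a": entity_dict(rel.side_a),
                    "side_b": entity_dict(rel.side_b),
                    "supporting_hits": [list(p) for p in rel.supporting_hits],
                    "signals": [
                        {
                            "color": s.color,
                            "member": s.member,
                            "outside_hit": s.outside_hit,
                        }
                        for s in rel.signals
                    ],
                }
                for key in sorted(self.relations)
                for rel in self.relations[key]
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RelationStore":
        if data.get("format") != STORE_FORMAT:
            raise ConfigurationError("not an orthopair store document")
        organisms = [OrganismMeta(**o) for o in data["organisms"]]
        sequences = [SequenceRecord(**s) for s in data["sequences"]]
        groups: dict[tuple[str, str], list[ValidatedGroup]] = {}
        for g in data["groups"]:
            vg = ValidatedGroup(
                g["organism_id"],
                g["target_organism_id"],
                frozenset(g["members"]),
                g["provenance"],
            )
            groups.setdefault(
                (vg.organism_id, vg.target_organism_id), []
            ).append(vg)
        relations: dict[tuple[str, str], list[OrthologyRelation]] = {}
        for r in data["relations"]:
            side_a = Entity(
                r["side_a"]["organism_id"],
                r["side_a"]["kind"],
                frozenset(r["side_a"]["members"]),
                r["side_a"]["relative_to"],
            )
            side_b = Entity(
                r["side_b"]["organism_id"],
                r["side_b"]["kind"],
                frozenset(r["side_b"]["members"]),
                r["side_b"]["relative_to"],
            )
            rel = OrthologyRelation(
                r["type"],
                side_a,
                side_b,
                tuple(tuple(p) for p in r["supporting_hits"]),
                tuple(WarningSignal(**s) for s in r["signals"]),
            )
            key = (side_a.organism_id, side_b.organism_id)
            relations.setdefault(key, []).append(rel)
        return cls(organisms, sequences, groups, relations)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RelationStore":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def build_store(
    organisms: Sequence[OrganismMeta],
    proteomes: Mapping[str, Sequence[SequenceRecord]],
    hits: Iterable[BlastHit],
    *,
    min_len: int = 20,
    max_len: int = 10000,
    collapse: bool = True,
    identity_threshold: float = 99.0,
    coverage_threshold: float = 0.9,
    surface_ties: bool = False,
    flag: bool = True,
) -> RelationStore:
    """Run the full inference pipeline and assemble a store.

    ``proteomes`` maps organism id to its sequence records; ``hits`` are the
    parsed (cutoff-filtered) BLAST rows.  Hygiene filters (length window and
    within-organism redundancy collapse) run first; hits touching a filtered
    protein are dropped, hits naming a completely unknown accession raise.
    """
    known_ids = {m.organism_id for m in organisms}
    for org in proteomes:
        if org not in known_ids:
            raise UnknownOrganismError(
                f"proteome for organism {org!r} absent from the manifest"
            )
    hits = list(hits)
    all_accs = {
        rec.accession for recs in proteomes.values() for rec in recs
    }
    for h in hits:
        for acc in (h.query_acc, h.subject_acc):
            if acc not in all_accs:
                raise UnknownAccessionError(
                    f"hit references unknown accession {acc!r}"
                )

    kept_records: list[SequenceRecord] = []
    for org in sorted(proteomes):
        recs, _ = preprocess.filter_by_length(proteomes[org], min_len, max_len)
        if collapse and recs:
            acc_set = {r.accession for r in recs}
            within = [
                h
                for h in hits
                if h.query_acc in acc_set and h.subject_acc in acc_set
            ]
            recs, _ = preprocess.collapse_redundant(
                recs, within, identity_threshold, coverage_threshold
            )
        kept_records.extend(recs)

    acc_to_org = {r.accession: r.organism_id for r in kept_records}
    kept_hits = [
        h for h in hits if h.query_acc in acc_to_org and h.subject_acc in acc_to_org
    ]
    index = HitIndex(kept_hits, acc_to_org)
    groups = build_validated_groups(index)
    relations = detect_all_relations(
        groups,
        index,
        organisms=sorted(m.organism_id for m in organisms),
        surface_ties=surface_ties,
        flag=flag,
    )
    return RelationStore(organisms, kept_records, groups, relations)


# -- queries ---------------------------------------------------------------


def presence_absence_query(
    store: RelationStore,
    focal_organism: str,
    constraint: Mapping[str, str],
) -> list[str]:
    """Focal-organism proteins matching presence/absence constraints.

    ``constraint`` maps organism id to ``presence``/``absence``/``uncaring``
    (unlisted organisms are uncaring).  A protein matches when it has at
    least one relation with every presence organism and none with any
    absence organism.  At least one organism must be constrained.
    """
    store.require_organism(focal_organism)
    required = {o for o, c in constraint.items() if c == PRESENCE}
    forbidden = {o for o, c in constraint.items() if c == ABSENCE}
    for org in required | forbidden:
        store.require_organism(org)
    for org, c in constraint.items():
        if c not in (PRESENCE, ABSENCE, UNCARING):
            raise ConfigurationError(f"unknown constraint {c!r} for {org!r}")
    if not required and not forbidden:
        raise ConfigurationError(
            "at least one organism must be constrained to presence or absence"
        )
    out: list[str] = []
    for acc in store.accessions(focal_organism):
        partners = store.partner_organisms(acc)
        if required <= partners and not (forbidden & partners):
            out.append(acc)
    return out


def query_by_sequence(
    store: RelationStore, fasta_stream: TextIO | str
) -> dict[str, str | None]:
    """Match FASTA sequences to stored accessions by exact sequence identity.

    Matching is case-insensitive (digest based).  Unmatched queries map to
    ``None``; a digest shared by several stored records resolves to the
    smallest accession.
    """
    from Bio import SeqIO

    if isinstance(fasta_stream, str):
        fasta_stream = io.StringIO(fasta_stream)
    result: dict[str, str | None] = {}
    for rec in SeqIO.parse(fasta_stream, "fasta"):
        matches = store._digest_index.get(sequence_digest(str(rec.seq)), [])
        result[rec.id] = matches[0] if matches else None
    return result


def query_by_text(
    store: RelationStore, text: str, field: str = "accession"
) -> list[str]:
    """Accession (exact) or description (case-insensitive substring) search."""
    if not text:
        raise ConfigurationError("query text must be non-empty")
    if field == "accession":
        return [text] if text in store.sequences else []
    if field == "description":
        needle = text.lower()
        return sorted(
            acc
            for acc, rec in store.sequences.items()
            if needle in rec.description.lower()
        )
    raise ConfigurationError(f"unknown query field {field!r}")


def normalized_relation_counts(
    store: RelationStore, org_x: str, org_y: str, relation_type: str
) -> float:
    """Relation count for a pair, normalized by its potential maximum.

    * 1-to-1: divided by the smaller proteome size;
    * 1-to-many: divided by the larger proteome size, counting only
      relations oriented from ``org_x`` (singleton side) to ``org_y``;
    * many-to-many: divided by the product of the proteome sizes.
    """
    store.require_organism(org_x)
    store.require_organism(org_y)
    nx_, ny_ = store.proteome_size(org_x), store.proteome_size(org_y)
    if nx_ == 0 or ny_ == 0:
        raise ConfigurationError("proteome sizes must be positive")
    pair = (min(org_x, org_y), max(org_x, org_y))
    rels = store.relations.get(pair, [])
    if relation_type == ONE_TO_ONE:
        count = sum(1 for r in rels if r.type == ONE_TO_ONE)
        return count / min(nx_, ny_)
    if relation_type == MANY_TO_MANY:
        count = sum(1 for r in rels if r.type == MANY_TO_MANY)
        return count / (nx_ * ny_)
    if relation_type == ONE_TO_MANY:
        count = sum(
            1
            for r in rels
            if r.type == ONE_TO_MANY
            and r.side_in(org_x).kind == SINGLETON
        )
        return count / max(nx_, ny_)
    raise ConfigurationError(f"unknown relation type {relation_type!r}")


# -- exports ---------------------------------------------------------------


def _relation_rows(store: RelationStore) -> list[tuple]:
    rows = []
    for key in sorted(store.relations):
        for rel in store.relations[key]:
            rows.append(
                (
                    rel.side_a.organism_id,
                    rel.side_b.organism_id,
                    rel.type,
                    ",".join(sorted(rel.side_a.members)),
                    ",".join(sorted(rel.side_b.members)),
                    rel.n_red,
                    rel.n_orange,
                )
            )
    return rows


def _csv_text(header: Sequence[str], rows: Iterable[Sequence]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    writer.writerows(rows)
    return buf.getvalue()


def _relations_xml(store: RelationStore) -> str:
    root = ElementTree.Element("relations")
    for key in sorted(store.relations):
        for rel in store.relations[key]:
            el = ElementTree.SubElement(
                root,
                "relation",
                org_a=rel.side_a.organism_id,
                org_b=rel.side_b.organism_id,
                type=rel.type,
            )
            for tag, side in (("members_a", rel.side_a), ("members_b", rel.side_b)):
                mel = ElementTree.SubElement(el, tag)
                for acc in sorted(side.members):
                    ElementTree.SubElement(mel, "member").text = acc
            if rel.signals:
                sel = ElementTree.SubElement(el, "signals")
                for s in rel.signals:
                    ElementTree.SubElement(
                        sel,
                        "signal",
                        color=s.color,
                        member=s.member,
                        outside_hit=s.outside_hit,
                    )
    ElementTree.indent(root)
    return ElementTree.tostring(root, encoding="unicode") + "\n"


def _groups_xml(store: RelationStore) -> str:
    root = ElementTree.Element("groups")
    for key in sorted(store.groups):
        for g in store.groups[key]:
            el = ElementTree.SubElement(
                root,
                "group",
                organism=g.organism_id,
                target_organism=g.target_organism_id,
                provenance=g.provenance,
            )
            for acc in sorted(g.members):
                ElementTree.SubElement(el, "member").text = acc
    ElementTree.indent(root)
    return ElementTree.tostring(root, encoding="unicode") + "\n"


def _pa_matrix_csv(
    store: RelationStore, accessions: Sequence[str] | None = None
) -> str:
    orgs = store.organism_ids
    accs = sorted(accessions) if accessions is not None else store.accessions()
    rows = []
    for acc in accs:
        store._require_accession(acc)
        row: list[str] = [acc]
        for org in orgs:
            types = store.relation_types_with(acc, org)
            cell = "0"
            for rel_type, code in _PA_PRECEDENCE:
                if rel_type in types:
                    cell = code
                    break
            row.append(cell)
        rows.append(row)
    return _csv_text(["accession"] + orgs, rows)


def _graphml(store: RelationStore) -> str:
    g = nx.Graph()
    participating = sorted(
        {
            acc
            for rels in store.relations.values()
            for rel in rels
            for acc in rel.side_a.members | rel.side_b.members
        }
    )
    for acc in participating:
        g.add_node(acc, organism=store.sequences[acc].organism_id)
    for key in sorted(store.relations):
        for rel in store.relations[key]:
            for a in sorted(rel.side_a.members):
                for b in sorted(rel.side_b.members):
                    g.add_edge(
                        a,
                        b,
                        type=rel.type,
                        red_signals=rel.n_red,
                        orange_signals=rel.n_orange,
                    )
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    return buf.getvalue().decode("utf-8")


def export(
    store: RelationStore,
    what: str,
    format: str,
    accessions: Sequence[str] | None = None,
) -> str:
    """Render part of the store in one of the supported formats.

    Supported combinations: relations -> csv|xml, groups -> csv|xml,
    sequences -> fasta, pa_matrix -> csv, graph -> graphml.  Output is
    byte-deterministic for a fixed store (stable sort keys everywhere).
    ``accessions`` optionally restricts the pa_matrix rows.
    """
    key = (what, format)
    if key == ("relations", "csv"):
        return _csv_text(
            [
                "org_a",
                "org_b",
                "type",
                "members_a",
                "members_b",
                "n_signals_red",
                "n_signals_orange",
            ],
            _relation_rows(store),
        )
    if key == ("relations", "xml"):
        return _relations_xml(store)
    if key == ("groups", "csv"):
        rows = [
            (
                g.organism_id,
                g.target_organism_id,
                g.provenance,
                ",".join(sorted(g.members)),
            )
            for k in sorted(store.groups)
            for g in store.groups[k]
        ]
        return _csv_text(
            ["organism", "target_organism", "provenance", "members"], rows
        )
    if key == ("groups", "xml"):
        return _groups_xml(store)
    if key == ("sequences", "fasta"):
        ordered = sorted(
            store.sequences.values(), key=lambda r: (r.organism_id, r.accession)
        )
        return write_fasta(ordered)
    if key == ("pa_matrix", "csv"):
        return _pa_matrix_csv(store, accessions)
    if key == ("graph", "graphml"):
        return _graphml(store)
    raise ExportError(f"unsupported export combination {what!r}/{format!r}")
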