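"""Readers and the in-memory model for the three pipeline inputs.

An analysis starts from three artifacts:

* one or more NCBI BLAST tabular result files (``-outfmt 6``, 12 columns)
  covering an all-versus-all search of every proteome against the pooled
  database of all proteomes;
* one FASTA proteome file per organism;
* an organism manifest (XML, or a plain four-column TSV dialect) giving the
  display name, sequence source and taxonomic identifier of each organism.

This module parses those artifacts into :class:`BlastHit`,
:class:`SequenceRecord` and :class:`OrganismMeta` values and indexes the hits
into a :class:`HitIndex`, the per-protein ranked hit list that all downstream
inference consumes.

Ranking convention
------------------
Hits of a query are ordered by ascending E-value, ties broken by descending
bit score, then ascending subject accession.  The E-value is the biological
ranking key; the bit-score refinement exists because E-values saturate at 0.0
for highly similar proteins in real BLAST output, and the accession tie-break
makes the order total and reproducible.

If a query's hit list does not contain the query itself, a synthetic self-hit
(E-value 0, infinite bit-score sentinel) is injected so that every protein is
rank 1 of its own list, as an all-versus-all search guarantees in practice.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO
from xml.etree import ElementTree

from Bio import SeqIO

from .errors import (
    BlastParseError,
    FastaError,
    ManifestError,
    UnknownAccessionError,
)

#: Bit-score sentinel used for injected self-hits; beats any real bit score.
SELF_HIT_BITSCORE = math.inf


def sequence_digest(sequence: str) -> str:
    """Checksum of a protein sequence, case-insensitive.

    Equal sequences (up to case) map to equal digests; used for exact-sequence
    batch queries against a store.
    """
    return hashlib.sha1(sequence.upper().encode("ascii")).hexdigest()


@dataclass(frozen=True)
class SequenceRecord:
    """One proteome entry.

    ``accession`` is the FASTA header token up to the first whitespace;
    ``description`` the remainder of the header (possibly empty).  ``length``
    and ``digest`` are derived from the sequence at construction.
    """

    accession: str
    description: str
    organism_id: str
    sequence: str
    length: int = field(init=False)
    digest: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.accession:
            raise FastaError("sequence record with empty accession")
        if not self.sequence:
            raise FastaError(f"empty sequence for accession {self.accession!r}")
        object.__setattr__(self, "length", len(self.sequence))
        object.__setattr__(self, "digest", sequence_digest(self.sequence))


@dataclass(frozen=True)
class OrganismMeta:
    """Manifest entry: internal key plus descriptive metadata."""

    organism_id: str
    name: str
    source: str
    taxid: str


@dataclass(frozen=True)
class BlastHit:
    """One query->subject similarity record (best HSP after reduction)."""

    query_acc: str
    subject_acc: str
    evalue: float
    bitscore: float
    pident: float = 100.0
    aln_length: int = 1


def _hit_rank_key(hit: BlastHit) -> tuple:
    return (hit.evalue, -hit.bitscore, hit.subject_acc)


def parse_blast_tabular(
    stream: Iterable[str], evalue_cutoff: float = 1e-9
) -> list[BlastHit]:
    """Parse 12-column NCBI BLAST tabular output.

    Rows with an E-value above ``evalue_cutoff`` are discarded (the
    conventional cutoff for proteome-scale searches is 1e-9, the default).
    Comment lines starting with ``#`` and blank lines are skipped.  Columns
    5-10 (mismatches, gap opens, coordinates) are validated as present but not
    retained in the data model.

    Raises :class:`BlastParseError` naming the offending line number when a
    line does not have exactly 12 tab-separated fields or a numeric field
    does not parse.
    """
    hits: list[BlastHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise BlastParseError(
                f"line {lineno}: expected 12 tab-separated columns, "
                f"found {len(parts)}"
            )
        try:
            pident = float(parts[2])
            aln_length = int(parts[3])
            evalue = float(parts[10])
            bitscore = float(parts[11])
        except ValueError as exc:
            raise BlastParseError(f"line {lineno}: {exc}") from exc
        if evalue < 0:
            raise BlastParseError(f"line {lineno}: negative E-value {evalue}")
        if not 0.0 <= pident <= 100.0:
            raise BlastParseError(
                f"line {lineno}: percent identity {pident} outside [0, 100]"
            )
        if aln_length <= 0:
            raise BlastParseError(
                f"line {lineno}: non-positive alignment length {aln_length}"
            )
        if evalue <= evalue_cutoff:
            hits.append(
                BlastHit(
                    query_acc=parts[0],
                    subject_acc=parts[1],
                    evalue=evalue,
                    bitscore=bitscore,
                    pident=pident,
                    aln_length=aln_length,
                )
            )
    return hits


def reduce_to_best_hsp(hits: Iterable[BlastHit]) -> list[BlastHit]:
    """Keep a single hit per (query, subject) pair.

    BLAST emits one row per HSP; inference needs one score per protein pair.
    The retained hit has minimal E-value (tie: maximal bit score).  The
    result is returned in the deterministic index order (query ascending,
    then the module-wide ranking) and the operation is idempotent.
    """
    best: dict[tuple[str, str], BlastHit] = {}
    for hit in hits:
        key = (hit.query_acc, hit.subject_acc)
        prev = best.get(key)
        if prev is None or (hit.evalue, -hit.bitscore) < (prev.evalue, -prev.bitscore):
            best[key] = hit
    return sorted(best.values(), key=lambda h: (h.query_acc,) + _hit_rank_key(h))


def read_fasta_proteome(stream: TextIO | str, organism_id: str) -> list[SequenceRecord]:
    """Read one organism's proteome from FASTA.

    The accession is the header token before the first whitespace (compound
    ``db|acc|locus`` identifiers are kept verbatim, a documented dialect
    restriction).  Duplicate accessions and empty sequences are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        accession = rec.id
        if accession in seen:
            raise FastaError(
                f"duplicate accession {accession!r} in proteome {organism_id!r}"
            )
        seen.add(accession)
        description = rec.description[len(rec.id):].strip()
        sequence = str(rec.seq)
        if not sequence:
            raise FastaError(
                f"empty sequence for accession {accession!r} "
                f"in proteome {organism_id!r}"
            )
        records.append(
            SequenceRecord(
                accession=accession,
                description=description,
                organism_id=organism_id,
                sequence=sequence,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], width: int = 60) -> str:
    """Render records as FASTA text (fixed line width, input order)."""
    out: list[str] = []
    for rec in records:
        header = rec.accession if not rec.description else f"{rec.accession} {rec.description}"
        out.append(f">{header}")
        for i in range(0, len(rec.sequence), width):
            out.append(rec.sequence[i : i + width])
    return "\n".join(out) + ("\n" if out else "")


def read_organism_manifest(
    stream: TextIO | str, dialect: str = "xml"
) -> list[OrganismMeta]:
    """Read the organism manifest in the XML or TSV dialect.

    XML schema: root ``<organisms>`` with ``<organism id="...">`` children
    each carrying ``<name>``, ``<source>`` and ``<taxid>`` elements.  TSV
    dialect: four columns ``organism_id, name, source, taxid``, no header.
    Duplicate organism ids and missing required fields are errors.
    """
    if dialect == "xml":
        metas = _read_manifest_xml(stream)
    elif dialect == "tsv":
        metas = _read_manifest_tsv(stream)
    else:
        raise ManifestError(f"unknown manifest dialect {dialect!r}")
    seen: set[str] = set()
    for meta in metas:
        if meta.organism_id in seen:
            raise ManifestError(f"duplicate organism_id {meta.organism_id!r}")
        seen.add(meta.organism_id)
    return metas


def _read_manifest_xml(stream: TextIO | str) -> list[OrganismMeta]:
    try:
        if isinstance(stream, str):
            root = ElementTree.fromstring(stream)
        else:
            root = ElementTree.parse(stream).getroot()
    except ElementTree.ParseError as exc:
        raise ManifestError(f"malformed manifest XML: {exc}") from exc
    if root.tag != "organisms":
        raise ManifestError(f"manifest root must be <organisms>, got <{root.tag}>")
    metas: list[OrganismMeta] = []
    for el in root.findall("organism"):
        organism_id = el.get("id")
        if not organism_id:
            raise ManifestError("organism element without an id attribute")
        fields: dict[str, str] = {}
        for name in ("name", "source", "taxid"):
            child = el.find(name)
            if child is None:
                raise ManifestError(
                    f"organism {organism_id!r}: missing <{name}> element"
                )
            fields[name] = (child.text or "").strip()
        metas.append(OrganismMeta(organism_id, fields["name"], fields["source"], fields["taxid"]))
    return metas


def _read_manifest_tsv(stream: TextIO | str) -> list[OrganismMeta]:
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream
    metas: list[OrganismMeta] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ManifestError(
                f"manifest TSV line {lineno}: expected 4 columns, found {len(parts)}"
            )
        if not parts[0]:
            raise ManifestError(f"manifest TSV line {lineno}: empty organism_id")
        metas.append(OrganismMeta(*parts))
    return metas


def write_organism_manifest(metas: Iterable[OrganismMeta], dialect: str = "xml") -> str:
    """Serialize manifest entries in either supported dialect."""
    metas = list(metas)
    if dialect == "tsv":
        return "".join(
            f"{m.organism_id}\t{m.name}\t{m.source}\t{m.taxid}\n" for m in metas
        )
    if dialect != "xml":
        raise ManifestError(f"unknown manifest dialect {dialect!r}")
    root = ElementTree.Element("organisms")
    for m in metas:
        el = ElementTree.SubElement(root, "organism", id=m.organism_id)
        ElementTree.SubElement(el, "name").text = m.name
        ElementTree.SubElement(el, "source").text = m.source
        ElementTree.SubElement(el, "taxid").text = m.taxid
    ElementTree.indent(root)
    return ElementTree.tostring(root, encoding="unicode") + "\n"


class HitIndex:
    """Per-protein ranked hit lists plus the accession -> organism map.

    The index is built from reduced (one row per protein pair) hits; the
    constructor applies :func:`reduce_to_best_hsp` itself, which is harmless
    on already-reduced input.  Every query and subject accession must resolve
    to exactly one organism through ``accession_to_organism``; unknown
    accessions raise :class:`UnknownAccessionError`.

    Proteins present in the accession map but absent from the hits are
    retained with empty hit lists — they can never enter groups or relations
    but still count as singleton entities of their organism.
    """

    def __init__(
        self,
        hits: Iterable[BlastHit],
        accession_to_organism: Mapping[str, str],
        inject_self_hits: bool = True,
    ) -> None:
        self._org: dict[str, str] = dict(accession_to_organism)
        reduced = reduce_to_best_hsp(hits)
        for hit in reduced:
            for acc in (hit.query_acc, hit.subject_acc):
                if acc not in self._org:
                    raise UnknownAccessionError(
                        f"hit references unknown accession {acc!r}"
                    )
        per_query: dict[str, list[BlastHit]] = {}
        for hit in reduced:
            per_query.setdefault(hit.query_acc, []).append(hit)
        if inject_self_hits:
            for query, lst in per_query.items():
                if not any(h.subject_acc == query for h in lst):
                    lst.append(
                        BlastHit(
                            query_acc=query,
                            subject_acc=query,
                            evalue=0.0,
                            bitscore=SELF_HIT_BITSCORE,
                        )
                    )
        self._hits: dict[str, tuple[BlastHit, ...]] = {
            q: tuple(sorted(lst, key=_hit_rank_key)) for q, lst in per_query.items()
        }
        self._evalue: dict[tuple[str, str], float] = {
            (h.query_acc, h.subject_acc): h.evalue
            for lst in self._hits.values()
            for h in lst
        }

    def __contains__(self, accession: str) -> bool:
        return accession in self._org

    @property
    def organisms(self) -> list[str]:
        """Sorted list of organism ids present in the accession map."""
        return sorted(set(self._org.values()))

    def accessions(self, organism_id: str | None = None) -> list[str]:
        """Sorted accessions, optionally restricted to one organism."""
        if organism_id is None:
            return sorted(self._org)
        return sorted(a for a, o in self._org.items() if o == organism_id)

    def organism_of(self, accession: str) -> str:
        try:
            return self._org[accession]
        except KeyError:
            raise UnknownAccessionError(f"unknown accession {accession!r}") from None

    def hits_for(self, query: str) -> tuple[BlastHit, ...]:
        """The query's full ranked hit list (empty tuple if it has no hits)."""
        if query not in self._org:
            raise UnknownAccessionError(f"unknown accession {query!r}")
        return self._hits.get(query, ())

    def hits_in(self, query: str, target_organism: str) -> tuple[BlastHit, ...]:
        """The query's ranked hits restricted to one target organism."""
        return tuple(
            h for h in self.hits_for(query) if self._org[h.subject_acc] == target_organism
        )

    def evalue_of(self, query: str, subject: str) -> float | None:
        """E-value of subject in query's list, or None if absent."""
        return self._evalue.get((query, subject))
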