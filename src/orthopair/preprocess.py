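"""Proteome hygiene applied before inference.

Two rules are available, mirroring standard large-scale practice:

* a length window — sequences shorter than 20 or longer than 10000 residues
  are excluded (both bounds strict on the outside, i.e. 20 and 10000 stay);
* a redundancy collapse — within one organism, sequences sharing more than
  99% identity over a sufficient fraction of the shorter sequence are treated
  as duplicates and only the longest representative is retained.

The redundancy graph is derived from the supplied within-organism BLAST hits
(no internal aligner): each qualifying hit is an edge, and one survivor is
kept per connected component.  Because BLAST identity is reported per local
alignment, a coverage requirement (default 0.9 of the shorter sequence)
prevents two distinct multi-domain proteins sharing one near-identical domain
from collapsing.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx

from .blast_io import BlastHit, SequenceRecord
from .errors import ConfigurationError, UnknownAccessionError


def filter_by_length(
    records: Iterable[SequenceRecord],
    min_len: int = 20,
    max_len: int = 10000,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (kept, dropped) by the residue-length window.

    Kept records satisfy ``min_len <= length <= max_len``; the two lists
    partition the input and preserve its order.
    """
    if min_len > max_len:
        raise ConfigurationError(
            f"min_len ({min_len}) must not exceed max_len ({max_len})"
        )
    kept: list[SequenceRecord] = []
    dropped: list[SequenceRecord] = []
    for rec in records:
        (kept if min_len <= rec.length <= max_len else dropped).append(rec)
    return kept, dropped


def collapse_redundant(
    records: Sequence[SequenceRecord],
    self_hits: Iterable[BlastHit],
    identity_threshold: float = 99.0,
    coverage_threshold: float = 0.9,
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Collapse near-identical sequences within an organism.

    ``self_hits`` must be within-organism hits over ``records``.  A hit is a
    redundancy edge when its percent identity is strictly greater than
    ``identity_threshold`` and its alignment covers at least
    ``coverage_threshold`` of the shorter of the two sequences.  Within each
    connected component of the resulting graph the longest sequence is
    retained (tie: lexicographically smallest accession).

    Returns ``(kept_records, collapsed_pairs)`` where kept records preserve
    input order and ``collapsed_pairs`` lists ``(dropped_acc, kept_acc)``
    sorted by dropped accession.
    """
    by_acc = {rec.accession: rec for rec in records}
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(by_acc)
    for hit in self_hits:
        for acc in (hit.query_acc, hit.subject_acc):
            if acc not in by_acc:
                raise UnknownAccessionError(
                    f"self-hit references unknown accession {acc!r}"
                )
        q, s = by_acc[hit.query_acc], by_acc[hit.subject_acc]
        if q.organism_id != s.organism_id:
            raise ConfigurationError(
                f"hit {hit.query_acc!r}->{hit.subject_acc!r} crosses organisms "
                f"({q.organism_id!r} vs {s.organism_id!r}); "
                "collapse_redundant expects within-organism hits"
            )
        if hit.query_acc == hit.subject_acc:
            continue
        shorter = min(q.length, s.length)
        if (
            hit.pident > identity_threshold
            and hit.aln_length / shorter >= coverage_threshold
        ):
            graph.add_edge(hit.query_acc, hit.subject_acc)

    keep: set[str] = set()
    collapsed: list[tuple[str, str]] = []
    for component in nx.connected_components(graph):
        survivor = min(component, key=lambda a: (-by_acc[a].length, a))
        keep.add(survivor)
        collapsed.extend((acc, survivor) for acc in component if acc != survivor)
    kept_records = [rec for rec in records if rec.accession in keep]
    return kept_records, sorted(collapsed)


def collapsed_pairs_tsv(collapsed_pairs: Iterable[tuple[str, str]]) -> str:
    """Two-column TSV report of the collapse (dropped, kept)."""
    return "".join(f"{dropped}\t{kept}\n" for dropped, kept in collapsed_pairs)
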