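"""Input parsing, hit reduction and the deterministic hit index."""

import io
import math

import pytest
from hypothesis import given, strategies as st

from orthopair import blast_io
from orthopair.blast_io import BlastHit, HitIndex
from orthopair.errors import (
    BlastParseError,
    FastaError,
    ManifestError,
    UnknownAccessionError,
)


def _line(q="A1", s="B1", pident=45.2, length=300, evalue="1e-50", bits=190.0):
    return (
        f"{q}\t{s}\t{pident}\t{length}\t10\t2\t1\t{length}\t1\t{length}"
        f"\t{evalue}\t{bits}"
    )


class TestParseBlastTabular:
    def test_parses_fields_and_applies_cutoff(self):
        hits = blast_io.parse_blast_tabular(io.StringIO(_line() + "\n"), 1e-9)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.query_acc, hit.subject_acc) == ("A1", "B1")
        assert hit.evalue == 1e-50
        assert hit.bitscore == 190.0
        assert hit.pident == 45.2
        assert hit.aln_length == 300

    def test_cutoff_excludes_weak_hits(self):
        hits = blast_io.parse_blast_tabular(io.StringIO(_line() + "\n"), 1e-60)
        assert hits == []

    def test_comment_and_blank_lines_skipped(self):
        text = "# BLASTP 2.x\n" + "\n".join(
            _line(s=f"B{i}") for i in range(3)
        ) + "\n\n"
        hits = blast_io.parse_blast_tabular(io.StringIO(text))
        assert len(hits) == 3

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("A1\tB1\tonly-three-cols\n", "line 1"),
            (_line() + "\n" + "A1\tB1\tbad\t300\t1\t1\t1\t1\t1\t1\t1e-5\t10\n", "line 2"),
            (_line(evalue="not-a-number") + "\n", "line 1"),
        ],
    )
    def test_errors_name_the_line(self, text, fragment):
        with pytest.raises(BlastParseError, match=fragment):
            blast_io.parse_blast_tabular(io.StringIO(text))


class TestReduceToBestHsp:
    def test_keeps_minimal_evalue(self):
        hits = [BlastHit("A1", "B1", 1e-50, 100.0), BlastHit("A1", "B1", 1e-20, 300.0)]
        (kept,) = blast_io.reduce_to_best_hsp(hits)
        assert kept.evalue == 1e-50

    def test_bitscore_breaks_evalue_ties(self):
        hits = [BlastHit("A1", "B1", 0.0, 400.0), BlastHit("A1", "B1", 0.0, 900.0)]
        (kept,) = blast_io.reduce_to_best_hsp(hits)
        assert kept.bitscore == 900.0

    def test_distinct_subjects_both_kept(self):
        hits = [BlastHit("A1", "B1", 1e-50, 100.0), BlastHit("A1", "B2", 1e-40, 90.0)]
        assert len(blast_io.reduce_to_best_hsp(hits)) == 2

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["A1", "A2"]),
                st.sampled_from(["B1", "B2", "B3"]),
                st.sampled_from([0.0, 1e-50, 1e-20, 1e-10]),
                st.sampled_from([50.0, 100.0, 200.0]),
            ),
            max_size=30,
        )
    )
    def test_idempotent_and_order_insensitive(self, rows):
        hits = [BlastHit(*r) for r in rows]
        once = blast_io.reduce_to_best_hsp(hits)
        assert blast_io.reduce_to_best_hsp(once) == once
        assert blast_io.reduce_to_best_hsp(list(reversed(hits))) == once


class TestFastaProteome:
    def test_accession_description_split(self):
        recs = blast_io.read_fasta_proteome(
            io.StringIO(">P1 myotubularin\nMKT\n"), "hs"
        )
        assert recs[0].accession == "P1"
        assert recs[0].description == "myotubularin"
        assert recs[0].length == 3

    def test_multiline_sequences_folded(self):
        recs = blast_io.read_fasta_proteome(io.StringIO(">P1\nMK\nTA\n"), "hs")
        assert recs[0].sequence == "MKTA"
        assert recs[0].description == ""

    def test_duplicate_accession_rejected(self):
        with pytest.raises(FastaError, match="P1"):
            blast_io.read_fasta_proteome(
                io.StringIO(">P1\nMKT\n>P1\nAAA\n"), "hs"
            )

    def test_digest_is_case_insensitive(self):
        assert blast_io.sequence_digest("mkta") == blast_io.sequence_digest("MKTA")
        assert blast_io.sequence_digest("MKTA") != blast_io.sequence_digest("MKTT")

    @given(
        st.lists(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=90),
            min_size=1,
            max_size=8,
        )
    )
    def test_round_trip(self, sequences):
        records = [
            blast_io.SequenceRecord(f"P{i}", f"desc {i}", "org", seq)
            for i, seq in enumerate(sequences)
        ]
        text = blast_io.write_fasta(records)
        back = blast_io.read_fasta_proteome(io.StringIO(text), "org")
        assert [(r.accession, r.sequence) for r in back] == [
            (r.accession, r.sequence) for r in records
        ]


class TestManifest:
    XML = (
        "<organisms>"
        '<organism id="hs"><name>Homo sapiens</name>'
        "<source>ensembl</source><taxid>9606</taxid></organism>"
        '<organism id="mm"><name>Mus musculus</name>'
        "<source>ensembl</source><taxid>10090</taxid></organism>"
        "</organisms>"
    )

    def test_xml_dialect(self):
        metas = blast_io.read_organism_manifest(self.XML, "xml")
        assert [m.organism_id for m in metas] == ["hs", "mm"]
        assert metas[0].taxid == "9606"

    def test_tsv_dialect(self):
        metas = blast_io.read_organism_manifest(
            "hs\tHomo sapiens\tensembl\t9606\n", "tsv"
        )
        assert metas == [
            blast_io.OrganismMeta("hs", "Homo sapiens", "ensembl", "9606")
        ]

    def test_duplicate_id_rejected(self):
        text = "hs\tA\ts\t1\nhs\tB\ts\t2\n"
        with pytest.raises(ManifestError, match="hs"):
            blast_io.read_organism_manifest(text, "tsv")

    def test_missing_field_rejected(self):
        xml = '<organisms><organism id="hs"><name>x</name></organism></organisms>'
        with pytest.raises(ManifestError, match="source"):
            blast_io.read_organism_manifest(xml, "xml")

    def test_round_trip_both_dialects(self):
        metas = blast_io.read_organism_manifest(self.XML, "xml")
        for dialect in ("xml", "tsv"):
            text = blast_io.write_organism_manifest(metas, dialect)
            assert blast_io.read_organism_manifest(text, dialect) == metas


class TestHitIndex:
    ACC_ORG = {"A1": "a", "A2": "a", "B1": "b", "B2": "b"}

    def test_ranking_order(self):
        hits = [
            BlastHit("A1", "B2", 1e-30, 100.0),
            BlastHit("A1", "B1", 1e-50, 100.0),
            BlastHit("A1", "A2", 1e-60, 100.0),
        ]
        index = HitIndex(hits, self.ACC_ORG)
        assert [h.subject_acc for h in index.hits_for("A1")] == [
            "A1",  # injected self-hit
            "A2",
            "B1",
            "B2",
        ]

    def test_self_hit_injected_at_rank_one(self):
        index = HitIndex([BlastHit("A1", "B1", 0.0, 900.0)], self.ACC_ORG)
        top = index.hits_for("A1")[0]
        assert top.subject_acc == "A1"
        assert top.evalue == 0.0
        assert math.isinf(top.bitscore)

    def test_proteins_without_hits_keep_empty_lists(self):
        index = HitIndex([BlastHit("A1", "B1", 1e-20, 50.0)], self.ACC_ORG)
        assert index.hits_for("A2") == ()
        assert index.accessions("a") == ["A1", "A2"]

    def test_unknown_subject_rejected(self):
        with pytest.raises(UnknownAccessionError, match="ZZ"):
            HitIndex([BlastHit("A1", "ZZ", 1e-20, 50.0)], self.ACC_ORG)

    def test_full_tie_broken_by_accession(self):
        hits = [
            BlastHit("A1", "B2", 0.0, 900.0),
            BlastHit("A1", "B1", 0.0, 900.0),
        ]
        index = HitIndex(hits, self.ACC_ORG)
        assert index.hits_in("A1", "b")[0].subject_acc == "B1"

    @given(st.permutations(range(6)))
    def test_order_invariant_under_input_permutation(self, perm):
        base = [
            BlastHit("A1", "B1", 1e-50, 100.0),
            BlastHit("A1", "B2", 1e-50, 200.0),
            BlastHit("A1", "A2", 0.0, 900.0),
            BlastHit("A2", "B1", 1e-10, 40.0),
            BlastHit("A2", "B2", 1e-10, 40.0),
            BlastHit("B1", "A1", 1e-30, 80.0),
        ]
        shuffled = [base[i] for i in perm]
        ref = HitIndex(base, self.ACC_ORG)
        alt = HitIndex(shuffled, self.ACC_ORG)
        for acc in self.ACC_ORG:
            assert ref.hits_for(acc) == alt.hits_for(acc)
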