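"""Store queries, normalization formulas, exports and persistence."""

import io
import xml.etree.ElementTree as ET

import networkx as nx
import pytest

from orthopair import store_query
from orthopair.errors import (
    ConfigurationError,
    ExportError,
    UnknownOrganismError,
)
from orthopair.relations import MANY_TO_MANY, ONE_TO_MANY, ONE_TO_ONE


class TestPresenceAbsence:
    def test_presence_and_absence_combined(self, toy_store):
        # X proteins with orthologs in y but not in z
        result = store_query.presence_absence_query(
            toy_store, "x", {"y": "presence", "z": "absence"}
        )
        assert result == ["X1"]  # X2/X3 relate to both, X4 to neither

    def test_absence_only_includes_relationless_proteins(self, toy_store):
        result = store_query.presence_absence_query(
            toy_store, "x", {"y": "absence"}
        )
        assert result == ["X4"]

    def test_presence_equals_direct_scan(self, toy_store):
        result = store_query.presence_absence_query(
            toy_store, "x", {"z": "presence"}
        )
        scan = sorted(
            acc
            for acc in toy_store.accessions("x")
            if "z" in toy_store.partner_organisms(acc)
        )
        assert result == scan == ["X2", "X3"]

    def test_unknown_organism_rejected(self, toy_store):
        with pytest.raises(UnknownOrganismError):
            store_query.presence_absence_query(
                toy_store, "x", {"nosuch": "presence"}
            )

    def test_all_uncaring_rejected(self, toy_store):
        with pytest.raises(ConfigurationError):
            store_query.presence_absence_query(toy_store, "x", {"y": "uncaring"})


class TestSequenceAndTextQueries:
    def test_exact_sequence_matches(self, toy_store):
        fasta = ">q1\nMKTAYIAKQR\n>q2 lower case\nmndlwqrtsa\n>q3 novel\nMWWWWWWWWW\n"
        result = store_query.query_by_sequence(toy_store, fasta)
        assert result == {"q1": "X1", "q2": "X2", "q3": None}

    def test_accession_exact_match(self, toy_store):
        assert store_query.query_by_text(toy_store, "X1", "accession") == ["X1"]
        assert store_query.query_by_text(toy_store, "nosuch", "accession") == []

    def test_description_substring_case_insensitive(self, toy_store):
        assert store_query.query_by_text(toy_store, "KINASE BETA", "description") == [
            "X2",
            "X3",
            "Y2",
            "Z1",
            "Z2",
        ]


class TestNormalizedRelationCounts:
    """Hand-computed values; proteome sizes are |x|=4, |y|=2, |z|=3."""

    def test_one_to_one_uses_smaller_proteome(self, toy_store):
        value = store_query.normalized_relation_counts(toy_store, "x", "y", ONE_TO_ONE)
        assert abs(value - 1 / 2) < 1e-12

    def test_one_to_many_is_oriented_and_uses_larger_proteome(self, toy_store):
        # the single 1-to-many has its singleton side in y
        y_to_x = store_query.normalized_relation_counts(toy_store, "y", "x", ONE_TO_MANY)
        x_to_y = store_query.normalized_relation_counts(toy_store, "x", "y", ONE_TO_MANY)
        assert abs(y_to_x - 1 / 4) < 1e-12
        assert x_to_y == 0.0

    def test_many_to_many_uses_proteome_product(self, toy_store):
        value = store_query.normalized_relation_counts(toy_store, "x", "z", MANY_TO_MANY)
        assert abs(value - 1 / 12) < 1e-12

    def test_pair_without_relations_is_zero(self, toy_store):
        for rel_type in (ONE_TO_ONE, ONE_TO_MANY, MANY_TO_MANY):
            assert store_query.normalized_relation_counts(
                toy_store, "y", "z", rel_type
            ) == 0.0


class TestExports:
    def test_relations_csv_layout(self, toy_store):
        text = store_query.export(toy_store, "relations", "csv")
        lines = text.splitlines()
        assert lines[0] == (
            "org_a,org_b,type,members_a,members_b,n_signals_red,n_signals_orange"
        )
        assert 'x,y,ONE_TO_ONE,X1,Y1,0,0' in lines
        assert 'x,z,MANY_TO_MANY,"X2,X3","Z1,Z2",0,0' in lines

    def test_relations_xml_parses_back(self, toy_store):
        root = ET.fromstring(store_query.export(toy_store, "relations", "xml"))
        assert root.tag == "relations"
        types = {el.get("type") for el in root.findall("relation")}
        assert types == {ONE_TO_ONE, ONE_TO_MANY, MANY_TO_MANY}

    def test_groups_exports(self, toy_store):
        csv_text = store_query.export(toy_store, "groups", "csv")
        assert "x,y,full,\"X2,X3\"" in csv_text
        root = ET.fromstring(store_query.export(toy_store, "groups", "xml"))
        members = {
            tuple(m.text for m in el.findall("member"))
            for el in root.findall("group")
        }
        assert ("X2", "X3") in members

    def test_sequences_fasta_round_trip(self, toy_store):
        from orthopair.blast_io import read_fasta_proteome

        text = store_query.export(toy_store, "sequences", "fasta")
        # one organism at a time: accessions grouped by organism prefix here
        accs = [
            line[1:].split()[0] for line in text.splitlines() if line.startswith(">")
        ]
        assert accs == sorted(toy_store.accessions(), key=lambda a: (a[0], a))

    def test_pa_matrix_cells(self, toy_store):
        text = store_query.export(toy_store, "pa_matrix", "csv")
        rows = {line.split(",")[0]: line.split(",")[1:] for line in text.splitlines()[1:]}
        header = store_query.export(toy_store, "pa_matrix", "csv").splitlines()[0]
        assert header == "accession,x,y,z"
        assert rows["X1"] == ["0", "1", "0"]   # 1-to-1 with y
        assert rows["X2"] == ["0", "M", "MM"]  # co-ortholog set to y, m-m to z
        assert rows["X4"] == ["0", "0", "0"]   # no relations at all
        assert rows["Y2"] == ["M", "0", "0"]

    def test_pa_matrix_row_subset(self, toy_store):
        text = store_query.export(
            toy_store, "pa_matrix", "csv", accessions=["X2"]
        )
        assert len(text.splitlines()) == 2

    def test_graphml_structure(self, toy_store):
        text = store_query.export(toy_store, "graph", "graphml")
        g = nx.parse_graphml(text)
        assert g.nodes["X1"]["organism"] == "x"
        assert g.edges["X1", "Y1"]["type"] == ONE_TO_ONE
        assert g.edges["X2", "Z1"]["type"] == MANY_TO_MANY
        assert "X4" not in g  # relation-less proteins stay out of the graph

    def test_unsupported_combination_rejected(self, toy_store):
        with pytest.raises(ExportError):
            store_query.export(toy_store, "sequences", "xml")

    def test_exports_are_deterministic(self, toy_store):
        for what, fmt in (
            ("relations", "csv"),
            ("relations", "xml"),
            ("groups", "csv"),
            ("sequences", "fasta"),
            ("pa_matrix", "csv"),
            ("graph", "graphml"),
        ):
            a = store_query.export(toy_store, what, fmt)
            b = store_query.export(toy_store, what, fmt)
            assert a == b


class TestPersistence:
    def test_round_trip_preserves_query_answers(self, toy_store, tmp_path):
        path = tmp_path / "store.json"
        toy_store.save(path)
        back = store_query.RelationStore.load(path)
        assert back.accessions() == toy_store.accessions()
        assert store_query.presence_absence_query(
            back, "x", {"y": "presence", "z": "absence"}
        ) == store_query.presence_absence_query(
            toy_store, "x", {"y": "presence", "z": "absence"}
        )
        for what, fmt in (("relations", "csv"), ("groups", "csv"), ("pa_matrix", "csv")):
            assert store_query.export(back, what, fmt) == store_query.export(
                toy_store, what, fmt
            )

    def test_saved_bytes_are_deterministic(self, toy_store, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        toy_store.save(p1)
        store_query.RelationStore.load(p1).save(p2)
        assert p1.read_bytes() == p2.read_bytes()
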