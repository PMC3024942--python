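"""Shared fixtures: parsed myotubularin dataset and a hand-built toy store."""

from __future__ import annotations

import io

import pytest
from hypothesis import settings

from orthopair import blast_io, store_query
from orthopair.fixtures import generate_myotubularin_fixture
from orthopair.inparalog_core import ValidatedGroup
from orthopair.relations import (
    GROUP,
    MANY_TO_MANY,
    ONE_TO_MANY,
    ONE_TO_ONE,
    SINGLETON,
    Entity,
    OrthologyRelation,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def myotubularin_inputs():
    """Parsed manifest, proteomes and hits of the myotubularin example."""
    fx = generate_myotubularin_fixture()
    metas = blast_io.read_organism_manifest(fx.manifest_xml, "xml")
    proteomes = {
        org: blast_io.read_fasta_proteome(io.StringIO(text), org)
        for org, text in fx.proteomes.items()
    }
    hits = blast_io.parse_blast_tabular(io.StringIO(fx.blast_tabular))
    return metas, proteomes, hits


@pytest.fixture(scope="session")
def myotubularin_store(myotubularin_inputs):
    metas, proteomes, hits = myotubularin_inputs
    return store_query.build_store(metas, proteomes, hits)


def _record(acc: str, org: str, seq: str, description: str = ""):
    return blast_io.SequenceRecord(
        accession=acc, description=description, organism_id=org, sequence=seq
    )


@pytest.fixture(scope="session")
def toy_store():
    """Three organisms with one relation of each type, placed by hand.

    x has 4 proteins, y has 2, z has 3.  Relations: X1<->Y1 one-to-one;
    Y2 (singleton) to the group {X2, X3} one-to-many; group {X2, X3} to
    group {Z1, Z2} many-to-many.
    """
    organisms = [
        blast_io.OrganismMeta("x", "Organism X", "synthetic", "1"),
        blast_io.OrganismMeta("y", "Organism Y", "synthetic", "2"),
        blast_io.OrganismMeta("z", "Organism Z", "synthetic", "3"),
    ]
    seqs = [
        _record("X1", "x", "MKTAYIAKQR", "kinase alpha"),
        _record("X2", "x", "MNDLWQRTSA", "kinase beta"),
        _record("X3", "x", "MHHGLLVRRT", "kinase beta prime"),
        _record("X4", "x", "MAACDEFGHI", "orphan"),
        _record("Y1", "y", "MKTAYIAKQQ", "kinase alpha"),
        _record("Y2", "y", "MNDLWQRTSV", "kinase beta"),
        _record("Z1", "z", "MNDLWQKTSA", "kinase beta"),
        _record("Z2", "z", "MNDLWQKTSL", "kinase beta-like"),
        _record("Z3", "z", "MPPPQRSTVW", "orphan"),
    ]
    gx_y = ValidatedGroup("x", "y", frozenset({"X2", "X3"}), "full")
    gx_z = ValidatedGroup("x", "z", frozenset({"X2", "X3"}), "full")
    gz_x = ValidatedGroup("z", "x", frozenset({"Z1", "Z2"}), "full")
    groups = {("x", "y"): [gx_y], ("x", "z"): [gx_z], ("z", "x"): [gz_x]}

    def singleton(org, acc, rel_to):
        return Entity(org, SINGLETON, frozenset({acc}), rel_to)

    rel_11 = OrthologyRelation(
        ONE_TO_ONE,
        singleton("x", "X1", "y"),
        singleton("y", "Y1", "x"),
        (("X1", "Y1"), ("Y1", "X1")),
    )
    rel_1m = OrthologyRelation(
        ONE_TO_MANY,
        Entity("x", GROUP, gx_y.members, "y"),
        singleton("y", "Y2", "x"),
        (("Y2", "X2"), ("X2", "Y2")),
    )
    rel_mm = OrthologyRelation(
        MANY_TO_MANY,
        Entity("x", GROUP, gx_z.members, "z"),
        Entity("z", GROUP, gz_x.members, "x"),
        (("X2", "Z1"), ("Z1", "X2")),
    )
    relations = {
        ("x", "y"): [rel_11, rel_1m],
        ("x", "z"): [rel_mm],
        ("y", "z"): [],
    }
    return store_query.RelationStore(organisms, seqs, groups, relations)
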