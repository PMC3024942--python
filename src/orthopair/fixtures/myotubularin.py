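"""The myotubularin-family worked example.

The myotubularin lipid-phosphatase family is a classic hard case for
graph-based orthology inference: a single yeast gene (Sc-MTM) faces eight
human paralogs (Hs-MTM, Hs-R1...Hs-R4, Hs-R6...Hs-R8) and three fly paralogs
(Dm-R1-2, Dm-R3-4, Dm-R6-7-8), all produced by duplications after the
yeast split.  RBH-anchored methods lose the most divergent human members;
inparalog-group comparison keeps them all.

This module emits a deterministic three-organism dataset (proteome FASTA,
BLAST tabular, manifest) whose synthetic E-values realise that topology:

* every human protein ranks all eight human myotubularins above any
  non-human hit, and every fly protein ranks the three fly proteins above
  any non-fly hit — so one inparalog group of 8 (human) and one of 3 (fly)
  w.r.t. yeast fully validate;
* cross-organism best hits pair each protein with its subfamily counterpart
  (MTM/R1/R2 <-> Dm-R1-2, R3/R4 <-> Dm-R3-4, R6/R7/R8 <-> Dm-R6-7-8) and the
  yeast protein with Hs-MTM / Dm-R1-2, giving the reciprocal best hits
  Sc-MTM <-> Hs-MTM, Sc-MTM <-> Dm-R1-2, Hs-R1 <-> Dm-R1-2, Hs-R3 <-> Dm-R3-4
  and Hs-R6 <-> Dm-R6-7-8;
* expected inference: a 1-to-many relation linking Sc-MTM to all 8 human
  members, a 1-to-many linking Sc-MTM to all 3 fly members, and a
  many-to-many linking the human and fly groups — with zero warning signals.

Sequences are random amino-acid strings (the inference consumes only the hit
table); they exist to exercise FASTA I/O and digest queries.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

HUMAN = ["Hs-MTM", "Hs-R1", "Hs-R2", "Hs-R3", "Hs-R4", "Hs-R6", "Hs-R7", "Hs-R8"]
FLY = ["Dm-R1-2", "Dm-R3-4", "Dm-R6-7-8"]
YEAST = ["Sc-MTM"]

_ORGANISM_OF = {
    **{acc: "hs" for acc in HUMAN},
    **{acc: "dm" for acc in FLY},
    **{acc: "sc" for acc in YEAST},
}

#: Subfamily counterpart in fly for each human protein (forward best hit).
_HUMAN_TO_FLY = {
    "Hs-MTM": "Dm-R1-2",
    "Hs-R1": "Dm-R1-2",
    "Hs-R2": "Dm-R1-2",
    "Hs-R3": "Dm-R3-4",
    "Hs-R4": "Dm-R3-4",
    "Hs-R6": "Dm-R6-7-8",
    "Hs-R7": "Dm-R6-7-8",
    "Hs-R8": "Dm-R6-7-8",
}

#: Best human hit of each fly protein (return arrows).
_FLY_TO_HUMAN = {
    "Dm-R1-2": "Hs-R1",
    "Dm-R3-4": "Hs-R3",
    "Dm-R6-7-8": "Hs-R6",
}

_DESCRIPTIONS = {
    "Hs-MTM": "myotubularin",
    "Hs-R1": "myotubularin-related protein 1",
    "Hs-R2": "myotubularin-related protein 2",
    "Hs-R3": "myotubularin-related protein 3",
    "Hs-R4": "myotubularin-related protein 4",
    "Hs-R6": "myotubularin-related protein 6",
    "Hs-R7": "myotubularin-related protein 7",
    "Hs-R8": "myotubularin-related protein 8",
    "Dm-R1-2": "myotubularin-related, MTMR1/2 subfamily",
    "Dm-R3-4": "myotubularin-related, MTMR3/4 subfamily",
    "Dm-R6-7-8": "myotubularin-related, MTMR6/7/8 subfamily",
    "Sc-MTM": "myotubularin-like phosphatase",
}


@dataclass(frozen=True)
class Fixture:
    """The three input artifacts of one analysis, as text."""

    manifest_xml: str
    proteomes: dict[str, str]  # organism id -> FASTA text
    blast_tabular: str


def _sequence(accession: str, length: int = 240) -> str:
    rng = random.Random(f"myotubularin:{accession}")
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _ranked_subjects(query: str) -> list[str]:
    """Full ranked subject list of one query (self first)."""
    org = _ORGANISM_OF[query]
    if org == "hs":
        same = [query] + [a for a in HUMAN if a != query]
        fly_best = _HUMAN_TO_FLY[query]
        cross = [fly_best] + [a for a in FLY if a != fly_best] + YEAST
    elif org == "dm":
        same = [query] + [a for a in FLY if a != query]
        human_best = _FLY_TO_HUMAN[query]
        cross = [human_best] + [a for a in HUMAN if a != human_best] + YEAST
    else:  # yeast
        same = [query]
        cross = (
            ["Hs-MTM"]
            + [a for a in HUMAN if a != "Hs-MTM"]
            + ["Dm-R1-2"]
            + [a for a in FLY if a != "Dm-R1-2"]
        )
    return same + cross


def _blast_rows() -> list[str]:
    rows: list[str] = []
    for query in HUMAN + FLY + YEAST:
        for rank, subject in enumerate(_ranked_subjects(query)):
            if subject == query:
                evalue, bitscore, pident = 0.0, 2500.0, 100.0
            else:
                # strictly increasing E-values down the list; all <= 1e-9
                evalue = 10.0 ** -(170 - 8 * rank)
                bitscore = round(1500.0 - 10.0 * rank, 1)
                pident = round(90.0 - rank, 1)
            rows.append(
                "\t".join(
                    [
                        query,
                        subject,
                        f"{pident:.1f}",
                        "230",
                        "20",
                        "2",
                        "1",
                        "230",
                        "1",
                        "230",
                        f"{evalue:.1e}" if evalue else "0.0",
                        f"{bitscore:.1f}",
                    ]
                )
            )
    return rows


def generate_myotubularin_fixture() -> Fixture:
    """Deterministic myotubularin-family dataset (see module docstring)."""
    manifest = (
        '<organisms>\n'
        '  <organism id="hs">\n'
        "    <name>Homo sapiens</name>\n"
        "    <source>synthetic</source>\n"
        "    <taxid>9606</taxid>\n"
        "  </organism>\n"
        '  <organism id="dm">\n'
        "    <name>Drosophila melanogaster</name>\n"
        "    <source>synthetic</source>\n"
        "    <taxid>7227</taxid>\n"
        "  </organism>\n"
        '  <organism id="sc">\n'
        "    <name>Saccharomyces cerevisiae</name>\n"
        "    <source>synthetic</source>\n"
        "    <taxid>559292</taxid>\n"
        "  </organism>\n"
        "</organisms>\n"
    )
    proteomes: dict[str, str] = {}
    for org, accs in (("hs", HUMAN), ("dm", FLY), ("sc", YEAST)):
        lines = []
        for acc in accs:
            lines.append(f">{acc} {_DESCRIPTIONS[acc]}")
            seq = _sequence(acc)
            lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        proteomes[org] = "\n".join(lines) + "\n"
    blast = "\n".join(_blast_rows()) + "\n"
    return Fixture(manifest_xml=manifest, proteomes=proteomes, blast_tabular=blast)


def write_fixture(fixture: Fixture, directory: str | Path) -> None:
    """Materialize a fixture as a ready-to-build input directory."""
    directory = Path(directory)
    (directory / "proteomes").mkdir(parents=True, exist_ok=True)
    (directory / "blast").mkdir(parents=True, exist_ok=True)
    (directory / "manifest.xml").write_text(fixture.manifest_xml)
    for org, fasta in fixture.proteomes.items():
        (directory / "proteomes" / f"{org}.fasta").write_text(fasta)
    (directory / "blast" / "all_vs_all.tsv").write_text(fixture.blast_tabular)
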