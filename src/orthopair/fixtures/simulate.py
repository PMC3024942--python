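"""Gene-family simulator with exact ground truth.

The simulator evolves independent gene families down a *caterpillar* species
tree: organisms are listed in splitting order, speciation ``i`` detaches
organism ``i`` from the remaining clade at depth ``10*(i+1)``, and all leaves
are sampled at the same final time.  Duplication events are placed on named
branches — a branch is addressed by the tuple of organisms below it, so with
organisms ``("A", "B")`` the address ``("A",)`` is A's terminal branch
(duplication *after* the A/B split: inparalogs) and ``("A", "B")`` is the
root branch (duplication *before* the split: outparalogs).  No gene loss is
modelled; every lineage survives to the leaves.

Truth is derived solely from the simulated gene tree, never from scores:
two genes of organisms X and Y are orthologs exactly when their last common
ancestor is the X/Y speciation node, and the true inparalog groups of X
w.r.t. Y are the cells of X's genes sharing an ancestor at that node.

Similarity scores equal the divergence time of the gene pair (later
divergence = more similar), plus a small per-pair deterministic jitter that
keeps ranks distinct without ever reordering genuinely different distances,
plus optional Gaussian noise of magnitude ``epsilon``.  Scores are mapped to
E-values through a fixed strictly decreasing exponential, so at ``epsilon=0``
the BLAST table is strictly monotone in true evolutionary distance and the
inference pipeline must recover the truth exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from ..blast_io import OrganismMeta, write_organism_manifest
from ..errors import ConfigurationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Depth spacing between successive speciations.
_DEPTH_STEP = 10.0
#: Jitter band; strictly below the smallest possible distance gap.
_JITTER_SPAN = 0.4
#: Per-branch duplication budget keeping duplication-time gaps above the jitter.
_MAX_EVENTS_PER_BRANCH = 20


@dataclass(frozen=True)
class Duplication:
    """``count`` duplications on the branch above ``branch`` (a clade tuple),
    affecting family ``family``."""

    branch: tuple[str, ...]
    count: int = 1
    family: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    organisms: tuple[str, ...]
    duplications: tuple[Duplication, ...] = ()
    n_families: int = 1
    epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.organisms) < 2:
            raise ConfigurationError("at least two organisms are required")
        if len(set(self.organisms)) != len(self.organisms):
            raise ConfigurationError("organism ids must be unique")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be >= 0")
        valid = self._valid_branches()
        budget: dict[tuple[tuple[str, ...], int], int] = {}
        for dup in self.duplications:
            if dup.branch not in valid:
                raise ConfigurationError(
                    f"branch {dup.branch!r} is not a branch of the caterpillar "
                    f"tree over {self.organisms!r}"
                )
            if dup.count < 1:
                raise ConfigurationError("duplication count must be >= 1")
            if not 0 <= dup.family < self.n_families:
                raise ConfigurationError(
                    f"duplication family {dup.family} out of range"
                )
            key = (dup.branch, dup.family)
            budget[key] = budget.get(key, 0) + dup.count
            if budget[key] > _MAX_EVENTS_PER_BRANCH:
                raise ConfigurationError(
                    f"more than {_MAX_EVENTS_PER_BRANCH} duplications on "
                    f"branch {dup.branch!r}"
                )

    def _valid_branches(self) -> set[tuple[str, ...]]:
        branches = {(org,) for org in self.organisms}
        for i in range(len(self.organisms) - 1):
            branches.add(tuple(self.organisms[i:]))
        return branches


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of one simulation, derived from the gene tree only.

    ``groups`` maps each ordered (organism, target organism) pair to the
    frozenset of true inparalog groups (member sets of size >= 2).
    ``relations`` maps each unordered organism pair, keyed ``(min, max)``,
    to the set of ``(type, members_of_first, members_of_second)`` triples.
    """

    groups: dict[tuple[str, str], frozenset[frozenset[str]]]
    relations: dict[tuple[str, str], frozenset[tuple[str, frozenset[str], frozenset[str]]]]


@dataclass(frozen=True)
class SimulationResult:
    config: SimulationConfig
    manifest_xml: str
    proteomes: dict[str, str]  # organism id -> FASTA text
    blast_tabular: str
    truth: TruthSet
    accession_to_organism: dict[str, str] = field(default_factory=dict)


class _Node:
    """Gene-tree branching event (speciation copy or duplication)."""

    __slots__ = ("time", "parent")

    def __init__(self, time: float, parent: "_Node | None") -> None:
        self.time = time
        self.parent = parent


@dataclass(frozen=True)
class _Leaf:
    accession: str
    organism: str
    family: int
    attachment: _Node


def _ancestor_at(leaf: _Leaf, time: float) -> _Node:
    node = leaf.attachment
    while node.time > time:
        assert node.parent is not None
        node = node.parent
    return node


def _lca_time(x: _Leaf, y: _Leaf) -> float:
    ancestors: dict[int, float] = {}
    node: _Node | None = x.attachment
    while node is not None:
        ancestors[id(node)] = node.time
        node = node.parent
    node = y.attachment
    while node is not None:
        if id(node) in ancestors:
            return node.time
        node = node.parent
    raise ValueError("leaves of different families share no ancestor")


def _simulate_family(cfg: SimulationConfig, fam: int) -> list[_Leaf]:
    organisms = cfg.organisms
    n = len(organisms)
    leaf_time = _DEPTH_STEP * n
    leaves: list[_Leaf] = []

    def split_time(clade: tuple[str, ...]) -> float:
        # clade = organisms[i:], its next speciation detaches organisms[i]
        i = organisms.index(clade[0])
        return _DEPTH_STEP * (i + 1)

    def descend(clade: tuple[str, ...], t_start: float, tips: list[_Node]) -> None:
        t_end = leaf_time if len(clade) == 1 else split_time(clade)
        total = sum(
            d.count
            for d in cfg.duplications
            if d.branch == clade and d.family == fam
        )
        tips = list(tips)
        if total:
            delta = (t_end - t_start) / (total + 1)
            for j in range(total):
                t = t_start + (j + 1) * delta
                src = tips[j % len(tips)]
                node = _Node(t, src)
                tips[j % len(tips)] = node
                tips.append(node)
        if len(clade) == 1:
            org = clade[0]
            for idx, tip in enumerate(tips, start=1):
                leaves.append(
                    _Leaf(f"{org}-f{fam}g{idx}", org, fam, tip)
                )
            return
        copies = [_Node(t_end, tip) for tip in tips]
        descend((clade[0],), t_end, copies)
        descend(clade[1:], t_end, copies)

    root = _Node(0.0, None)
    descend(organisms, 0.0, [root])
    return leaves


def _derive_truth(cfg: SimulationConfig, leaves: list[_Leaf]) -> TruthSet:
    organisms = cfg.organisms
    by_org: dict[str, list[_Leaf]] = {org: [] for org in organisms}
    for leaf in leaves:
        by_org[leaf.organism].append(leaf)

    groups: dict[tuple[str, str], frozenset[frozenset[str]]] = {}
    relations: dict[
        tuple[str, str], frozenset[tuple[str, frozenset[str], frozenset[str]]]
    ] = {}

    def cells_at(org: str, time: float) -> dict[int, set[str]]:
        cells: dict[int, set[str]] = {}
        for leaf in by_org[org]:
            cells.setdefault(id(_ancestor_at(leaf, time)), set()).add(
                leaf.accession
            )
        return cells

    for i, org_x in enumerate(organisms):
        for j, org_y in enumerate(organisms):
            if i == j:
                continue
            ts = _DEPTH_STEP * (min(i, j) + 1)
            cells = cells_at(org_x, ts)
            groups[(org_x, org_y)] = frozenset(
                frozenset(cell) for cell in cells.values() if len(cell) >= 2
            )

    for i, org_x in enumerate(organisms):
        for j in range(i + 1, len(organisms)):
            org_y = organisms[j]
            ts = _DEPTH_STEP * (i + 1)
            cells_x = cells_at(org_x, ts)
            cells_y = cells_at(org_y, ts)
            key = (min(org_x, org_y), max(org_x, org_y))
            first, second = key
            rels: set[tuple[str, frozenset[str], frozenset[str]]] = set()
            for anc, sx in cells_x.items():
                sy = cells_y.get(anc)
                if not sy:
                    continue
                if len(sx) == 1 and len(sy) == 1:
                    rel_type = "ONE_TO_ONE"
                elif len(sx) == 1 or len(sy) == 1:
                    rel_type = "ONE_TO_MANY"
                else:
                    rel_type = "MANY_TO_MANY"
                side_x, side_y = frozenset(sx), frozenset(sy)
                if first == org_x:
                    rels.add((rel_type, side_x, side_y))
                else:
                    rels.add((rel_type, side_y, side_x))
            relations[key] = frozenset(rels)
    return TruthSet(groups=groups, relations=relations)


def _score_table(
    cfg: SimulationConfig, leaves: list[_Leaf]
) -> dict[tuple[str, str], float]:
    """Ordered-pair similarity scores (within each family only)."""
    by_family: dict[int, list[_Leaf]] = {}
    for leaf in leaves:
        by_family.setdefault(leaf.family, []).append(leaf)
    pairs: list[tuple[_Leaf, _Leaf]] = []
    for fam in sorted(by_family):
        fam_leaves = sorted(by_family[fam], key=lambda l: l.accession)
        for x in fam_leaves:
            for y in fam_leaves:
                if x.accession != y.accession:
                    pairs.append((x, y))
    rng = random.Random(cfg.seed) if cfg.epsilon > 0 else None
    scores: dict[tuple[str, str], float] = {}
    n_pairs = len(pairs)
    for idx, (x, y) in enumerate(pairs):
        score = _lca_time(x, y) + _JITTER_SPAN * (idx + 1) / (n_pairs + 1)
        if rng is not None:
            score += rng.gauss(0.0, cfg.epsilon)
        scores[(x.accession, y.accession)] = score
    return scores


def _blast_text(
    cfg: SimulationConfig,
    leaves: list[_Leaf],
    scores: dict[tuple[str, str], float],
) -> str:
    leaf_time = _DEPTH_STEP * len(cfg.organisms)
    rows: list[str] = []
    accessions = sorted(leaf.accession for leaf in leaves)
    ordered = sorted(
        scores.items(), key=lambda kv: (kv[0][0], -kv[1], kv[0][1])
    )
    by_query: dict[str, list[tuple[str, float]]] = {}
    for (q, s), score in ordered:
        by_query.setdefault(q, []).append((s, score))
    for q in accessions:
        rows.append(
            f"{q}\t{q}\t100.0\t200\t0\t0\t1\t200\t1\t200\t0.0\t4000.0"
        )
        for s, score in by_query.get(q, []):
            exponent = 10.0 + 140.0 * (score / leaf_time)
            exponent = min(max(exponent, 1.0), 300.0)
            evalue = 10.0 ** -exponent
            bitscore = round(20.0 + 2.0 * score, 4)
            pident = round(min(99.0, 30.0 + score), 2)
            rows.append(
                f"{q}\t{s}\t{pident}\t200\t10\t1\t1\t200\t1\t200\t"
                f"{evalue:.6e}\t{bitscore}"
            )
    return "\n".join(rows) + "\n"


def _fasta_text(accessions: list[str], organism: str) -> str:
    lines: list[str] = []
    for acc in accessions:
        rng = random.Random(f"simulated:{acc}")
        length = 120 + rng.randrange(120)
        seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
        lines.append(f">{acc} simulated family member ({organism})")
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(lines) + "\n"


def simulate_proteomes(config: SimulationConfig) -> SimulationResult:
    """Run one simulation and emit the input artifacts plus the truth.

    Byte-identical output for identical configs (the seed only feeds the
    score noise, so at ``epsilon=0`` the output is seed-independent).
    """
    leaves: list[_Leaf] = []
    for fam in range(config.n_families):
        leaves.extend(_simulate_family(config, fam))
    truth = _derive_truth(config, leaves)
    scores = _score_table(config, leaves)

    by_org: dict[str, list[str]] = {org: [] for org in config.organisms}
    for leaf in leaves:
        by_org[leaf.organism].append(leaf.accession)
    proteomes = {
        org: _fasta_text(sorted(accs), org) for org, accs in by_org.items()
    }
    metas = [
        OrganismMeta(org, f"Simulated organism {org}", "simulated", str(1000 + i))
        for i, org in enumerate(config.organisms)
    ]
    return SimulationResult(
        config=config,
        manifest_xml=write_organism_manifest(metas, "xml"),
        proteomes=proteomes,
        blast_tabular=_blast_text(config, leaves, scores),
        truth=truth,
        accession_to_organism={
            leaf.accession: leaf.organism for leaf in leaves
        },
    )


def write_simulation(result: SimulationResult, directory: str | Path) -> None:
    """Materialize a simulation as a ready-to-build directory + truth TSVs."""
    directory = Path(directory)
    (directory / "proteomes").mkdir(parents=True, exist_ok=True)
    (directory / "blast").mkdir(parents=True, exist_ok=True)
    (directory / "manifest.xml").write_text(result.manifest_xml)
    for org, fasta in result.proteomes.items():
        (directory / "proteomes" / f"{org}.fasta").write_text(fasta)
    (directory / "blast" / "all_vs_all.tsv").write_text(result.blast_tabular)
    lines = ["organism\ttarget_organism\tmembers\n"]
    for key in sorted(result.truth.groups):
        for members in sorted(result.truth.groups[key], key=sorted):
            lines.append(f"{key[0]}\t{key[1]}\t" + ",".join(sorted(members)) + "\n")
    (directory / "truth_groups.tsv").write_text("".join(lines))
    lines = ["org_a\torg_b\ttype\tmembers_a\tmembers_b\n"]
    for key in sorted(result.truth.relations):
        for rel_type, sa, sb in sorted(
            result.truth.relations[key],
            key=lambda t: (t[0], sorted(t[1]), sorted(t[2])),
        ):
            lines.append(
                f"{key[0]}\t{key[1]}\t{rel_type}\t"
                + ",".join(sorted(sa))
                + "\t"
                + ",".join(sorted(sb))
                + "\n"
            )
    (directory / "truth_relations.tsv").write_text("".join(lines))


def default_config_grid() -> list[SimulationConfig]:
    """The packaged grid of noiseless study conditions.

    Covers: no duplication (pure 1-to-1), a terminal-branch duplication
    (1-to-many), an ancestral duplication (outparalogs: two separate 1-to-1
    lineages), duplications in both lineages (many-to-many), an
    internal-branch duplication (inparalogs w.r.t. the outgroup only), and
    larger mixed multi-family trees.
    """
    return [
        SimulationConfig(organisms=("A", "B"), n_families=2),
        SimulationConfig(
            organisms=("A", "B"),
            duplications=(Duplication(branch=("A",)),),
        ),
        SimulationConfig(
            organisms=("A", "B"),
            duplications=(Duplication(branch=("A", "B")),),
        ),
        SimulationConfig(
            organisms=("A", "B"),
            duplications=(
                Duplication(branch=("A",), count=2),
                Duplication(branch=("B",)),
            ),
        ),
        SimulationConfig(
            organisms=("A", "B", "C"),
            duplications=(Duplication(branch=("B", "C")),),
        ),
        SimulationConfig(
            organisms=("A", "B", "C"),
            duplications=(
                Duplication(branch=("A",), count=2),
                Duplication(branch=("C",)),
                Duplication(branch=("B", "C")),
            ),
            n_families=2,
        ),
        SimulationConfig(
            organisms=("A", "B", "C", "D"),
            duplications=(
                Duplication(branch=("C", "D"), family=0),
                Duplication(branch=("B",), family=0),
                Duplication(branch=("D",), count=2, family=1),
            ),
            n_families=2,
        ),
        SimulationConfig(
            organisms=("A", "B", "C", "D", "E"),
            duplications=(
                Duplication(branch=("B", "C", "D", "E")),
                Duplication(branch=("A",)),
                Duplication(branch=("E",), count=2),
                Duplication(branch=("D", "E")),
            ),
        ),
    ]
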