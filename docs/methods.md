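# Methods

## Model and procedure

`orthopair` infers orthology and inparalogy from a protein BLAST
all-versus-all search over a set of proteomes. The only signal consumed is
the per-protein ranked hit list; no alignments or trees are built. The
method rests on two assumptions: (i) E-values rank evolutionary proximity
well enough that, for a protein of organism A, everything of A ranked above
the best hit in organism B diverged after the A/B speciation; (ii) an
inparalog hypothesis is only trustworthy when every implicated protein's
own BLAST output confirms it.

**Step 1 — groups.** For each protein *p* of A and each other organism B in
which *p* has at least one hit, the boundary is the E-value of *p*'s best
hit in B; the putative inparalog group of *p* w.r.t. B is *p* plus every
protein of A with E-value strictly below the boundary. "Strictly" is a
deliberate, conservative reading: a protein tying the boundary E-value is
excluded. Putative groups are deduplicated by member set, then validated:
the group stands iff each member's own putative set w.r.t. B equals it
(order-insensitive). On failure, every mutually-confirmed member pair
(each contains the other in its putative set) becomes a candidate;
candidates are accepted greedily in order of the *weaker* of their two
cross E-values (max of the pair, ties lexicographic), discarding candidates
that touch an accepted pair, so surviving pairs are disjoint. The greedy
similarity-first rule is our generalization for overlapping rescue pairs;
only the single-pair case is forced by the validation principle. Fully
validated groups take precedence: fallback never runs over their members,
which keeps the per-(A, B) groups pairwise disjoint.

**Step 2 — relations.** Per organism pair, each side is partitioned into
entities: its validated groups w.r.t. the partner, and all remaining
proteins as singletons (a grouped protein never doubles as a singleton for
that pair). Relations are typed from plain best hits — the top-ranked
cross-organism hit, *not* the group boundary hit: 1-to-1 needs a reciprocal
best hit between singletons; 1-to-many needs a best hit from the singleton
into the group and a returning best hit from any member; many-to-many needs
one best hit in each direction between the two groups (the literal
two-hits reading; reciprocity between the groups as a pair is not
required).

**Step 3 — signals.** For every member of a group-side entity whose best
hit in the partner organism lands outside both entities, the relation gets
a warning: red when that outside protein's best hit points straight back at
the member, orange otherwise. Signals are annotations for the user; they
veto nothing.

## Ranking, ties and degenerate inputs

Hits are ranked by (E-value ↑, bit score ↓, subject accession ↑). The bit
score refinement matters because real BLAST saturates E-values at 0.0; the
accession tie-break makes every downstream result invariant under input
permutation. An optional `surface_ties` switch returns *all* subjects
co-ranked at identical (E-value, bit score) and widens the existential
checks in step 2/3; default off, so a tie resolves deterministically to one
subject. Multiple HSPs per protein pair are reduced to the best one
(minimal E-value, then maximal bit score) before anything else. A query
missing from its own hit list receives an injected self-hit (E-value 0,
infinite-bit-score sentinel) so it is rank 1 of its own list, as an
all-versus-all search guarantees in practice; proteins absent from the
BLAST results entirely are retained as permanent singletons. A protein that
appears as a *subject* inside someone's putative group while having no
query output of its own is treated as an input inconsistency and raises an
error rather than being silently guessed around.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `evalue_cutoff` | 1e-9 | parse-time hit threshold, the conventional proteome-scale choice |
| `min_len`, `max_len` | 20, 10000 | residue window; fragments and concatenation artifacts are excluded, bounds inclusive |
| `identity_threshold` | 99.0 | redundancy collapse requires identity strictly above this (percent) |
| `coverage_threshold` | 0.9 | fraction of the *shorter* sequence the >99%-identity alignment must cover |
| `surface_ties` | off | surface all co-ranked best hits instead of one |

The coverage requirement accompanies the 99% identity rule because BLAST
identity is local: two distinct multi-domain proteins sharing one
near-identical domain should not collapse. 0.9 of the shorter sequence is a
documented judgement call, configurable. Redundancy edges come from the
supplied within-organism hits (no internal aligner); within each connected
component the longest sequence survives, ties broken by smallest accession.
Source-database priority rules (e.g. preferring curated entries) are out of
scope — the inputs carry no source annotation per sequence.

## Persistence and exports

Results live in a single-file JSON store (`orthopair-store` v1) with stable
sort keys, so saving, reloading and re-saving is byte-identical. Exports:
relation/group tables (CSV with RFC-4180 quoting and `\n` terminators, or
XML), sequences (FASTA), a presence/absence matrix (CSV; cells `0` absent,
`1` one-to-one, `M` member of a 1-to-many co-ortholog set, `MM`
many-to-many, strongest code winning when several apply; the own-organism
cell is `0`), and the relation network as graphML (nodes = proteins that
participate in at least one relation, with an organism attribute; edges =
member pairs of each relation with type and signal counts). The
presence/absence *query* counts any relation type as presence, including
co-orthology through a group, because a lineage-specific expansion is still
orthology.

## Synthetic data

The simulator evolves gene families down a caterpillar species tree
(speciations at depths 10, 20, …; ultrametric leaves). Duplication events
are placed on named branches — `("A",)` after the last split involving A,
`("A","B")` before the A/B split — so inparalog/outparalog ground truth
follows directly from the gene tree: genes of X and Y are orthologs iff
their LCA is the X/Y speciation node, and the true inparalog groups of X
w.r.t. Y are the cells of X's genes sharing an ancestor at that node.
Similarity scores equal LCA depth plus a per-pair deterministic jitter
(strictly smaller than any true distance gap, so ranks become distinct
without ever reordering genuinely different distances) plus optional
Gaussian noise ε; a fixed strictly decreasing exponential maps scores to
E-values. At ε = 0 the hit table is strictly monotone in true evolutionary
distance and exact recovery is forced; this is what the noiseless grid
verifies.

What the simulator does *not* model — and what passing tests therefore do
not show about real data: gene loss (the no-loss assumption is exactly why
noiseless recovery is exact; losses make boundaries fall at deeper
speciations), incomplete proteomes, alignment-length/identity artifacts,
compositional biases, and any realistic sequence evolution (sequences are
random strings; scores are simulated directly). The random-instance
harness compensates differently: arbitrary messy hit tables with frequent
E-value and full ties, checked for exact agreement against a brute-force
oracle that re-derives every rule with flat scans and no shared code.

## Problem sizes

The packaged analyses are desk-scale by design: the worked example has 12
proteins across three organisms; the oracle harness runs 200 random
instances of up to 5 organisms and 60 proteins; the noiseless grid covers
eight configurations from 2 to 5 organisms. These sizes exercise every code
path (full validation, pair fallback, all three relation types, both signal
colors, every tie-break) while keeping the whole suite and the acceptance
script in the seconds range.

## Known limitations

- Accessions are the FASTA header token up to the first whitespace;
  compound `db|acc|locus` identifiers are not decomposed.
- Groups are strictly pairwise-relative; no hierarchical clustering across
  multiple speciation depths at once.
- Flagged relations are not automatically split or merged.
- Plain text streams only (no gzip transparency); legacy non-tabular BLAST
  reports are not parsed.
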