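# orthopair

Graph-based orthology and inparalogy inference from BLAST all-versus-all
searches, for comparative genomicists who need co-ortholog predictions that
survive lineage-specific expansions.

## The problem and the method

Orthologs are homologs separated by a speciation event; paralogs by a
duplication. When duplications happen *after* a given speciation, the
resulting **inparalogs** are collectively co-orthologous to the counterpart
lineage — and classical reciprocal-best-hit (RBH) detection silently drops
the more divergent members of such expansions.

`orthopair` infers relations in three steps, directly from the ranked hit
lists of a protein BLAST all-versus-all search:

1. **Inparalog group formation and validation.** For a protein *p* of
   organism *A*, every protein of *A* with an E-value strictly inferior to
   the E-value of *p*'s best hit in organism *B* joins the putative group
   {*p*₁, …, *p*ₙ}^/B^. The group is *validated* only if the BLAST output of
   every member defines the same member set (in any order). If full
   validation fails, mutually confirmed two-member subgroups are rescued;
   remaining proteins become singletons.
2. **Pairwise entity comparison.** Each organism of a pair is partitioned
   into entities (validated groups + singletons) and relations are typed
   from best hits (BH): *1-to-1* = RBH between two singletons; *1-to-many* =
   BH from a singleton into a group plus a returning BH from any group
   member; *many-to-many* = one BH in each direction between two groups.
3. **Contradiction detection.** A group member whose best hit escapes both
   compared entities raises a warning signal on the relation — **red** if
   the escape is reciprocal, **orange** if it is a simple best hit. Signals
   annotate; they never remove a relation.

Ranking is by ascending E-value, with descending bit score and ascending
accession as deterministic tie-breaks. Optional proteome hygiene mirrors
large-scale practice: a 20–10000 residue length window and collapse of
within-organism sequences sharing >99% identity (longest representative
kept).

## Worked example: the myotubularin family

The packaged example reproduces the myotubularin lipid-phosphatase family —
one yeast gene, three fly and eight human paralogs, all duplicated after the
yeast split, a topology on which RBH-anchored methods produce false
negatives:

```bash
orthopair simulate --preset myotubularin --out demo/inputs
orthopair build --manifest demo/inputs/manifest.xml \
    --proteome-dir demo/inputs/proteomes --blast-dir demo/inputs/blast \
    --out demo/store.json
orthopair export demo/store.json --what relations --format csv
```

prints

```
store written to demo/store.json: 12 sequences, 4 validated groups, 3 relations
org_a,org_b,type,members_a,members_b,n_signals_red,n_signals_orange
dm,hs,MANY_TO_MANY,"Dm-R1-2,Dm-R3-4,Dm-R6-7-8","Hs-MTM,Hs-R1,Hs-R2,Hs-R3,Hs-R4,Hs-R6,Hs-R7,Hs-R8",0,0
dm,sc,ONE_TO_MANY,"Dm-R1-2,Dm-R3-4,Dm-R6-7-8",Sc-MTM,0,0
hs,sc,ONE_TO_MANY,"Hs-MTM,Hs-R1,Hs-R2,Hs-R3,Hs-R4,Hs-R6,Hs-R7,Hs-R8",Sc-MTM,0,0
```

All eight human and all three fly myotubularins are recovered as inparalogs
with respect to yeast (the 4 validated groups are the human and fly groups,
each relative to the two partner organisms), the single yeast gene is linked
to every one of them by 1-to-many relations — no false negatives — and no
contradiction signals are raised. `orthopair stats demo/store.json --pair sc
hs` reports the normalized 1-to-many count `0.125` (one oriented relation
divided by the larger proteome, 8).

Queries work on any built store, e.g. all human proteins with orthologs in
yeast:

```bash
orthopair query demo/store.json --focal hs --presence sc   # lists all 8
```

The `simulate` subcommand (without `--preset`) generates gene families on a
caterpillar species tree with chosen duplication events and writes the true
groups/relations beside the inputs, for controlled recovery experiments.

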