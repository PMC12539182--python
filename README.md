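# obpcur

Curation of insect odorant-binding-protein (OBP) repertoires.

Annotating a multigene family like the OBPs of the Mediterranean fruit fly
(*Ceratitis capitata*, medfly) means reconciling redundant records from
several sources — two genome assemblies, GenBank entries, a de novo
transcriptome — into one standardized, ortholog-named gene set.  `obpcur`
implements that curation as a tested, reusable pipeline:

1. **ORF mining** — six-frame ATG-anchored ORF extraction from transcripts
   (minimum 100 aa), with completeness flags;
2. **signal-peptide calling** — a deterministic rule-based caller
   (n-region charge, Kyte–Doolittle h-region, the (−3,−1) small-residue
   rule) returning `1..c` cleavage ranges;
3. **cysteine-scaffold classification** — the core computation.  OBPs are
   defined by six conserved cysteines C1..C6 with hallmark spacings
   C2-X₃-C3 and C5-X₈-C6.  Subfamilies are called by motif content:
   *Classical* (one motif), *Plus-C* (one motif + extra conserved
   cysteines, canonically 10 total, and a proline just after C6),
   *Minus-C* (4 cysteines, read as the classical scaffold lacking C2 and
   C5), *Atypical* (two complete motifs, C1..C6 and C1*..C6*);
4. **homology** — Smith–Waterman local alignment (BLOSUM62, affine 11/1)
   against a reference OBP set, with identity, query coverage, bit score
   and Karlin–Altschul E-values `E = m·n·2^(−bit)`;
5. **phylogeny** — neighbor-joining on global-alignment p-distances
   (optionally Poisson-corrected), with deterministic tie-breaks, Newick
   I/O and nearest-reference clade queries;
6. **consolidation** — single-linkage grouping of redundant records
   (identity ≥ 90 %, mutual coverage ≥ 80 %, same best hit), representative
   selection (complete > longest > source priority), isoform and
   tandem-copy sub-entries;
7. **nomenclature** — `<prefix>OBP<base>` names anchored on the best
   hit/tree agreement, with `-like`, `-likeN`, numeric copies (`56h1/56h2`
   style), letter copies (`99c-like1a/1b` style) and `-isoformN` suffixes,
   plus a lossless parser for such names.

A seeded synthetic-data generator plants scaffolds, signal peptides,
orthologs at 25–70 % identity, a five-subgroup expansion clade, isoforms,
fragments and decoys — with a truth table — so every stage is testable
without downloads.  The package also ships the curated 48-entry medfly
repertoire table (`obpcur.seqio.load_repertoire_table()`).

## Worked example

```bash
obpcur generate --seed 42 --outdir data/
obpcur run --candidates data/candidates.fasta \
           --references data/references.fasta --outdir out/
```

The `run` command prints the repertoire summary, e.g. at seed 42:

```json
{
  "n_entries": 24,
  "by_subfamily": {"Classical": 20, "Plus-C": 4},
  "signal_peptide_present": 23,
  "by_suffix_kind": {"isoform": 4, "like": 1, "like_numbered": 6,
                     "none": 11, "numeric_copy": 2},
  "like_subgroup_counts": {"49c": 5}
}
```
(abridged; the command also prints accession-prefix and per-source
tallies).  Here the generator planted 20 genes (101 candidate records
including 20 decoys); the pipeline consolidates them into 20 groups and
emits 24 named entries — the extras are two 2-member isoform splits
(`-isoform1/2`), a `99c-like`-style expansion (winner `OBP49c` plus five
`-likeN` subgroups, one with letter copies `a/b`), and one near-equal
species duplication named with numeric copies.  `out/repertoire.tsv` lists each entry with accession,
length, signal-peptide range, subfamily, best hit, E-value, identity and
coverage — the same ten columns as the packaged curated table; `out/`
also holds the grouping report, the naming audit trail, the pairwise hit
table and the Newick tree.

Library use mirrors the CLI: `generate_dataset`, `classify_scaffold`,
`best_hit`, `nj`, `cluster_candidates`, `assign_names`, `run_pipeline`.

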