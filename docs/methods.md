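# Methods

This note records the models, rules and numerical choices behind
`obpcur`, and what the synthetic benchmarks do and do not demonstrate.

## Scaffold model and classification

An OBP scaffold is six conserved cysteines C1..C6.  Gaps are counted as
residues strictly between two cysteines.  Two gaps are hallmark-exact
(tolerance 0 by default, configurable): C2–C3 = 3 and C5–C6 = 8.  The
remaining gaps are window-constrained: C1–C2 ∈ [15, 45], C3–C4 ∈ [20, 60],
C4–C5 ∈ [4, 25].  `find_classical_motifs` enumerates all cysteine
6-tuples satisfying these constraints (depth-first with window pruning,
exact for any cysteine count seen in practice) and keeps a non-overlapping
set greedily, in lexicographic (leftmost-first) order.

Classification applies most-specific-first precedence so a Plus-C
sequence cannot degrade into a trivial Classical match:

* **Atypical**: ≥ 2 disjoint motifs (conserved count 6 per motif);
* **Plus-C**: 1 motif, ≥ 2 extra cysteines (canonical total 10), and a
  proline within 3 residues after C6;
* **Classical**: exactly 1 motif (extra cysteines without the Plus-C
  proline signature are tolerated, as in real N-terminally
  cysteine-rich classical members);
* **Minus-C**: 0 motifs and exactly 4 cysteines whose three gaps fit the
  composite windows obtained by deleting C2 and C5 from the classical
  model (C1–C3 ∈ [19, 49], C3–C4 ∈ [20, 60], C4–C6 ∈ [13, 34]).  Only
  window plausibility is enforced because both hallmark gaps involve a
  deleted cysteine;
* **Unclassified** otherwise.

Sequences that carry all six cysteines but cluster phylogenetically with
Minus-C members are classified Classical by pattern; tree affinity is
reported separately by the phylo module.  The candidate filter requires a
recognizable scaffold and a mature length in [80, 400]; a signal peptide
is deliberately not required, since curated repertoires retain members
whose N-termini diverged beyond detection.

## Signal-peptide caller

A deterministic stand-in for neural predictors, built from the classical
tripartite model.  For each candidate cleavage position c ∈ [10, 45]:

    score(c) = w_charge · [any K/R among residues 1..5]
             + w_hydro  · max mean Kyte–Doolittle over a 7-residue window
                          within residues [5, c−3]
             + 0.5 per small residue (A, G, S, C, T) at positions c−2 and c

with defaults w_charge = w_hydro = 1.0 and threshold 2.5; ties go to the
smallest c.  The charge term is scored as presence rather than count so
that a chance cluster of lysines cannot substitute for a missing
h-region.  Sequences shorter than 30 residues return an absent call with
a warning.  Search window 10..45 covers all signal ranges in the packaged
repertoire (max observed 1–35).  The caller reproduces present/absent
calls and ±2-residue boundaries on planted signals; it makes no attempt
to model signal anchors or predictor probabilities.  In the pipeline the
scaffold outranks the caller: if removing a predicted signal destroys an
otherwise recognizable scaffold, the call is retracted and the full
sequence is classified (heuristic callers do misfire inside domains, and
published repertoires document complete-ORF members without detectable
signals).

## Homology statistics

Local alignment uses Smith–Waterman with affine gaps via
`Bio.Align.PairwiseAligner` (BLOSUM62, open 11, extend 1 — a gap of
length k costs 11 + k).  Bit scores use the standard gapped-BLOSUM62
Karlin–Altschul parameters λ = 0.267, K = 0.041; E = m·n·2^(−bit) with m
the query length and n the total reference residues.  Composition-based
statistics and database-size corrections are omitted; E-values are
nominal.  Two identities are reported: the BLAST-convention identity
(identities / all alignment columns, gaps included) for reporting, and a
gap-excluded identity (identities / aligned residue pairs) used for
redundancy grouping — an isoform differing only by a 20-residue internal
insertion is ~97 % identical residue-wise but would fall below 90 % under
the gap-inclusive convention purely from the indel columns.  Coverage is
query coverage.  Best hits maximize bit score, ties broken by identity
then subject id.  The all-vs-all stage may apply a score screen (≥ 1.0
per residue of the shorter sequence) before traceback; pairs near the
90 % grouping threshold score several units per residue, so the screen
only skips pairs far below any grouping rule.

## Trees

Distances are p-distances over aligned non-gap columns of pairwise global
alignments (optional Poisson correction −ln(1−p), saturated at 10), not a
multiple alignment: the downstream queries need only topology and path
lengths, and pairwise distances keep the stage deterministic and
dependency-light.  Neighbor joining is implemented directly (Saitou–Nei
Q-criterion) so its tie-break is an explicit contract: the joined pair
minimizes Q with ties resolved by the minimal index pair, and negative
branch lengths clamp to zero.  On additive matrices the result reproduces
every input distance exactly (the additive tree is unique), which the
tests exploit as an oracle alongside an independent library
implementation.  No support values are computed: naming uses best-hit /
nearest-reference agreement instead of posterior-probability thresholds,
and this substitution is the package's stated contract rather than an
imitation of Bayesian support.

## Consolidation

Records are grouped by single-linkage over explicit thresholds:
gap-excluded identity ≥ 90 %, mutual coverage ≥ 80 %, and (by default) an
identical best reference hit.  Connected components become gene groups;
representatives rank by complete ORF, then length, then source priority
(GenBank > genome A > genome B > transcriptome), then id.  Within a
group, splice forms are the components of the "no internal indel ≥ 15
residues between us" relation — if several forms coexist, each extra form
is an isoform sub-entry.  Otherwise members are sub-clustered at 94 %
identity; extra sub-clusters become tandem-copy sub-entries (redundant
cross-source records of one gene sit ≥ 96 % pairwise, planted tandem
copies ~91–93 %).  Sequence alone cannot prove tandem duplication — real
curation uses chromosomal coordinates — so the copy threshold is a
declared operational definition, not an inference.

## Nomenclature

For every reference base name B claimed by one or more groups (via the
best hit, normalized by stripping `OBP` and ` isoform X`): the group
whose best hit and nearest tree reference agree on B with the top bit
score takes B unsuffixed; if two or more agreeing groups have near-equal
scores (within 10 % of the top), all take numeric copies B1, B2, … —
the species-specific-duplication pattern; remaining claimants take
`-like` (one) or `-like1..N` (several, by descending score).  Isoform
sub-entries number all emitted entries `-isoform1..k`; tandem-copy
sub-entries take letters on like-names (`-like1a/1b`) and numeric copies
on plain bases.  Groups with no accepted hit are named
`<prefix>OBP-novel<N>` and flagged.  The "1-to-1 ortholog" rule
(best hit + nearest reference + top score) is this package's own
operational definition of a criterion that is verbal in curation
practice; the naming report records which rule fired and its evidence.
`parse_name` inverts the full grammar losslessly.

## Synthetic study conditions

The generator's defaults emulate the scale of a medfly-style curation:
73 references, 20 planted genes (five of them a single-clade expansion at
35–45 % reference identity, mimicking a 99c-like radiation), 2–5
redundant variants per gene at 98–99.5 % identity spread across sources,
ortholog identities 25–70 %, signal-peptide rate 0.94, isoform rate 0.1
(internal insertions of 18–25 residues), fragment rate 0.1 (C-terminal
truncation ≤ 12 %), tandem-copy rate 0.15 (91.5–93 % identity),
near-equal sister-gene rate 0.1, and 20 decoys.  Scaffolds are built by
constraint (cysteines placed inside the classifier's windows; Plus-C
extras positioned where no alternative motif can recruit them), so
planted labels are valid by construction.  Mutations never touch
conserved cysteines, the post-C6 proline window, or the signal peptide;
decoys are cysteine-free, drawn from a hydrophilic pool, and redrawn
until no 7-residue window is net hydrophobic (mean KD < 0), making them
h-region-free by construction.  Transcripts wrap reverse-translated CDSs
in random UTRs with an in-frame stop ahead of the initiator.

Consequences worth stating plainly: passing the round-trip tests shows
the pipeline inverts its own generative model, not that it matches
neural signal-peptide predictors or heuristic BLAST statistics on real
data; real evolution does mutate cysteines (Minus-C subfamilies arose
exactly that way), real fragments truncate anywhere, and real decoys
include secreted non-OBP proteins with genuine signal peptides, none of
which the generator emulates.  Fragments may legitimately lose their
planted subfamily when truncation removes C-terminal motif features;
truth-table comparisons therefore treat fragment classification as
best-effort.

## Numerical and determinism choices

All randomness flows through seeded `random.Random` instances; identical
seeds give byte-identical generator output and pipeline reports (tables
are sorted, floats formatted with fixed precision).  Alignment tie-breaks
follow the aligner's deterministic first-optimal path; NJ and naming
tie-breaks are explicit (minimal index pair; lexicographic ids).
Problem sizes used by the test-suite benchmarks — 200 alignment-oracle
pairs at ≤ 50 aa, additive matrices up to 8 taxa, 100-seed consolidation
recovery at the default 20-gene conditions, 500 scaffolds per subfamily —
were chosen as the smallest sets that exercise every rule and tie-break.

## Known limitations

Local-alignment identity over-reports planted site-wise identity at low
identity (the optimal alignment clips or gaps into better-matching
cores); tests therefore assert exact site-wise recovery and
no-under-reporting by the aligners.  E-values are nominal, uncorrected
desk-scale quantities.  The NJ tree carries no uncertainty estimates.
Cytogenetic renaming by chromosomal location is out of scope, as is any
profile-HMM domain detection.
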