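"""Seeded synthetic-data generator with planted ground truth.

Emulates the raw material of a multigene-family curation study: a
reference OBP set (73 proteins, standing in for the *D. melanogaster*
repertoire), a candidate set with per-gene redundancy across sources (two
genome assemblies, GenBank entries, transcriptome variants), planted
cysteine scaffolds of the four subfamilies, planted signal peptides,
ortholog pairs at 25–70% identity, one lineage-specific expansion clade
with five subgroups (mimicking a 99c-like-style radiation), tandem-copy
and isoform sub-entries, truncated fragments, and cysteine-free decoys.
Every emitted record has exactly one truth-table row, so every pipeline
stage can be scored without downloads.

Scaffolds are built by constraint: cysteines are placed inside the same
gap windows the classifier checks, extra Plus-C cysteines are positioned
where they cannot seed a spurious motif, and mutations never touch
conserved cysteines, the post-C6 proline window, or the signal peptide, so
planted labels stay valid at any identity.  (Real evolution does mutate
these sites — Minus-C subfamilies arose exactly that way — which is a
stated limit of what these data can exercise.)  Decoys are drawn from a
hydrophilic residue pool, emulating soluble non-secreted proteins with
neither a cysteine scaffold nor a hydrophobic signal-anchor region.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio.Data import CodonTable

from .scaffold import ClassifierConfig, DEFAULT_CLASSIFIER, classify_scaffold
from .seqio import SequenceRecord, write_fasta

#: uniform background over the 19 non-cysteine residues
BODY_RESIDUES = "ADEFGHIKLMNPQRSTVWY"
#: hydrophilic pool for decoys (no C; no strongly hydrophobic residues)
DECOY_RESIDUES = "ADEGHKNPQRSTY"
#: h-region pool for planted signal peptides
HYDROPHOBIC = "LIVF"

SUBFAMILY_WEIGHTS = (("Classical", 0.70), ("Plus-C", 0.15),
                     ("Minus-C", 0.10), ("Atypical", 0.05))

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()
_STOP_CODONS = sorted(_CODON_TABLE.stop_codons)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs of the generator (defaults emulate the scale
    and composition of a medfly-style OBP curation)."""

    seed: int = 0
    n_refs: int = 73
    n_genes: int = 20
    variants_per_gene: tuple[int, int] = (2, 5)
    ortholog_identity_range: tuple[float, float] = (25.0, 70.0)
    duplication_rate: float = 0.15        # within-group tandem copy
    species_duplication_rate: float = 0.10  # near-equal sister gene (B1/B2 analog)
    expansion: bool = True                # one clade with 5 like-subgroups
    expansion_subgroups: int = 5
    expansion_identity: tuple[float, float] = (35.0, 45.0)
    isoform_rate: float = 0.10
    fragment_rate: float = 0.10
    decoy_count: int = 20
    signal_peptide_rate: float = 0.94
    variant_identity: tuple[float, float] = (98.0, 99.5)
    copy_identity: tuple[float, float] = (91.5, 93.0)
    indel_rate: float = 0.005


DEFAULT_GENERATOR = GeneratorConfig()


def _body(rng: random.Random, n: int, pool: str = BODY_RESIDUES) -> str:
    return "".join(rng.choice(pool) for _ in range(n))


def _classical_core(rng: random.Random, cfg: ClassifierConfig,
                    g12: Optional[int] = None) -> str:
    """One six-cysteine domain: C1 .. C6 with hallmark and window gaps,
    no leader or tail."""
    if g12 is None:
        g12 = rng.randint(*cfg.c1_c2_window)
    g34 = rng.randint(*cfg.c3_c4_window)
    g45 = rng.randint(*cfg.c4_c5_window)
    return ("C" + _body(rng, g12) + "C" + _body(rng, cfg.c2_c3_gap) + "C"
            + _body(rng, g34) + "C" + _body(rng, g45) + "C"
            + _body(rng, cfg.c5_c6_gap) + "C")


def generate_scaffold(subfamily: str, config: ClassifierConfig = DEFAULT_CLASSIFIER,
                      seed: int = 0, rng: Optional[random.Random] = None) -> str:
    """Mature protein sequence whose scaffold satisfies ``subfamily``'s
    constraints exactly (verified against the classifier before return)."""
    if rng is None:
        rng = random.Random(seed)
    for _ in range(20):
        seq = _build_scaffold(subfamily, config, rng)
        if classify_scaffold(seq, config).subfamily == subfamily:
            return seq
    raise RuntimeError(f"could not realize a {subfamily} scaffold")  # pragma: no cover


def _build_scaffold(subfamily: str, cfg: ClassifierConfig, rng: random.Random) -> str:
    leader = _body(rng, rng.randint(12, 18))
    tail = _body(rng, rng.randint(15, 30))
    if subfamily == "Classical":
        return leader + _classical_core(rng, cfg) + tail
    if subfamily == "Plus-C":
        # Four extra cysteines clustered near the N-terminus where no pairing
        # with core cysteines can satisfy the motif windows (g12 is pinned
        # to the window maximum so extras are always too far from C2).
        prefix = (_body(rng, 4) + "CC" + _body(rng, 1) + "CC" + _body(rng, 10))
        core = _classical_core(rng, cfg, g12=cfg.c1_c2_window[1])
        return prefix + core + "P" + _body(rng, rng.randint(14, 29))
    if subfamily == "Minus-C":
        # classical scaffold minus C2 and C5: windows are the composites
        lo13 = cfg.c1_c2_window[0] + 1 + cfg.c2_c3_gap
        hi13 = cfg.c1_c2_window[1] + 1 + cfg.c2_c3_gap
        lo46 = cfg.c4_c5_window[0] + 1 + cfg.c5_c6_gap
        hi46 = cfg.c4_c5_window[1] + 1 + cfg.c5_c6_gap
        return (leader + "C" + _body(rng, rng.randint(lo13, hi13)) + "C"
                + _body(rng, rng.randint(*cfg.c3_c4_window)) + "C"
                + _body(rng, rng.randint(lo46, hi46)) + "C" + tail)
    if subfamily == "Atypical":
        d1 = _classical_core(rng, cfg)
        d2 = _classical_core(rng, cfg)
        return (_body(rng, rng.randint(5, 10)) + d1 + _body(rng, 15) + d2
                + _body(rng, rng.randint(8, 15)))
    raise ValueError(f"cannot generate subfamily {subfamily!r}")


def generate_signal_peptide(rng: random.Random) -> str:
    """Tripartite signal peptide: M + charged n-region + hydrophobic
    h-region + A-x-A c-region.  Cleavage falls after the final residue.
    The h-region is at least 10 residues so a full 7-residue hydrophobicity
    window fits between position 5 and the (-3) site."""
    h = _body(rng, rng.randint(10, 14), HYDROPHOBIC)
    return "MK" + h + "AQA"


def _anchor_positions(seq: str, cfg: ClassifierConfig,
                      protected: Optional[set[int]] = None) -> set[int]:
    """0-based positions mutations must not touch: every cysteine, the
    post-C6 proline window of each motif, plus caller-protected sites."""
    anchors = {i for i, aa in enumerate(seq) if aa == "C"}
    sc = classify_scaffold(seq, cfg) if set(seq) <= set(BODY_RESIDUES + "C") else None
    if sc is not None:
        for motif in sc.motif_positions:
            c6 = motif[5]
            anchors.update(range(c6, min(c6 + cfg.proline_window, len(seq))))
    if protected:
        anchors |= protected
    return anchors


def mutate_to_identity(seq: str, target_identity_pct: float,
                       allow_indels: bool = False, seed: int = 0,
                       rng: Optional[random.Random] = None,
                       protected: Optional[set[int]] = None,
                       config: ClassifierConfig = DEFAULT_CLASSIFIER) -> str:
    """Substitution mutant at a planted gap-free identity (±1 point).

    Substituted positions are sampled outside the anchor set, so the
    cysteine scaffold (and any protected prefix, e.g. a signal peptide)
    survives at any attainable identity.  With ``allow_indels`` a short
    insertion is additionally placed in the unanchored tail.
    """
    if not 0 < target_identity_pct <= 100:
        raise ValueError("target identity must lie in (0, 100]")
    if rng is None:
        rng = random.Random(seed)
    L = len(seq)
    n_sub = round(L * (1.0 - target_identity_pct / 100.0))
    if n_sub == 0:
        return seq
    anchors = _anchor_positions(seq, config, protected)
    mutable = [i for i in range(L) if i not in anchors]
    if n_sub > len(mutable):
        raise ValueError(
            f"target identity {target_identity_pct}% needs {n_sub} substitutions "
            f"but only {len(mutable)} non-anchor sites exist")
    out = list(seq)
    for i in sorted(rng.sample(mutable, n_sub)):
        choices = [aa for aa in BODY_RESIDUES if aa != seq[i]]
        out[i] = rng.choice(choices)
    mutated = "".join(out)
    if allow_indels:
        last_anchor = max(anchors) if anchors else 0
        pos = max(last_anchor + 4, L - 10)
        if pos < L:
            mutated = mutated[:pos] + _body(rng, rng.randint(2, 4)) + mutated[pos:]
    return mutated


def insert_internal_indel(seq: str, rng: random.Random, min_len: int = 18,
                          max_len: int = 25,
                          config: ClassifierConfig = DEFAULT_CLASSIFIER) -> str:
    """Insert an isoform-scale run after the last anchored position."""
    anchors = _anchor_positions(seq, config)
    last_anchor = max(anchors) if anchors else 0
    pos = min(max(last_anchor + 4, len(seq) - 12), len(seq) - 6)
    return seq[:pos] + _body(rng, rng.randint(min_len, max_len)) + seq[pos:]


def reverse_translate(protein: str, rng: random.Random) -> str:
    """A coding sequence for ``protein`` plus a stop codon (synonymous
    codons drawn uniformly)."""
    codons = [rng.choice(_AA_TO_CODONS[aa]) for aa in protein]
    codons.append(rng.choice(_STOP_CODONS))
    return "".join(codons)


_REF_NUMBERS = (8, 19, 22, 28, 44, 46, 47, 49, 50, 51, 56, 57, 58, 59,
                69, 73, 76, 83, 84, 85, 93, 99)


def _reference_bases(n: int) -> list[str]:
    bases = []
    for letter in "abcd":
        for num in _REF_NUMBERS:
            bases.append(f"{num}{letter}")
            if len(bases) == n - 1:
                bases.append("lush")
                return bases
    raise ValueError(f"cannot derive {n} reference base names")  # pragma: no cover


@dataclass
class SyntheticDataset:
    """Generator output: records plus a truth table (one row per emitted
    candidate/transcript/decoy record)."""

    config: GeneratorConfig
    references: list[SequenceRecord]
    candidates: list[SequenceRecord]
    transcripts: list[SequenceRecord]
    truth: pd.DataFrame

    @property
    def planted_gene_count(self) -> int:
        mask = ~self.truth["variant_kind"].isin(["decoy"])
        return int(self.truth.loc[mask, "gene_id"].nunique())

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "references": outdir / "references.fasta",
            "candidates": outdir / "candidates.fasta",
            "transcripts": outdir / "transcripts.fasta",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.references, paths["references"])
        write_fasta(self.candidates, paths["candidates"])
        write_fasta(self.transcripts, paths["transcripts"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


TRUTH_COLUMNS = ("record_id", "gene_id", "subfamily", "ortholog_base",
                 "variant_kind", "sp_cleavage", "identity_to_ortholog", "source")


def generate_dataset(config: GeneratorConfig = DEFAULT_GENERATOR,
                     classifier: ClassifierConfig = DEFAULT_CLASSIFIER,
                     ) -> SyntheticDataset:
    """Deterministic dataset for a given config (identical seed, identical
    bytes)."""
    rng = random.Random(config.seed)
    bases = _reference_bases(config.n_refs)

    refs: list[SequenceRecord] = []
    ref_mature: dict[str, str] = {}
    ref_subfam: dict[str, str] = {}
    for base in bases:
        subfam = _weighted_choice(rng, SUBFAMILY_WEIGHTS)
        mature = generate_scaffold(subfam, classifier, rng=rng)
        sp = generate_signal_peptide(rng) if rng.random() < 0.9 else "M"
        rid = f"DmelOBP{base}"
        refs.append(SequenceRecord(id=rid, seq=sp + mature, alphabet="protein",
                                   source="reference", complete_orf=True,
                                   description=f"OBP{base}"))
        ref_mature[rid] = mature
        ref_subfam[rid] = subfam

    n_sub = config.expansion_subgroups if config.expansion else 0
    n_ordinary = config.n_genes - n_sub
    if n_ordinary < 1:
        raise ValueError("n_genes must exceed the expansion subgroup count")
    ortholog_refs = rng.sample(refs, n_ordinary)
    expansion_ref = ortholog_refs[-1] if config.expansion else None

    candidates: list[SequenceRecord] = []
    transcripts: list[SequenceRecord] = []
    truth_rows: list[tuple] = []

    gene_specs: list[tuple[str, SequenceRecord, float]] = []
    for gi, ref in enumerate(ortholog_refs):
        if config.expansion and ref is expansion_ref:
            ident = rng.uniform(55.0, config.ortholog_identity_range[1])
        else:
            ident = rng.uniform(*config.ortholog_identity_range)
        gene_specs.append((f"g{gi + 1:02d}", ref, ident))
    for si in range(n_sub):
        gene_specs.append((f"g{n_ordinary + si + 1:02d}x", expansion_ref,
                           rng.uniform(*config.expansion_identity)))

    counter = 0

    def emit(seq, source, complete, gid, subfam, base, kind, cleavage, ident):
        nonlocal counter
        counter += 1
        rid = f"cand{counter:04d}"
        candidates.append(SequenceRecord(id=rid, seq=seq, alphabet="protein",
                                         source=source, complete_orf=complete))
        truth_rows.append((rid, gid, subfam, base, kind, cleavage,
                           round(ident, 2), source))
        return rid

    extra_specs: list[tuple[str, SequenceRecord, float, str]] = []
    for gid, ref, ident in gene_specs:
        base = ref.description[3:]  # strip "OBP"
        subfam = ref_subfam[ref.id]
        mature = mutate_to_identity(ref_mature[ref.id], ident, rng=rng,
                                    config=classifier)
        has_sp = rng.random() < config.signal_peptide_rate
        sp = generate_signal_peptide(rng) if has_sp else "M"
        protein = sp + mature
        cleavage = len(sp) if has_sp else 0
        protected = set(range(len(sp)))

        k = rng.randint(*config.variants_per_gene)
        sources = ["genbank"] + [["genomeA", "genomeB", "transcriptome"][i % 3]
                                 for i in range(k - 1)]
        emit(protein, "genbank", True, gid, subfam, base, "primary", cleavage, ident)
        for vi in range(1, k):
            vident = rng.uniform(*config.variant_identity)
            vseq = mutate_to_identity(protein, vident, rng=rng,
                                      protected=protected, config=classifier)
            emit(vseq, sources[vi], rng.random() < 0.8, gid, subfam, base,
                 "redundant", cleavage, ident)
        if rng.random() < config.isoform_rate:
            iso = insert_internal_indel(
                mutate_to_identity(protein, rng.uniform(*config.variant_identity),
                                   rng=rng, protected=protected, config=classifier),
                rng, config=classifier)
            emit(iso, "transcriptome", True, gid, subfam, base, "isoform",
                 cleavage, ident)
        if rng.random() < config.fragment_rate:
            cut = min(15, int(0.12 * len(protein)))
            frag = mutate_to_identity(protein, rng.uniform(*config.variant_identity),
                                      rng=rng, protected=protected,
                                      config=classifier)[:len(protein) - cut]
            emit(frag, "transcriptome", False, gid, subfam, base, "fragment",
                 cleavage, ident)
        if rng.random() < config.duplication_rate:
            dup = mutate_to_identity(protein, rng.uniform(*config.copy_identity),
                                     rng=rng, protected=protected, config=classifier)
            emit(dup, "genomeA", True, gid, subfam, base, "duplicate",
                 cleavage, ident)
        if rng.random() < config.species_duplication_rate:
            extra_specs.append((gid + "s", ref, ident, base))

    for gid, ref, parent_ident, base in extra_specs:
        # a sister gene below the same-gene threshold but with near-equal
        # reference affinity: the numeric-copy (B1/B2) scenario
        subfam = ref_subfam[ref.id]
        mature = mutate_to_identity(ref_mature[ref.id], parent_ident * 0.93,
                                    rng=rng, config=classifier)
        sp = generate_signal_peptide(rng)
        protein = sp + mature
        emit(protein, "genbank", True, gid, subfam, base, "primary",
             len(sp), parent_ident * 0.93)
        vseq = mutate_to_identity(protein, rng.uniform(*config.variant_identity),
                                  rng=rng, protected=set(range(len(sp))),
                                  config=classifier)
        emit(vseq, "genomeB", True, gid, subfam, base, "redundant",
             len(sp), parent_ident * 0.93)

    for di in range(config.decoy_count):
        counter += 1
        rid = f"cand{counter:04d}"
        seq = generate_decoy(rng)
        candidates.append(SequenceRecord(id=rid, seq=seq, alphabet="protein",
                                         source="genbank"))
        truth_rows.append((rid, rid, "Unclassified", "", "decoy", 0, 0.0, "genbank"))

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    for rec in candidates:
        if rec.source == "transcriptome":
            cds = reverse_translate(rec.seq, rng)
            # in-frame stop ahead of the CDS so a chance upstream ATG in the
            # UTR cannot extend the ORF past the real initiator
            tx = (_body_nt(rng, rng.randint(20, 80)) + "TAA" + cds
                  + _body_nt(rng, rng.randint(20, 80)))
            transcripts.append(SequenceRecord(id=rec.id + "_tx", seq=tx,
                                              alphabet="nucleotide",
                                              source="transcriptome"))
    return SyntheticDataset(config=config, references=refs,
                            candidates=candidates, transcripts=transcripts,
                            truth=truth)


def generate_decoy(rng: random.Random, length: Optional[int] = None) -> str:
    """Cysteine-free decoy without an h-region.

    Drawn from the hydrophilic pool and redrawn until no 7-residue window
    is net hydrophobic (mean Kyte–Doolittle < 0; a true signal h-region
    scores about 3.4), so decoys are h-region-free by construction.
    """
    from .sigpep import KYTE_DOOLITTLE
    n = length if length is not None else rng.randint(90, 200)
    while True:
        seq = _body(rng, n, DECOY_RESIDUES)
        kdv = [KYTE_DOOLITTLE[aa] for aa in seq]
        if max(sum(kdv[i:i + 7]) / 7 for i in range(len(kdv) - 6)) < 0.0:
            return seq


def _body_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _weighted_choice(rng: random.Random, weighted) -> str:
    x = rng.random()
    acc = 0.0
    for value, w in weighted:
        acc += w
        if x < acc:
            return value
    return weighted[-1][0]
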