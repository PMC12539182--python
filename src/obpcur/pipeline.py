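"""End-to-end curation pipeline: mine -> classify -> homologize -> tree ->
consolidate -> name -> report.

``run_pipeline`` executes the stages in order and returns a
:class:`RepertoireReport`; with an output directory it also writes every
intermediate artifact (classification TSV, hit tables, grouping report,
newick tree, naming report, and the final Table-1-style repertoire TSV).
Output is deterministic for a given config and seed: records are processed
in input order and every emitted table is sorted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import homology, orf, phylo, sigpep
from .consolidate import (DEFAULT_GROUPING, GeneGroup, GroupingParams,
                          cluster_candidates)
from .homology import DEFAULT_SCHEME, HomologyHit, ScoringScheme, hits_to_table
from .nomenclature import NameAssignment, assign_names, parse_name
from .scaffold import (DEFAULT_CLASSIFIER, ClassifierConfig, classify_scaffold,
                       is_obp_candidate)
from .seqio import (CuratedEntry, SequenceRecord, load_repertoire_table,
                    read_fasta, write_repertoire_table)
from .sigpep import DEFAULT_SIGPEP, SigpepConfig

log = logging.getLogger("obpcur")

#: local-alignment score screen (units per residue) applied before the
#: all-vs-all traceback; redundancy-level pairs score far above it
ALL_VS_ALL_SCREEN = 1.0


@dataclass
class PipelineConfig:
    candidates: Optional[str] = None
    transcripts: Optional[str] = None
    references: Optional[str] = None
    outdir: Optional[str] = None
    prefix: str = "Ccap"
    min_orf_aa: int = orf.DEFAULT_MIN_AA
    evalue_accept: float = 1e-3
    seed: int = 0
    classifier: ClassifierConfig = DEFAULT_CLASSIFIER
    sigpep: SigpepConfig = DEFAULT_SIGPEP
    scoring: ScoringScheme = DEFAULT_SCHEME
    grouping: GroupingParams = DEFAULT_GROUPING

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config file: flat keys plus optional ``classifier``,
        ``sigpep``, ``scoring`` and ``grouping`` sections."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sections = {
            "classifier": (ClassifierConfig, DEFAULT_CLASSIFIER),
            "sigpep": (SigpepConfig, DEFAULT_SIGPEP),
            "scoring": (ScoringScheme, DEFAULT_SCHEME),
            "grouping": (GroupingParams, DEFAULT_GROUPING),
        }
        kwargs = {}
        for key, value in raw.items():
            if key in sections:
                typ, default = sections[key]
                fixed = {k: tuple(v) if isinstance(v, list) else v
                         for k, v in (value or {}).items()}
                kwargs[key] = replace(default, **fixed)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class RepertoireReport:
    """Curated repertoire plus provenance and audit structures."""

    entries: list[CuratedEntry]
    groups: list[GeneGroup]
    assignments: list[NameAssignment]
    subfamily_counts: dict[str, int]
    provenance: dict[str, tuple[str, ...]]  # final name -> sources seen
    newick: str = ""


def mine_transcripts(transcripts: Sequence[SequenceRecord],
                     min_aa: int = orf.DEFAULT_MIN_AA) -> list[SequenceRecord]:
    """Translate each transcript's best ORF (longest; complete preferred)
    into a protein candidate."""
    out = []
    for t in transcripts:
        calls = orf.find_orfs(t, min_aa=min_aa)
        if not calls:
            continue
        best = sorted(calls, key=lambda c: (not c.complete, -len(c.protein)))[0]
        out.append(SequenceRecord(
            id=f"{t.id}_orf1", seq=best.protein, alphabet="protein",
            source=t.source if t.source != "synthetic" else "transcriptome",
            complete_orf=best.complete))
    return out


def call_and_classify(seq: str,
                      classifier: ClassifierConfig = DEFAULT_CLASSIFIER,
                      sp_config: SigpepConfig = DEFAULT_SIGPEP):
    """Signal-peptide call plus scaffold classification of the mature
    sequence.

    The scaffold is the stronger evidence: if removing a predicted signal
    peptide destroys an otherwise recognizable scaffold (the heuristic
    caller fired inside the domain), the call is retracted and the full
    sequence classified instead.
    """
    sp = sigpep.predict_signal_peptide(seq, sp_config)
    mature = sigpep.mature_sequence(seq, sp)
    scaffold = None
    if classifier.min_mature_len <= len(mature) <= classifier.max_mature_len:
        scaffold = classify_scaffold(mature, classifier)
    if sp.present and (scaffold is None or scaffold.subfamily == "Unclassified"):
        full = classify_scaffold(seq, classifier)
        if (full.subfamily != "Unclassified"
                and classifier.min_mature_len <= len(seq)
                <= classifier.max_mature_len):
            sp = sigpep.SignalPeptideCall(False, 0, sp.score)
            scaffold = full
    if scaffold is None:
        scaffold = classify_scaffold(mature, classifier) \
            if mature else classify_scaffold(seq, classifier)
    return sp, scaffold


def classify_candidates(records: Sequence[SequenceRecord],
                        classifier: ClassifierConfig = DEFAULT_CLASSIFIER,
                        sp_config: SigpepConfig = DEFAULT_SIGPEP):
    """Signal-peptide call and scaffold classification per record.

    Returns (kept records, per-id subfamily, per-id signal-peptide call).
    Records whose mature length falls outside the classifier's window or
    whose scaffold is unrecognizable are dropped.
    """
    kept, subfamilies, sp_calls = [], {}, {}
    for rec in records:
        sp, scaffold = call_and_classify(rec.seq, classifier, sp_config)
        if not is_obp_candidate(rec, scaffold, sp, classifier):
            continue
        kept.append(rec)
        subfamilies[rec.id] = scaffold.subfamily
        sp_calls[rec.id] = sp
    return kept, subfamilies, sp_calls


def _accept(hit: HomologyHit, evalue_accept: float) -> HomologyHit:
    if hit.no_hit or hit.evalue > evalue_accept:
        return homology._no_hit(hit.query_id)
    return hit


def run_pipeline(config: PipelineConfig,
                 candidates: Optional[Sequence[SequenceRecord]] = None,
                 references: Optional[Sequence[SequenceRecord]] = None,
                 transcripts: Optional[Sequence[SequenceRecord]] = None,
                 ) -> RepertoireReport:
    """Execute the full curation pipeline.

    Inputs may be passed in memory or read from the FASTA paths in the
    config.  An empty candidate set after filtering yields an explicit
    empty report rather than an error.
    """
    if references is None:
        if not config.references:
            raise ValueError("stage input: no reference set provided")
        references = read_fasta(config.references, source="reference")
    if candidates is None:
        candidates = read_fasta(config.candidates) if config.candidates else []
    candidates = list(candidates)
    if transcripts is None and config.transcripts:
        transcripts = read_fasta(config.transcripts, alphabet="nucleotide",
                                 source="transcriptome")
    if transcripts:
        mined = mine_transcripts(transcripts, config.min_orf_aa)
        log.info("stage=orf transcripts=%d mined=%d", len(transcripts), len(mined))
        candidates = candidates + mined

    kept, subfamilies, sp_calls = classify_candidates(
        candidates, config.classifier, config.sigpep)
    log.info("stage=classify in=%d kept=%d", len(candidates), len(kept))

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        _write_classification(kept, subfamilies, sp_calls,
                              outdir / "classification.tsv", config.classifier,
                              config.sigpep)

    if not kept:
        report = RepertoireReport(entries=[], groups=[], assignments=[],
                                  subfamily_counts={}, provenance={})
        if outdir:
            write_repertoire_table([], outdir / "repertoire.tsv")
        return report

    best_hits = {r.id: _accept(homology.best_hit(r, references, config.scoring),
                               config.evalue_accept)
                 for r in kept}
    pair_hits = homology.all_vs_all_hits(kept, config.scoring,
                                         screen_score_per_residue=ALL_VS_ALL_SCREEN)
    log.info("stage=homologize best_hits=%d pair_hits=%d",
             len(best_hits), len(pair_hits))

    groups = cluster_candidates(kept, pair_hits, best_hits, config.grouping,
                                subfamilies)
    log.info("stage=consolidate candidates=%d groups=%d", len(kept), len(groups))

    rec_map = {r.id: r for r in kept}
    reps = [rec_map[g.representative_id] for g in groups]
    tree_records = (
        [SequenceRecord(id="Q|" + r.id, seq=r.seq, alphabet="protein",
                        source=r.source, complete_orf=r.complete_orf)
         for r in reps]
        + [SequenceRecord(id="R|" + r.id, seq=r.seq, alphabet="protein",
                          source="reference", description=r.description)
           for r in references])
    tree = phylo.nj(phylo.distance_matrix(tree_records, config.scoring,
                                          correction="poisson"))
    label = {r.id: "Q|" + r.id for r in reps}
    label.update({r.id: "R|" + r.id for r in references})
    log.info("stage=tree leaves=%d", len(tree_records))

    assignments = assign_names(groups, tree, references, prefix=config.prefix,
                               tree_label=label)
    log.info("stage=name groups=%d entries=%d", len(groups), len(assignments))

    group_by_id = {g.group_id: g for g in groups}
    entries, provenance = [], {}
    for a in sorted(assignments, key=lambda a: a.final_name):
        g = group_by_id[a.group_id]
        member = rec_map[a.member_id]
        sp = sp_calls[member.id]
        bh = best_hits[member.id]
        ref_desc = ""
        if not bh.no_hit:
            ref = next((r for r in references if r.id == bh.subject_id), None)
            ref_desc = (ref.description or ref.id) if ref else ""
        entries.append(CuratedEntry(
            name=a.final_name, accession=member.id, aa_length=len(member.seq),
            signal_peptide=(1, sp.cleavage_after) if sp.present else None,
            classification=subfamilies[member.id],
            hit_accession=bh.subject_id or "–",
            hit_description=ref_desc or "–",
            evalue=bh.evalue, identity_pct=bh.identity_pct,
            coverage_pct=bh.coverage_pct))
        provenance[a.final_name] = tuple(sorted(
            {rec_map[m].source for m in g.member_ids}))

    counts: dict[str, int] = {}
    for e in entries:
        counts[e.classification] = counts.get(e.classification, 0) + 1

    report = RepertoireReport(entries=entries, groups=groups,
                              assignments=assignments, subfamily_counts=counts,
                              provenance=provenance, newick=str(tree).strip())
    if outdir:
        _write_outputs(report, pair_hits, outdir)
    log.info("stage=report entries=%d", len(entries))
    return report


def _write_classification(kept, subfamilies, sp_calls, path, classifier, spcfg):
    rows = []
    for r in kept:
        sp, sc = call_and_classify(r.seq, classifier, spcfg)
        cys = ";".join(str(p) for m in sc.motif_positions for p in m)
        rows.append((r.id, subfamilies[r.id], sc.motif_count, cys,
                     sp.cleavage_after if sp.present else 0))
    pd.DataFrame(rows, columns=["id", "subfamily", "motif_count",
                                "motif_cysteines", "sp_cleavage"]
                 ).to_csv(path, sep="\t", index=False)


def _write_outputs(report: RepertoireReport, pair_hits, outdir: Path) -> None:
    write_repertoire_table(report.entries, outdir / "repertoire.tsv")
    hits_to_table(pair_hits).to_csv(outdir / "pairwise_hits.tsv", sep="\t",
                                    index=False)
    pd.DataFrame(
        [(g.group_id, ",".join(g.member_ids), g.representative_id,
          (g.best_hit.subject_id or "–") if g.best_hit else "–", g.subfamily)
         for g in report.groups],
        columns=["group", "members", "representative", "best_hit", "subfamily"],
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(a.group_id, a.final_name, a.suffix_kind, a.rule, a.evidence)
         for a in report.assignments],
        columns=["group", "name", "suffix_kind", "rule", "evidence"],
    ).to_csv(outdir / "naming.tsv", sep="\t", index=False)
    (outdir / "tree.nwk").write_text(report.newick + "\n", encoding="utf-8")


def summarize_report(entries: Sequence[CuratedEntry],
                     provenance: Optional[dict] = None) -> dict:
    """Tallies over a curated repertoire: totals, per-subfamily counts,
    signal-peptide presence, suffix kinds, accession prefixes, sources,
    and per-base like-subgroup counts."""
    by_subfamily: dict[str, int] = {}
    by_suffix: dict[str, int] = {}
    by_prefix: dict[str, int] = {}
    like_subgroups: dict[str, set] = {}
    sp_present = 0
    for e in entries:
        by_subfamily[e.classification] = by_subfamily.get(e.classification, 0) + 1
        if e.signal_peptide is not None:
            sp_present += 1
        acc_prefix = "".join(ch for ch in e.accession if ch.isalpha())[:2]
        by_prefix[acc_prefix] = by_prefix.get(acc_prefix, 0) + 1
        try:
            parsed = parse_name(e.name)
        except ValueError:
            continue
        by_suffix[parsed.suffix_kind] = by_suffix.get(parsed.suffix_kind, 0) + 1
        if parsed.suffix_kind == "like_numbered":
            like_subgroups.setdefault(parsed.base, set()).add(parsed.suffix_value)
    by_source: dict[str, int] = {}
    if provenance:
        for sources in provenance.values():
            for s in sources:
                by_source[s] = by_source.get(s, 0) + 1
    return {
        "n_entries": len(entries),
        "by_subfamily": dict(sorted(by_subfamily.items())),
        "signal_peptide_present": sp_present,
        "by_suffix_kind": dict(sorted(by_suffix.items())),
        "by_accession_prefix": dict(sorted(by_prefix.items())),
        "by_source": dict(sorted(by_source.items())),
        "like_subgroup_counts": {b: len(v) for b, v in sorted(like_subgroups.items())},
    }


def summarize_packaged_repertoire() -> dict:
    """Summary of the packaged 48-entry curated table."""
    return summarize_report(load_repertoire_table())
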