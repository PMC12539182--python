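"""Pairwise local alignment with BLAST-style statistics.

Smith–Waterman alignment with affine gaps (BLOSUM62, open 11, extend 1,
via Bio.Align.PairwiseAligner), reporting identity, query coverage, bit
score and a Karlin–Altschul E-value

    bit = (lambda * raw - ln K) / ln 2,      E = m * n * 2**(-bit)

with m the query length and n the total subject (database) residues.
Composition-based statistics and database-size corrections are omitted;
E-values are nominal, desk-scale quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties, and Karlin–Altschul
    parameters (BLASTp defaults for BLOSUM62 11/1 gapped searches)."""

    matrix: str = "BLOSUM62"
    gap_open: int = 11    # positive penalty charged at gap opening
    gap_extend: int = 1   # positive penalty per gap residue
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")


DEFAULT_SCHEME = ScoringScheme()


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load(scheme.matrix)
    # PairwiseAligner charges open_gap_score for the first gap residue
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    al.mode = mode
    return al


@dataclass(frozen=True)
class HomologyHit:
    """One query/subject local alignment.

    ``identity_pct`` follows the BLAST convention (identities over all
    alignment columns, gap columns included); ``identity_nongap_pct`` is the
    same count over aligned (non-gap) columns only and is the similarity
    used for redundancy grouping.  ``coverage_pct`` is query coverage.
    """

    query_id: str
    subject_id: Optional[str]
    identity_pct: float
    coverage_pct: float
    raw_score: float
    bit_score: float
    evalue: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    alignment_columns: int = 0
    identities: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    identity_nongap_pct: float = 0.0
    max_internal_gap: int = 0
    no_hit: bool = False


def bit_score(raw: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    return (scheme.lam * raw - math.log(scheme.k)) / math.log(2.0)


def evalue(bit: float, m: int, n: int) -> float:
    """Expected chance alignments at this bit score for query length m and
    database size n (residues); strictly decreasing in the bit score."""
    if m < 1 or n < 1:
        raise ValueError("sequence/database sizes must be >= 1")
    return float(m) * float(n) * 2.0 ** (-bit)


def _no_hit(query_id: str) -> HomologyHit:
    return HomologyHit(query_id=query_id, subject_id=None, identity_pct=0.0,
                       coverage_pct=0.0, raw_score=0.0, bit_score=0.0,
                       evalue=math.inf, no_hit=True)


def score_local(query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                ) -> float:
    """Optimal local alignment score only (fast path, no traceback)."""
    if not query or not subject:
        raise ValueError("empty sequence")
    return float(_aligner(scheme, "local").score(query, subject))


def align_local(query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME,
                query_id: str = "query", subject_id: str = "subject",
                db_residues: Optional[int] = None) -> HomologyHit:
    """Optimal Smith–Waterman alignment of two proteins.

    ``db_residues`` sets n of the E-value (defaults to the subject length,
    i.e. a single-sequence database).  A non-positive optimal score yields
    a ``no_hit`` marker.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    al = _aligner(scheme, "local")
    score = float(al.score(query, subject))
    if score <= 0:
        return _no_hit(query_id)
    aln = al.align(query, subject)[0]
    qblocks, sblocks = aln.aligned
    identities = mismatches = 0
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        for x, y in zip(query[qa:qb], subject[sa:sb]):
            if x == y:
                identities += 1
            else:
                mismatches += 1
    gap_cols = gap_opens = max_gap = 0
    for k in range(1, len(qblocks)):
        qg = qblocks[k][0] - qblocks[k - 1][1]
        sg = sblocks[k][0] - sblocks[k - 1][1]
        for g in (qg, sg):
            if g > 0:
                gap_cols += g
                gap_opens += 1
                max_gap = max(max_gap, g)
    columns = identities + mismatches + gap_cols
    q_start, q_end = int(qblocks[0][0]) + 1, int(qblocks[-1][1])
    s_start, s_end = int(sblocks[0][0]) + 1, int(sblocks[-1][1])
    bit = bit_score(score, scheme)
    n = db_residues if db_residues is not None else len(subject)
    return HomologyHit(
        query_id=query_id, subject_id=subject_id,
        identity_pct=100.0 * identities / columns,
        coverage_pct=100.0 * (q_end - q_start + 1) / len(query),
        raw_score=score, bit_score=bit, evalue=evalue(bit, len(query), n),
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        alignment_columns=columns, identities=identities, mismatches=mismatches,
        gap_opens=gap_opens,
        identity_nongap_pct=100.0 * identities / max(identities + mismatches, 1),
        max_internal_gap=max_gap)


def best_hit(query: SequenceRecord, refs: Sequence[SequenceRecord],
             scheme: ScoringScheme = DEFAULT_SCHEME) -> HomologyHit:
    """Best-scoring reference hit; ties broken by higher identity, then
    lexicographically smaller subject id.  E-values use the whole reference
    set as the database size."""
    if not refs:
        raise ValueError("reference set is empty")
    db_residues = sum(len(r.seq) for r in refs)
    scores = [(score_local(query.seq, r.seq, scheme), r) for r in refs]
    top = max(s for s, _ in scores)
    if top <= 0:
        return _no_hit(query.id)
    tied = [r for s, r in scores if s == top]
    hits = [align_local(query.seq, r.seq, scheme, query_id=query.id,
                        subject_id=r.id, db_residues=db_residues) for r in tied]
    hits.sort(key=lambda h: (-h.identity_pct, h.subject_id))
    return hits[0]


def all_vs_all_hits(records: Sequence[SequenceRecord],
                    scheme: ScoringScheme = DEFAULT_SCHEME,
                    screen_score_per_residue: float = 0.0) -> list[HomologyHit]:
    """Hits for every unordered pair of records (i < j order preserved).

    ``screen_score_per_residue`` > 0 enables a score prefilter: pairs whose
    optimal local score is below ``screen * min(len_i, len_j)`` are emitted
    as no_hit markers without a traceback.  High-identity pairs (the ones
    redundancy grouping acts on) score several units per residue, so a
    screen of ~1.0 is conservative for them.
    """
    out = []
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            if screen_score_per_residue > 0:
                s = score_local(a.seq, b.seq, scheme)
                if s < screen_score_per_residue * min(len(a.seq), len(b.seq)):
                    out.append(_no_hit(a.id))
                    continue
            out.append(align_local(a.seq, b.seq, scheme,
                                   query_id=a.id, subject_id=b.id))
    return [h for h in out if not h.no_hit]


OUTFMT6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore")


def hits_to_table(hits: Iterable[HomologyHit]) -> pd.DataFrame:
    """Tabulate hits in BLAST outfmt-6 column order."""
    rows = [(h.query_id, h.subject_id, round(h.identity_pct, 2),
             h.alignment_columns, h.mismatches, h.gap_opens,
             h.q_start, h.q_end, h.s_start, h.s_end,
             float(f"{h.evalue:.3g}") if math.isfinite(h.evalue) else math.inf,
             round(h.bit_score, 1))
            for h in hits if not h.no_hit]
    return pd.DataFrame(rows, columns=list(OUTFMT6_COLUMNS))
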