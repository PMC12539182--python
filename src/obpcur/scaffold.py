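"""Conserved-cysteine scaffold detection and OBP subfamily classification.

Insect odorant-binding proteins are defined by a six-cysteine scaffold
(C1..C6) whose hallmark spacings are C2-X3-C3 (exactly 3 intervening
residues) and C5-X8-C6 (exactly 8), with the remaining inter-cysteine gaps
falling into broad windows.  Subfamilies are called from the motif content
of the mature sequence:

* Atypical — two complete six-cysteine motifs on one polypeptide
  (C1..C6 and C1*..C6*);
* Plus-C — one motif plus extra conserved cysteines (canonically 10 total)
  and a conserved proline shortly after C6;
* Classical — exactly one motif and no qualifying extras;
* Minus-C — no motif and a reduced count of 4 cysteines, modeled as the
  classical scaffold lacking C2 and C5, with only window plausibility
  enforced (the hallmark gaps involve the deleted residues);
* Unclassified — anything else.

Precedence is most-specific-first (Atypical > Plus-C > Classical > Minus-C)
so that a Plus-C sequence never degrades to a trivial Classical match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import PROTEIN_CHARS, SequenceRecord
from .sigpep import SignalPeptideCall


@dataclass(frozen=True)
class ClassifierConfig:
    """Gap constraints and subfamily thresholds (residue counts are numbers
    of residues strictly between the two cysteines)."""

    c2_c3_gap: int = 3          # hallmark C2-X3-C3
    c5_c6_gap: int = 8          # hallmark C5-X8-C6
    gap_tolerance: int = 0      # slack on the two hallmark gaps
    c1_c2_window: tuple[int, int] = (15, 45)
    c3_c4_window: tuple[int, int] = (20, 60)
    c4_c5_window: tuple[int, int] = (4, 25)
    plusc_min_extra: int = 2    # extra cysteines beyond 6 (canonical total 10)
    proline_window: int = 3     # residues after C6 in which the proline must occur
    minusc_count: int = 4
    min_mature_len: int = 80
    max_mature_len: int = 400


DEFAULT_CLASSIFIER = ClassifierConfig()

SUBFAMILIES = ("Classical", "Plus-C", "Minus-C", "Atypical", "Unclassified")


@dataclass(frozen=True)
class CysteineScaffold:
    """Assigned conserved-cysteine positions (1-based) and subfamily call."""

    motif_positions: tuple[tuple[int, ...], ...]  # one 6-tuple per motif
    extra_cysteines: tuple[int, ...]
    proline_after_c6: bool
    motif_count: int
    subfamily: str
    conserved_cysteine_count: int


def cysteine_positions(seq: str) -> list[int]:
    """1-based positions of every cysteine."""
    return [i for i, aa in enumerate(seq, start=1) if aa == "C"]


def _hallmark_ok(gap: int, target: int, tol: int) -> bool:
    return abs(gap - target) <= tol


def _window_ok(gap: int, window: tuple[int, int]) -> bool:
    return window[0] <= gap <= window[1]


def _candidate_motifs(cys: list[int], cfg: ClassifierConfig):
    """All 6-tuples of cysteine positions satisfying the gap constraints,
    in lexicographic order (depth-first over increasing positions)."""
    n = len(cys)
    tol = cfg.gap_tolerance
    out = []
    for i1 in range(n):
        for i2 in range(i1 + 1, n):
            g = cys[i2] - cys[i1] - 1
            if g > cfg.c1_c2_window[1]:
                break
            if not _window_ok(g, cfg.c1_c2_window):
                continue
            for i3 in range(i2 + 1, n):
                g = cys[i3] - cys[i2] - 1
                if g > cfg.c2_c3_gap + tol:
                    break
                if not _hallmark_ok(g, cfg.c2_c3_gap, tol):
                    continue
                for i4 in range(i3 + 1, n):
                    g = cys[i4] - cys[i3] - 1
                    if g > cfg.c3_c4_window[1]:
                        break
                    if not _window_ok(g, cfg.c3_c4_window):
                        continue
                    for i5 in range(i4 + 1, n):
                        g = cys[i5] - cys[i4] - 1
                        if g > cfg.c4_c5_window[1]:
                            break
                        if not _window_ok(g, cfg.c4_c5_window):
                            continue
                        for i6 in range(i5 + 1, n):
                            g = cys[i6] - cys[i5] - 1
                            if g > cfg.c5_c6_gap + tol:
                                break
                            if not _hallmark_ok(g, cfg.c5_c6_gap, tol):
                                continue
                            out.append((cys[i1], cys[i2], cys[i3],
                                        cys[i4], cys[i5], cys[i6]))
    return out


def find_classical_motifs(seq: str, config: ClassifierConfig = DEFAULT_CLASSIFIER,
                          ) -> list[tuple[int, ...]]:
    """Non-overlapping six-cysteine motifs, chosen greedily leftmost-first
    from the lexicographically ordered candidate set."""
    cys = cysteine_positions(seq)
    chosen: list[tuple[int, ...]] = []
    used: set[int] = set()
    for cand in _candidate_motifs(cys, config):
        if used.isdisjoint(cand):
            chosen.append(cand)
            used.update(cand)
    return chosen


def _proline_after(seq: str, c6: int, window: int) -> bool:
    # residues c6+1 .. c6+window, 1-based
    return "P" in seq[c6:c6 + window]


def _minusc_plausible(cys: list[int], cfg: ClassifierConfig) -> bool:
    """Window plausibility for 4 cysteines read as C1, C3, C4, C6 of a
    classical scaffold that lost C2 and C5."""
    if len(cys) != 4:
        return False
    p1, p3, p4, p6 = cys
    g13 = p3 - p1 - 1
    g34 = p4 - p3 - 1
    g46 = p6 - p4 - 1
    lo13 = cfg.c1_c2_window[0] + 1 + cfg.c2_c3_gap
    hi13 = cfg.c1_c2_window[1] + 1 + cfg.c2_c3_gap
    lo46 = cfg.c4_c5_window[0] + 1 + cfg.c5_c6_gap
    hi46 = cfg.c4_c5_window[1] + 1 + cfg.c5_c6_gap
    return (lo13 <= g13 <= hi13
            and _window_ok(g34, cfg.c3_c4_window)
            and lo46 <= g46 <= hi46)


def classify_scaffold(seq: str, config: ClassifierConfig = DEFAULT_CLASSIFIER,
                      ) -> CysteineScaffold:
    """Classify a mature protein sequence into an OBP subfamily."""
    seq = seq.upper()
    illegal = set(seq) - PROTEIN_CHARS
    if illegal:
        raise ValueError(f"non-protein symbols in sequence: {sorted(illegal)!r}")

    cys = cysteine_positions(seq)
    motifs = find_classical_motifs(seq, config)
    in_motifs = {p for m in motifs for p in m}
    extras = tuple(p for p in cys if p not in in_motifs)
    proline = bool(motifs) and _proline_after(seq, motifs[0][5], config.proline_window)

    if len(motifs) >= 2:
        subfamily = "Atypical"
        count = 6 * len(motifs)
    elif len(motifs) == 1 and len(extras) >= config.plusc_min_extra and proline:
        subfamily = "Plus-C"
        count = 6 + len(extras)
    elif len(motifs) == 1:
        subfamily = "Classical"
        count = 6
    elif not motifs and _minusc_plausible(cys, config):
        subfamily = "Minus-C"
        count = config.minusc_count
    else:
        subfamily = "Unclassified"
        count = 0

    return CysteineScaffold(
        motif_positions=tuple(motifs),
        extra_cysteines=extras,
        proline_after_c6=proline,
        motif_count=len(motifs),
        subfamily=subfamily,
        conserved_cysteine_count=count,
    )


def is_obp_candidate(record: SequenceRecord, scaffold: CysteineScaffold,
                     sp: SignalPeptideCall,
                     config: ClassifierConfig = DEFAULT_CLASSIFIER) -> bool:
    """Candidate filter: a recognizable scaffold and a plausible mature
    length.  A signal peptide is deliberately NOT required — curated
    repertoires retain members whose N-termini diverged past detection."""
    mature_len = len(record.seq) - (sp.cleavage_after if sp.present else 0)
    return (scaffold.subfamily != "Unclassified"
            and config.min_mature_len <= mature_len <= config.max_mature_len)
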