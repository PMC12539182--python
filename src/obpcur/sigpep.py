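"""Rule-based N-terminal signal-peptide caller.

A deterministic, configurable heuristic built from the classical tripartite
signal-peptide model: a positively charged n-region, a hydrophobic h-region
(Kyte–Doolittle), and small residues at the (-3,-1) positions of the
cleavage site.  It produces the present/absent call plus a 1..cleavage_after
range compatible with curated-repertoire "1-24"-style annotations.  It is a
simplified stand-in for neural-network predictors such as SignalP and makes
no attempt to reproduce their probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

SMALL_RESIDUES = frozenset("AGSCT")
POSITIVE_RESIDUES = frozenset("KR")


@dataclass(frozen=True)
class SigpepConfig:
    """Weights and search window of the signal-peptide score.

    score(c) = weight_charge * (1 if any K/R among residues 1..5 else 0)
             + weight_hydro  * (max mean Kyte-Doolittle over a 7-residue
                                window between positions 5 and c-3)
             + small_bonus per small residue at positions c-2 and c
    present iff max_c score(c) >= threshold, c in [min_cleavage, max_cleavage].
    """

    weight_charge: float = 1.0
    weight_hydro: float = 1.0
    small_bonus: float = 0.5
    threshold: float = 2.5
    min_cleavage: int = 10
    max_cleavage: int = 45
    hydro_window: int = 7
    min_length: int = 30


DEFAULT_SIGPEP = SigpepConfig()


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool
    cleavage_after: int  # signal peptide = residues 1..cleavage_after (1-based)
    score: float


def predict_signal_peptide(seq: str, config: SigpepConfig = DEFAULT_SIGPEP,
                           ) -> SignalPeptideCall:
    """Deterministically score candidate cleavage sites of a protein.

    Sequences shorter than ``config.min_length`` return an absent call with
    a warning (they cannot carry both a signal and a mature domain).
    """
    seq = seq.upper()
    if len(seq) < config.min_length:
        warnings.warn(
            f"sequence of length {len(seq)} too short for signal-peptide "
            f"prediction (minimum {config.min_length})", stacklevel=2)
        return SignalPeptideCall(present=False, cleavage_after=0, score=0.0)

    charge = config.weight_charge * any(aa in POSITIVE_RESIDUES for aa in seq[:5])
    w = config.hydro_window
    # prefix sums of KD values for O(1) window means
    kdv = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq]
    pref = [0.0]
    for v in kdv:
        pref.append(pref[-1] + v)

    best_score, best_c = None, 0
    hi = min(config.max_cleavage, len(seq) - 1)
    for c in range(config.min_cleavage, hi + 1):
        # 0-based window starts: residues 5..c-3 (1-based) => [4, c-4]
        lo_s, hi_s = 4, (c - 4) - (w - 1)
        hydro = 0.0
        if hi_s >= lo_s:
            hydro = max((pref[s + w] - pref[s]) / w for s in range(lo_s, hi_s + 1))
        bonus = config.small_bonus * ((seq[c - 3] in SMALL_RESIDUES)
                                      + (seq[c - 1] in SMALL_RESIDUES))
        score = charge + config.weight_hydro * hydro + bonus
        if best_score is None or score > best_score:
            best_score, best_c = score, c
    present = best_score is not None and best_score >= config.threshold
    return SignalPeptideCall(present=present,
                             cleavage_after=best_c if present else 0,
                             score=float(best_score if best_score is not None else 0.0))


def mature_sequence(seq: str, call: SignalPeptideCall) -> str:
    """Sequence with the called signal peptide removed (identity if absent)."""
    return seq[call.cleavage_after:] if call.present else seq
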