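"""Six-frame ORF finding and translation for nucleotide transcripts.

ORFs are ATG-anchored, use the standard genetic code, and are reported
complete only when a stop codon terminates the span (longest-ORF-per-stop
convention; nested ATGs are not reported separately).  An ORF that runs off
the transcript end is reported with ``complete=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .seqio import SequenceRecord

FRAME_ORDER = (1, 2, 3, -1, -2, -3)

#: minimum translated length, in residues, for a reported ORF
DEFAULT_MIN_AA = 100


@dataclass(frozen=True)
class OrfCall:
    frame: int                 # one of +1,+2,+3,-1,-2,-3
    nt_start: int              # 1-based inclusive, on the input sequence
    nt_end: int                # 1-based inclusive; includes the stop codon if any
    protein: str               # translation, stop symbol excluded
    complete: bool             # starts with M and terminated by a stop codon


def translate(nt: str) -> str:
    """Standard-code translation; internal stops render ``*``.

    The input length must be divisible by 3.
    """
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    if not nt:
        return ""
    return str(Seq(nt).translate())


def find_orfs(record: SequenceRecord, min_aa: int = DEFAULT_MIN_AA) -> list[OrfCall]:
    """Scan all six frames of a nucleotide record for ATG-anchored ORFs.

    Returns calls with protein length >= ``min_aa``, sorted by protein
    length descending, ties by (frame order +1..+3,-1..-3, nt_start).
    """
    if record.alphabet != "nucleotide":
        raise ValueError(f"record {record.id!r}: find_orfs requires nucleotide input")
    seq = record.seq
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    calls: list[OrfCall] = []
    for frame in FRAME_ORDER:
        oriented = seq if frame > 0 else rc
        offset = abs(frame) - 1
        coding = oriented[offset:]
        coding = coding[: len(coding) // 3 * 3]
        if not coding:
            continue
        prot = translate(coding)
        calls.extend(_scan_frame(prot, frame, offset, L, min_aa))
    calls.sort(key=lambda c: (-len(c.protein), FRAME_ORDER.index(c.frame), c.nt_start))
    return calls


def _scan_frame(prot: str, frame: int, offset: int, L: int, min_aa: int):
    """Yield OrfCalls for one translated frame string."""
    n = len(prot)
    seg_start = 0
    while seg_start < n:
        stop = prot.find("*", seg_start)
        seg_end = stop if stop != -1 else n          # exclusive, codons
        m = prot.find("M", seg_start, seg_end)
        if m != -1:
            protein = prot[m:seg_end]
            complete = stop != -1
            last_codon = seg_end if complete else seg_end - 1  # include stop codon
            if len(protein) >= min_aa:
                start_f = offset + 3 * m                    # 0-based on oriented seq
                end_f = offset + 3 * last_codon + 2
                if frame > 0:
                    nt_start, nt_end = start_f + 1, end_f + 1
                else:
                    nt_start, nt_end = L - end_f, L - start_f
                yield OrfCall(frame=frame, nt_start=nt_start, nt_end=nt_end,
                              protein=protein, complete=complete)
        seg_start = seg_end + 1 if stop != -1 else n
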