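"""Sequence and table I/O.

FASTA reading/writing (via Biopython), source-tagged sequence records, and
the packaged curated-repertoire table of 48 medfly (*Ceratitis capitata*)
odorant-binding proteins homologized against *D. melanogaster*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_CHARS = frozenset("ACGTN")
SOURCES = ("genomeA", "genomeB", "genbank", "transcriptome", "reference", "synthetic")

#: columns of the curated-repertoire TSV, in order
TABLE_COLUMNS = (
    "name", "accession", "aa_length", "signal_peptide", "classification",
    "hit_accession", "hit_description", "evalue", "identity_pct", "coverage_pct",
)

#: tokens mapped to an absent value in TSV cells
ABSENT_TOKENS = {"–", "-", ""}


@dataclass
class SequenceRecord:
    """A protein or nucleotide sequence with provenance tags.

    Coordinates used throughout the package are 1-based inclusive.
    """

    id: str
    seq: str
    alphabet: str = "protein"  # "protein" | "nucleotide"
    source: str = "synthetic"
    complete_orf: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        legal = PROTEIN_CHARS if self.alphabet == "protein" else NUCLEOTIDE_CHARS
        if self.alphabet not in ("protein", "nucleotide"):
            raise ValueError(f"record {self.id!r}: unknown alphabet {self.alphabet!r}")
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in legal:
                raise ValueError(
                    f"record {self.id!r}: illegal {self.alphabet} symbol "
                    f"{ch!r} at position {pos}"
                )
        if self.source not in SOURCES:
            raise ValueError(f"record {self.id!r}: unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CuratedEntry:
    """One row of the curated repertoire (the Table-1-style report schema)."""

    name: str
    accession: str
    aa_length: int
    signal_peptide: Optional[tuple[int, int]]  # 1-based inclusive, or None
    classification: str
    hit_accession: str
    hit_description: str
    evalue: float
    identity_pct: float
    coverage_pct: float

    def __post_init__(self) -> None:
        if self.aa_length < 1:
            raise ValueError(f"{self.name}: aa_length must be >= 1")
        for label, v in (("identity_pct", self.identity_pct),
                         ("coverage_pct", self.coverage_pct)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.name}: {label} {v} outside [0, 100]")
        if self.signal_peptide is not None:
            a, b = self.signal_peptide
            if a != 1 or not (a <= b < self.aa_length):
                raise ValueError(
                    f"{self.name}: signal peptide range {a}-{b} invalid for "
                    f"length {self.aa_length}"
                )


def read_fasta(path, alphabet: str = "protein", source: str = "synthetic",
               ) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The id is the header token up to the first whitespace; the remainder is
    kept as the description.  ``source=<tag>`` and ``complete=<0|1>``
    key-value tokens in the description, as written by :func:`write_fasta`,
    override the defaults.  Duplicate ids and alphabet-illegal characters
    raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        rec_source, complete = source, False
        plain_tokens = []
        for tok in desc.split():
            if tok.startswith("source="):
                rec_source = tok[7:]
            elif tok.startswith("complete="):
                complete = tok[9:] == "1"
            else:
                plain_tokens.append(tok)
        records.append(SequenceRecord(
            id=rec.id, seq=str(rec.seq), alphabet=alphabet, source=rec_source,
            complete_orf=complete, description=" ".join(plain_tokens)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60,
                tags: bool = True) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns.

    With ``tags=True`` the provenance fields are serialized into the
    description so that ``read_fasta`` round-trips them.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            parts = [r.description] if r.description else []
            if tags:
                parts.append(f"source={r.source}")
                parts.append(f"complete={1 if r.complete_orf else 0}")
            header = r.id if not parts else r.id + " " + " ".join(parts)
            fh.write(f">{header}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i:i + width] + "\n")


def _parse_sp_range(token: str, row_label: str) -> Optional[tuple[int, int]]:
    token = token.strip()
    if token in ABSENT_TOKENS:
        return None
    try:
        a, b = token.split("-")
        return int(a), int(b)
    except Exception as exc:
        raise ValueError(
            f"row {row_label!r}: cannot parse signal-peptide range {token!r}"
        ) from exc


def load_repertoire_table(path=None) -> list[CuratedEntry]:
    """Load a curated-repertoire TSV; with ``path=None``, the packaged table
    of the 48 homologized CcapOBPs."""
    if path is None:
        path = packaged_table_path()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    entries = []
    for _, row in df.iterrows():
        label = row["name"]

        def num(col, cast, label=label, row=row):
            try:
                return cast(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"row {label!r}: unparseable {col} value {row[col]!r}"
                ) from exc

        entries.append(CuratedEntry(
            name=label,
            accession=row["accession"],
            aa_length=num("aa_length", int),
            signal_peptide=_parse_sp_range(row["signal_peptide"], label),
            classification=row["classification"],
            hit_accession=row["hit_accession"],
            hit_description=row["hit_description"],
            evalue=num("evalue", float),
            identity_pct=num("identity_pct", float),
            coverage_pct=num("coverage_pct", float),
        ))
    return entries


def write_repertoire_table(entries: Iterable[CuratedEntry], path) -> None:
    """Write curated entries in the packaged-table TSV layout (deterministic
    formatting: E-values in scientific notation, percentages to 2 dp)."""
    rows = []
    for e in entries:
        sp = "–" if e.signal_peptide is None else f"{e.signal_peptide[0]}-{e.signal_peptide[1]}"
        ev = "inf" if math.isinf(e.evalue) else f"{e.evalue:.2E}"
        rows.append((e.name, e.accession, str(e.aa_length), sp, e.classification,
                     e.hit_accession, e.hit_description, ev,
                     f"{e.identity_pct:.2f}", f"{e.coverage_pct:.2f}"))
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)


def packaged_table_path() -> Path:
    """Path of the packaged 48-entry curated repertoire table."""
    return Path(resources.files("obpcur").joinpath("data/ccap_obp_table1.tsv"))
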