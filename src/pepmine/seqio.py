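"""Protein sequence and tabular I/O.

Conventions enforced here and relied on by every other module:

* residue coordinates are **1-based and inclusive** (the ``f (97-99)``
  notation of peptide-profiling reports);
* sequences are uppercased on ingestion and validated against the 20
  standard one-letter amino-acid codes. ``strict`` policy (default)
  rejects anything else; ``lenient`` keeps the ambiguity/rare codes
  X, B, Z, U, O, which downstream never match cleavage patterns or
  dictionary peptides.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("XBZUO")
_KNOWN_AA = STANDARD_AA | AMBIGUOUS_AA


class SequenceValidationError(ValueError):
    """A sequence contains characters not allowed under the active policy."""


def validate_sequence(sequence: str, policy: str = "strict", record_id: str = "?") -> str:
    """Uppercase and validate a raw sequence string.

    Returns the canonical (uppercase) form or raises
    :class:`SequenceValidationError` naming the offending record and the
    1-based position of the first illegal character.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown residue policy: {policy!r}")
    seq = sequence.upper()
    allowed = STANDARD_AA if policy == "strict" else _KNOWN_AA
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise SequenceValidationError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos} "
                f"under {policy} policy"
            )
    if not seq:
        raise SequenceValidationError(f"record {record_id!r}: empty sequence")
    return seq


@dataclass(frozen=True, order=True)
class SequenceInterval:
    """A 1-based inclusive residue interval ``start..end``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def extract(self, sequence: str) -> str:
        """Substring of ``sequence`` covered by this interval."""
        if self.end > len(sequence):
            raise ValueError(
                f"interval {self} exceeds sequence of length {len(sequence)}"
            )
        return sequence[self.start - 1 : self.end]

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    ``n`` (the residue count) is the denominator of the occurrence and
    release frequencies computed downstream.
    """

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _KNOWN_AA
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: unknown residue characters {sorted(bad)!r}"
            )

    @classmethod
    def from_raw(
        cls, id: str, description: str, sequence: str, policy: str = "strict"
    ) -> "ProteinRecord":
        return cls(id, description, validate_sequence(sequence, policy, record_id=id))

    @property
    def n(self) -> int:
        """Residue count N."""
        return len(self.sequence)

    def slice(self, interval: SequenceInterval) -> str:
        return interval.extract(self.sequence)


def _as_handle(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    return open(Path(source), "r", encoding="utf-8")


def parse_fasta(source, policy: str = "strict") -> list[ProteinRecord]:
    """Parse a (possibly line-folded, multi-record) FASTA source.

    The record id is the first whitespace-delimited token of the header;
    the remainder becomes the description. Raises ``ValueError`` on an
    empty file and :class:`SequenceValidationError` on illegal residues.
    """
    handle = _as_handle(source)
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            records.append(ProteinRecord.from_raw(rec.id, desc, str(rec.seq), policy))
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise ValueError("no records found in FASTA source")
    return records


def parse_fasta_str(text: str, policy: str = "strict") -> list[ProteinRecord]:
    return parse_fasta(io.StringIO(text), policy=policy)


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as FASTA with deterministic, byte-stable formatting."""
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def write_table(
    rows: Sequence[Mapping[str, object]],
    path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write flat records as a tab-separated UTF-8 table with a header row.

    Row order is preserved exactly as given. ``columns`` fixes the header
    (required when ``rows`` is empty; otherwise inferred from the first row).
    """
    if columns is None:
        if not rows:
            raise ValueError("columns are required to write an empty table")
        columns = list(rows[0].keys())
    for i, row in enumerate(rows):
        if set(row.keys()) != set(columns):
            raise ValueError(f"row {i} fields {sorted(row)} do not match header {sorted(columns)}")
    frame = pd.DataFrame(list(rows), columns=list(columns))
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    """Read a tab-separated table written by :func:`write_table`.

    Values come back as strings (no NA coercion) so round-trips are exact.
    """
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
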