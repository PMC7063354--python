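"""The catalogue of known bioactive peptides.

A dictionary maps short peptide sequences (1-50 residues) to one or more
activity labels ("DPP-IV inhibitor", "ACE inhibitor", ...). Matching is
exact full-sequence equality over the 20-letter alphabet, case-insensitive
on input; a peptide whose lookup returns the empty set is *novel*.

Substring (occurrence) matching lives in :mod:`pepmine.profiles`; this
module only answers "is this exact peptide catalogued, and as what?".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator

import pandas as pd

from pepmine.seqio import STANDARD_AA

logger = logging.getLogger(__name__)

MAX_PEPTIDE_LENGTH = 50


@dataclass(frozen=True, order=True)
class PeptideEntry:
    """One catalogued peptide: sequence, activity label, free-text provenance."""

    sequence: str
    activity: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.strip().upper())
        object.__setattr__(self, "activity", self.activity.strip())
        if not self.sequence:
            raise ValueError("peptide entry requires a non-empty sequence")
        if len(self.sequence) > MAX_PEPTIDE_LENGTH:
            raise ValueError(
                f"peptide {self.sequence[:12]}... exceeds {MAX_PEPTIDE_LENGTH} residues"
            )
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(
                f"peptide {self.sequence!r}: non-standard residues {sorted(bad)!r}"
            )
        if not self.activity:
            raise ValueError(f"peptide {self.sequence!r}: empty activity label")


class BioactiveDictionary:
    """An indexed, deduplicated set of :class:`PeptideEntry`.

    Duplicate (sequence, activity) pairs collapse to one entry with a
    logged warning; an empty dictionary is an error.
    """

    def __init__(self, entries: Iterable[PeptideEntry]):
        seen: dict[tuple[str, str], PeptideEntry] = {}
        for entry in entries:
            key = (entry.sequence, entry.activity)
            if key in seen:
                logger.warning(
                    "duplicate dictionary entry collapsed: %s / %s",
                    entry.sequence,
                    entry.activity,
                )
                continue
            seen[key] = entry
        if not seen:
            raise ValueError("bioactive dictionary is empty")
        self._entries: tuple[PeptideEntry, ...] = tuple(
            sorted(seen.values(), key=lambda e: (e.sequence, e.activity))
        )
        index: dict[str, set[str]] = {}
        for entry in self._entries:
            index.setdefault(entry.sequence, set()).add(entry.activity)
        self._index: dict[str, frozenset[str]] = {
            seq: frozenset(acts) for seq, acts in index.items()
        }
        self._activities = frozenset(e.activity for e in self._entries)
        self._max_len = max(len(s) for s in self._index)

    @property
    def entries(self) -> tuple[PeptideEntry, ...]:
        return self._entries

    @property
    def activities(self) -> frozenset[str]:
        return self._activities

    @property
    def sequences(self) -> tuple[str, ...]:
        """Distinct peptide sequences, sorted."""
        return tuple(sorted(self._index))

    @property
    def max_peptide_length(self) -> int:
        return self._max_len

    def activities_of(self, peptide: str) -> frozenset[str]:
        """Activity labels catalogued for this exact peptide (empty = novel)."""
        return self._index.get(peptide.strip().upper(), frozenset())

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[PeptideEntry]:
        return iter(self._entries)

    def __contains__(self, peptide: str) -> bool:
        return peptide.strip().upper() in self._index


def load_dictionary(path) -> BioactiveDictionary:
    """Load a tab-separated dictionary file.

    Required columns: ``sequence``, ``activity``; optional ``source``.
    Malformed rows raise ``ValueError`` naming the data line number.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"sequence", "activity"} - set(frame.columns)
    if missing:
        raise ValueError(f"dictionary file missing columns: {sorted(missing)}")
    entries = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # line 1 = header
        try:
            entries.append(
                PeptideEntry(
                    sequence=row.sequence,
                    activity=row.activity,
                    source=getattr(row, "source", ""),
                )
            )
        except ValueError as exc:
            raise ValueError(f"dictionary line {i}: {exc}") from exc
    return BioactiveDictionary(entries)


def is_known(peptide: str, dictionary: BioactiveDictionary) -> frozenset[str]:
    """Activity labels under which ``peptide`` is catalogued (empty = novel)."""
    return dictionary.activities_of(peptide)


def bundled_dictionary() -> BioactiveDictionary:
    """The small demonstration dictionary shipped with the package.

    It holds the di-/tripeptide DPP-IV and ACE inhibitors used in the
    worked examples and tests. Real analyses should load a full external
    catalogue with :func:`load_dictionary`.
    """
    ref = resources.files("pepmine.data").joinpath("bioactive_dictionary.tsv")
    with resources.as_file(ref) as path:
        return load_dictionary(path)
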