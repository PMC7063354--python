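"""Profiles of potential biological activity.

For a protein of ``N`` residues and a bioactive-peptide dictionary, the
profile lists every position at which any catalogued peptide occurs as a
contiguous substring (overlaps and repeats all count, and a peptide
catalogued under k activities contributes to each of the k activities),
then summarizes per activity:

* ``a`` — occurrence count with multiplicity,
* ``A = a / N`` — frequency of occurrence (exact rational),
* ``sum_A`` — total over all activities present.

A per-activity *distinct* peptide count is reported alongside ``a`` for
transparency, since published totals sometimes sum types rather than
occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from pepmine.dictionary import BioactiveDictionary
from pepmine.display import format4
from pepmine.seqio import ProteinRecord, SequenceInterval


@dataclass(frozen=True, order=True)
class Occurrence:
    """One dictionary peptide found inside a protein."""

    interval: SequenceInterval
    peptide: str
    activity: str


def find_occurrences(
    protein: ProteinRecord, dictionary: BioactiveDictionary
) -> list[Occurrence]:
    """All occurrences of dictionary peptides in the protein sequence.

    Overlapping and repeated matches are all reported; results are sorted
    by position, then peptide, then activity.
    """
    sequence = protein.sequence
    found: list[Occurrence] = []
    for peptide in dictionary.sequences:
        start = sequence.find(peptide)
        while start != -1:
            interval = SequenceInterval(start + 1, start + len(peptide))
            for activity in sorted(dictionary.activities_of(peptide)):
                found.append(Occurrence(interval, peptide, activity))
            start = sequence.find(peptide, start + 1)
    found.sort()
    return found


@dataclass(frozen=True)
class ActivityOccurrences:
    """Occurrence summary for one activity inside one protein."""

    activity: str
    occurrences: tuple[Occurrence, ...]
    a: int
    a_distinct: int
    frequency: Fraction  # A = a / N

    @property
    def frequency_display(self) -> str:
        return format4(self.frequency)


@dataclass(frozen=True)
class ActivityProfile:
    """Per-activity occurrence statistics for one protein."""

    protein_id: str
    n: int
    records: dict[str, ActivityOccurrences]
    sum_a_frequency: Fraction  # sum(A) over activities present
    n_activities: int

    def frequency(self, activity: str) -> Fraction:
        """A for an activity (0 when the activity is absent)."""
        rec = self.records.get(activity)
        return rec.frequency if rec is not None else Fraction(0)

    def count(self, activity: str) -> int:
        rec = self.records.get(activity)
        return rec.a if rec is not None else 0

    @property
    def sum_a_display(self) -> str:
        return format4(self.sum_a_frequency)


def profile(protein: ProteinRecord, dictionary: BioactiveDictionary) -> ActivityProfile:
    """Compute the activity profile of a protein against a dictionary."""
    occurrences = find_occurrences(protein, dictionary)
    by_activity: dict[str, list[Occurrence]] = {}
    for occ in occurrences:
        by_activity.setdefault(occ.activity, []).append(occ)
    records = {}
    for activity in sorted(by_activity):
        occs = by_activity[activity]
        records[activity] = ActivityOccurrences(
            activity=activity,
            occurrences=tuple(occs),
            a=len(occs),
            a_distinct=len({o.peptide for o in occs}),
            frequency=Fraction(len(occs), protein.n),
        )
    total = sum((rec.frequency for rec in records.values()), Fraction(0))
    return ActivityProfile(
        protein_id=protein.id,
        n=protein.n,
        records=records,
        sum_a_frequency=total,
        n_activities=len(records),
    )


def profile_rows(prof: ActivityProfile) -> list[dict]:
    """Flatten a profile for the per-activity report table."""
    rows = []
    for activity, rec in prof.records.items():
        rows.append(
            {
                "protein_id": prof.protein_id,
                "activity": activity,
                "a": rec.a,
                "a_distinct": rec.a_distinct,
                "A": rec.frequency_display,
                "occurrences": ";".join(
                    f"{o.peptide}@{o.interval}" for o in rec.occurrences
                ),
            }
        )
    return rows


def summary_row(prof: ActivityProfile) -> dict:
    """One row of the roster summary (activity count and total frequency)."""
    return {
        "protein_id": prof.protein_id,
        "N": prof.n,
        "number_of_activities": prof.n_activities,
        "sum_A": prof.sum_a_display,
    }
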