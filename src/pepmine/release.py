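"""Release statistics: crossing a digestion with the dictionary.

A bioactive peptide counts as *released* only when its entire sequence
equals a digest fragment (full-fragment match); a catalogued peptide
buried inside a longer fragment is intrinsic but not released — this is
exactly the distinction between the occurrence frequency ``A = a/N`` and
the release frequency ``A_E = d/N``. The relative release frequency is
``W = A_E / A`` (undefined, reported as NA, when ``A = 0``).

``d`` counts multiplicity (one per released fragment occurrence), the
convention of inventory tables that annotate repetitions; a distinct
count is carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from pepmine.cleavage import DigestionResult
from pepmine.dictionary import BioactiveDictionary
from pepmine.display import format4
from pepmine.profiles import ActivityProfile
from pepmine.seqio import ProteinRecord, SequenceInterval


@dataclass(frozen=True)
class ReleasedPeptide:
    """One distinct released dictionary peptide with all its locations."""

    peptide: str
    multiplicity: int
    locations: tuple[SequenceInterval, ...]


def released_peptides(
    digestion: DigestionResult, dictionary: BioactiveDictionary
) -> dict[str, list[ReleasedPeptide]]:
    """Per-activity inventory of fragments that are dictionary peptides.

    Sorted by activity then peptide; multiplicity is the number of
    distinct fragment locations carrying that sequence.
    """
    per_activity: dict[str, dict[str, list[SequenceInterval]]] = {}
    for fragment, interval in digestion.fragments:
        for activity in dictionary.activities_of(fragment):
            per_activity.setdefault(activity, {}).setdefault(fragment, []).append(
                interval
            )
    inventory: dict[str, list[ReleasedPeptide]] = {}
    for activity in sorted(per_activity):
        inventory[activity] = [
            ReleasedPeptide(peptide, len(locs), tuple(locs))
            for peptide, locs in sorted(per_activity[activity].items())
        ]
    return inventory


@dataclass(frozen=True)
class ActivityRelease:
    """Release summary for one activity under one digestion."""

    activity: str
    released: tuple[ReleasedPeptide, ...]
    d: int
    d_distinct: int
    release_frequency: Fraction  # A_E = d / N
    relative_release: Fraction | None  # W = A_E / A; None when A = 0

    @property
    def release_frequency_display(self) -> str:
        return format4(self.release_frequency)

    @property
    def relative_release_display(self) -> str:
        return "NA" if self.relative_release is None else format4(self.relative_release)


@dataclass(frozen=True)
class ReleaseProfile:
    """Per-activity release statistics for one protein x enzyme run."""

    protein_id: str
    enzyme_ids: tuple[str, ...]
    n: int
    dh: Fraction
    records: dict[str, ActivityRelease]
    digestion: DigestionResult

    @property
    def dh_display(self) -> str:
        return format4(self.dh)


def release_profile(
    protein: ProteinRecord,
    digestion: DigestionResult,
    dictionary: BioactiveDictionary,
    activity_profile: ActivityProfile,
) -> ReleaseProfile:
    """Compute A_E and W per activity from a digest and a matching profile.

    The digest and the profile must describe the same protein; activities
    present in the profile but never released appear with ``d = 0`` and
    ``W = 0`` so report tables stay complete.
    """
    if digestion.protein_id != protein.id or activity_profile.protein_id != protein.id:
        raise ValueError(
            f"mismatched inputs: protein {protein.id!r}, digest "
            f"{digestion.protein_id!r}, profile {activity_profile.protein_id!r}"
        )
    inventory = released_peptides(digestion, dictionary)
    activities = sorted(set(inventory) | set(activity_profile.records))
    records = {}
    for activity in activities:
        released = tuple(inventory.get(activity, []))
        d = sum(r.multiplicity for r in released)
        a_freq = activity_profile.frequency(activity)
        release_freq = Fraction(d, protein.n)
        relative = release_freq / a_freq if a_freq > 0 else None
        records[activity] = ActivityRelease(
            activity=activity,
            released=released,
            d=d,
            d_distinct=len(released),
            release_frequency=release_freq,
            relative_release=relative,
        )
    return ReleaseProfile(
        protein_id=protein.id,
        enzyme_ids=digestion.enzyme_ids,
        n=protein.n,
        dh=digestion.dh,
        records=records,
        digestion=digestion,
    )


def release_rows(rp: ReleaseProfile) -> list[dict]:
    """Per-activity summary rows (DH, A_E, W)."""
    rows = []
    for activity, rec in rp.records.items():
        rows.append(
            {
                "protein_id": rp.protein_id,
                "enzymes": "+".join(rp.enzyme_ids),
                "DH": rp.dh_display,
                "activity": activity,
                "d": rec.d,
                "d_distinct": rec.d_distinct,
                "A_E": rec.release_frequency_display,
                "W": rec.relative_release_display,
            }
        )
    return rows


def inventory_rows(rp: ReleaseProfile) -> list[dict]:
    """Released-peptide inventory rows with repetition counts and locations."""
    rows = []
    for activity, rec in rp.records.items():
        for rel in rec.released:
            rows.append(
                {
                    "protein_id": rp.protein_id,
                    "enzymes": "+".join(rp.enzyme_ids),
                    "activity": activity,
                    "peptide": rel.peptide,
                    "multiplicity": rel.multiplicity,
                    "locations": ";".join(str(iv) for iv in rel.locations),
                }
            )
    return rows
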