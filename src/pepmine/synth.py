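"""Synthetic storage-protein-like sequences with planted bioactive motifs.

The generator emulates a seed-storage protein roster (default lengths
142-542 residues) and splices catalogued peptides into background
sequence at known positions, emitting matched ground truth so every
pipeline stage can be validated exactly:

* **guard policy** (default on): rejection sampling guarantees each
  planted peptide occurs in its protein *exactly* as many times as
  planted — no accidental extra occurrences of any planted peptide;
* **guard release** (when a rule set is supplied): each planted motif is
  flanked by residues the rule set is guaranteed to cut, and the motif
  itself must contain no internal cut site, so the digestion releases it
  intact; the flank pair is found by probing the actual engine.

All randomness flows from one seeded generator; a fixed seed gives
byte-identical FASTA output.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pepmine.cleavage import CleavageRuleSet, digest, find_cleavage_sites
from pepmine.profiles import Occurrence
from pepmine.seqio import STANDARD_AA, ProteinRecord, SequenceInterval

_ALPHABET = "".join(sorted(STANDARD_AA))

# Deterministic preference order for flank residues: cleavage-prone
# residues of common protease models first, so the probe search exits early.
_FLANK_ORDER = "KRFYWLMHAGNQSTDEIVCP"


class PlantingError(ValueError):
    """The planting spec cannot be satisfied (reported, never truncated)."""


@dataclass(frozen=True)
class PlantingSpec:
    """What to generate: roster size, lengths, background, planted motifs."""

    n_proteins: int = 1
    length_range: tuple[int, int] = (142, 542)
    background: Mapping[str, float] | None = None  # None = uniform over 20
    plants: tuple[tuple[str, str, int], ...] = ()  # (peptide, activity, copies)
    guard: bool = True
    release_rules: tuple[CleavageRuleSet, ...] | None = None
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length range {self.length_range}")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        object.__setattr__(self, "plants", tuple(self.plants))
        if self.release_rules is not None:
            object.__setattr__(self, "release_rules", tuple(self.release_rules))
        for pep, act, count in self.plants:
            if not pep or set(pep.upper()) - STANDARD_AA:
                raise ValueError(f"bad planted peptide {pep!r}")
            if not act:
                raise ValueError(f"planted peptide {pep!r}: empty activity")
            if count < 1:
                raise ValueError(f"planted peptide {pep!r}: count must be >= 1")
        if self.background is not None:
            bad = set(self.background) - STANDARD_AA
            if bad:
                raise ValueError(f"background residues {sorted(bad)!r} not standard")
            if not any(w > 0 for w in self.background.values()):
                raise ValueError("background distribution has no positive weight")


@dataclass
class GroundTruthProtein:
    """Planted truth for one generated protein."""

    protein_id: str
    occurrences: list[Occurrence]
    expected_counts: dict[str, int]  # activity -> a
    expected_release: dict[str, dict[str, int]] | None  # activity -> pep -> d


@dataclass
class GroundTruth:
    proteins: dict[str, GroundTruthProtein] = field(default_factory=dict)


def _count_overlapping(sequence: str, peptide: str) -> int:
    count, start = 0, sequence.find(peptide)
    while start != -1:
        count += 1
        start = sequence.find(peptide, start + 1)
    return count


def _find_flanks(
    motif: str, rules: Sequence[CleavageRuleSet], max_probes: int = 8000
) -> tuple[str, str]:
    """Flank strings (left, right) guaranteeing intact release of ``motif``.

    Probes two-residue flank pairs with the engine itself: the bonds at
    both motif boundaries must be cut and no internal motif bond may be,
    regardless of what background ends up beyond the probe padding (the
    assembled protein is re-verified afterwards in any case).
    """
    m = len(motif)
    pairs = [("G", f1) for f1 in _FLANK_ORDER] + [
        (f2, f1) for f2 in _FLANK_ORDER for f1 in _FLANK_ORDER if f2 != "G"
    ]
    probes = 0
    for f2, f1 in pairs:
        for r2, r1 in pairs:  # inner residue r1 varies first, like f1
            probes += 1
            if probes > max_probes:
                raise PlantingError(
                    f"flank search budget exhausted for motif {motif!r}"
                )
            probe = "G" + f2 + f1 + motif + r1 + r2 + "G"
            cuts = find_cleavage_sites(probe, rules)
            left_bond, right_bond = 3, 3 + m
            internal = set(range(4, 3 + m))
            if (
                left_bond in cuts
                and right_bond in cuts
                and not (internal & cuts)
            ):
                return f2 + f1, r1 + r2
    raise PlantingError(
        f"no flank pair releases motif {motif!r} intact under the given rules "
        "(the motif may contain an unavoidable internal cut site)"
    )


def _background(rng: random.Random, spec: PlantingSpec, length: int) -> str:
    if length == 0:
        return ""
    if spec.background is None:
        return "".join(rng.choices(_ALPHABET, k=length))
    residues = sorted(spec.background)
    weights = [spec.background[r] for r in residues]
    return "".join(rng.choices(residues, weights=weights, k=length))


def generate(spec: PlantingSpec) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate the roster and its ground truth.

    Raises :class:`PlantingError` when the spec is infeasible within the
    retry budget (motifs that cannot fit, cannot be guarded, or densities
    too high for rejection sampling).
    """
    rng = random.Random(spec.seed)
    lo, hi = spec.length_range

    plants = [(pep.upper(), act, count) for pep, act, count in spec.plants]
    copies: Counter[str] = Counter()
    activities_of: dict[str, set[str]] = {}
    for pep, act, count in plants:
        copies[pep] += count
        activities_of.setdefault(pep, set()).add(act)

    flanks: dict[str, tuple[str, str]] = {}
    if spec.release_rules is not None and spec.guard:
        for pep in sorted(copies):
            flanks[pep] = _find_flanks(pep, spec.release_rules)

    blocks: list[tuple[str, str, str]] = []  # (peptide, left flank, right flank)
    for pep, act, count in plants:
        left, right = flanks.get(pep, ("", ""))
        blocks.extend([(pep, left, right)] * count)
    required = sum(len(l) + len(p) + len(r) for p, l, r in blocks)
    if required > hi:
        raise PlantingError(
            f"planted blocks need {required} residues but max length is {hi}"
        )

    records: list[ProteinRecord] = []
    truth = GroundTruth()
    for i in range(spec.n_proteins):
        protein_id = f"synth_{i + 1:03d}"
        sequence, intervals = None, []
        for _ in range(spec.max_retries):
            length = rng.randint(max(lo, required), hi)
            order = list(blocks)
            rng.shuffle(order)
            extra = length - required
            cuts = sorted(rng.randint(0, extra) for _ in range(len(order)))
            gaps = (
                [cuts[0], *(b - a for a, b in zip(cuts, cuts[1:])), extra - cuts[-1]]
                if order
                else [extra]
            )
            parts, candidate_intervals, pos = [], [], 0
            for gap, (pep, left, right) in zip(gaps, order):
                bg = _background(rng, spec, gap)
                parts.append(bg + left + pep + right)
                start = pos + gap + len(left) + 1  # 1-based motif start
                candidate_intervals.append(
                    (pep, SequenceInterval(start, start + len(pep) - 1))
                )
                pos += gap + len(left) + len(pep) + len(right)
            parts.append(_background(rng, spec, gaps[-1] if order else length))
            candidate = "".join(parts)
            assert len(candidate) == length

            if spec.guard:
                if any(
                    _count_overlapping(candidate, pep) != copies[pep]
                    for pep in copies
                ):
                    continue
                if spec.release_rules is not None and copies:
                    frag_counts = Counter(
                        frag
                        for frag, _ in digest(candidate, spec.release_rules).fragments
                    )
                    if any(frag_counts[pep] != copies[pep] for pep in copies):
                        continue
            sequence, intervals = candidate, candidate_intervals
            break
        if sequence is None:
            raise PlantingError(
                f"could not assemble protein {protein_id} within "
                f"{spec.max_retries} retries (planting density too high?)"
            )

        occurrences = [
            Occurrence(interval, pep, act)
            for pep, interval in intervals
            for act in sorted(activities_of[pep])
        ]
        occurrences.sort()
        if spec.guard:
            expected_counts = {
                act: sum(copies[p] for p in copies if act in activities_of[p])
                for act in sorted({a for acts in activities_of.values() for a in acts})
            }
        else:
            # Without the guard, accidental occurrences are possible; report
            # truthful counts from a direct scan of the final sequence.
            expected_counts = {}
            for pep in copies:
                hits = _count_overlapping(sequence, pep)
                for act in activities_of[pep]:
                    expected_counts[act] = expected_counts.get(act, 0) + hits
        expected_release = None
        if spec.release_rules is not None and spec.guard:
            expected_release = {
                act: {
                    pep: copies[pep]
                    for pep in sorted(copies)
                    if act in activities_of[pep]
                }
                for act in expected_counts
            }
        records.append(
            ProteinRecord(
                id=protein_id,
                description=(
                    f"synthetic storage-protein-like sequence seed={spec.seed} "
                    f"length={len(sequence)} planted={len(intervals)}"
                ),
                sequence=sequence,
            )
        )
        truth.proteins[protein_id] = GroundTruthProtein(
            protein_id=protein_id,
            occurrences=occurrences,
            expected_counts=expected_counts,
            expected_release=expected_release,
        )
    return records, truth


def occurrence_rows(truth: GroundTruth) -> list[dict]:
    """Ground-truth occurrence table (one row per planted occurrence)."""
    rows = []
    for protein_id in sorted(truth.proteins):
        for occ in truth.proteins[protein_id].occurrences:
            rows.append(
                {
                    "protein_id": protein_id,
                    "peptide": occ.peptide,
                    "activity": occ.activity,
                    "start": occ.interval.start,
                    "end": occ.interval.end,
                }
            )
    return rows


def expected_count_rows(truth: GroundTruth) -> list[dict]:
    """Ground-truth per-activity occurrence counts."""
    rows = []
    for protein_id in sorted(truth.proteins):
        for act, count in sorted(truth.proteins[protein_id].expected_counts.items()):
            rows.append({"protein_id": protein_id, "activity": act, "a": count})
    return rows


def expected_release_rows(truth: GroundTruth) -> list[dict]:
    """Ground-truth released-peptide counts under the guard rule set."""
    rows = []
    for protein_id in sorted(truth.proteins):
        release = truth.proteins[protein_id].expected_release
        if release is None:
            continue
        for act in sorted(release):
            for pep, count in sorted(release[act].items()):
                rows.append(
                    {
                        "protein_id": protein_id,
                        "activity": act,
                        "peptide": pep,
                        "d": count,
                    }
                )
    return rows
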