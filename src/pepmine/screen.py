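"""Virtual screening of released peptides.

The cascade: collect all distinct released fragments of length k, label
novelty against the dictionary, join externally computed bioactivity
(ranker) and toxicity scores, apply a transparent solubility heuristic,
simulate gastrointestinal digestion of each candidate, and classify its
fate:

* ``intact``            — survives as itself,
* ``partly_hydrolyzed`` — some multi-residue fragment remains,
* ``fully_degraded``    — only free amino acids remain.

Ranker and toxicity predictors are trained external models and are
deliberately **not** reimplemented: their outputs enter through a score
table, and candidates absent from it stay "unknown". The solubility rule
is a labelled stand-in (hydrophobic-majority, no charged residue =>
poor), not a reimplementation of any proprietary server; it is known to
diverge on histidine-containing peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from pepmine.cleavage import CleavageRuleSet, digest
from pepmine.dictionary import BioactiveDictionary
from pepmine.release import ReleaseProfile
from pepmine.seqio import STANDARD_AA, SequenceInterval

HYDROPHOBIC = frozenset("AVLIMFWYCP")
CHARGED = frozenset("DEKRH")

FATE_INTACT = "intact"
FATE_PARTLY = "partly_hydrolyzed"
FATE_DEGRADED = "fully_degraded"

_TOXICITY_ALIASES = {
    "toxin": "toxic",
    "toxic": "toxic",
    "non-toxin": "non-toxic",
    "nontoxin": "non-toxic",
    "non-toxic": "non-toxic",
    "nontoxic": "non-toxic",
}


def solubility_heuristic(peptide: str) -> str:
    """Classify water solubility as ``poor`` or ``good``.

    ``poor`` iff hydrophobic residues (AVLIMFWYCP) make up more than half
    of the peptide *and* it carries no charged residue (DEKRH). A simple,
    documented stand-in for server-based predictors.
    """
    peptide = peptide.upper()
    if not peptide or set(peptide) - STANDARD_AA:
        raise ValueError(f"invalid peptide {peptide!r}")
    hydrophobic = sum(res in HYDROPHOBIC for res in peptide)
    has_charge = any(res in CHARGED for res in peptide)
    if hydrophobic * 2 > len(peptide) and not has_charge:
        return "poor"
    return "good"


@dataclass(frozen=True)
class GIResult:
    """Outcome of simulated gastrointestinal digestion of one peptide."""

    peptide: str
    fragments: tuple[str, ...]
    fate: str
    secondary_products: tuple[str, ...]  # multi-residue products of a partial cut

    @property
    def pattern(self) -> str:
        """Fragment pattern in hyphen notation, e.g. ``H-PF``."""
        return "-".join(self.fragments)


def classify_fate(peptide: str, fragments: Sequence[str]) -> str:
    if tuple(fragments) == (peptide,):
        return FATE_INTACT
    if all(len(f) == 1 for f in fragments):
        return FATE_DEGRADED
    return FATE_PARTLY


def gi_stability(
    peptide: str, gi_rules: Sequence[CleavageRuleSet]
) -> GIResult:
    """Concurrent GI digestion of a single peptide.

    Secondary products are the fragments of length >= 2 left by a
    non-intact digestion (the "new generation" peptides).
    """
    result = digest(peptide.upper(), gi_rules, mode="concurrent")
    fragments = tuple(frag for frag, _ in result.fragments)
    fate = classify_fate(peptide.upper(), fragments)
    secondary = (
        tuple(f for f in fragments if len(f) >= 2) if fate != FATE_INTACT else ()
    )
    return GIResult(peptide.upper(), fragments, fate, secondary)


@dataclass(frozen=True)
class CandidateSource:
    """Where a candidate fragment came from."""

    protein_id: str
    enzyme_ids: tuple[str, ...]
    location: SequenceInterval


@dataclass(frozen=True)
class Candidate:
    peptide: str
    sources: tuple[CandidateSource, ...]
    known_activities: frozenset[str]

    @property
    def novel(self) -> bool:
        return not self.known_activities


def select_candidates(
    release_profiles: Iterable[ReleaseProfile],
    k: int,
    dictionary: BioactiveDictionary,
) -> list[Candidate]:
    """All distinct released fragments of length exactly ``k``.

    Each candidate carries every source location across all given runs
    and its novelty labels from the dictionary.
    """
    if k < 2:
        raise ValueError("candidate length filter k must be >= 2")
    sources: dict[str, list[CandidateSource]] = {}
    for rp in release_profiles:
        for fragment, interval in rp.digestion.fragments:
            if len(fragment) == k:
                sources.setdefault(fragment, []).append(
                    CandidateSource(rp.protein_id, rp.enzyme_ids, interval)
                )
    return [
        Candidate(
            peptide=pep,
            sources=tuple(srcs),
            known_activities=dictionary.activities_of(pep),
        )
        for pep, srcs in sorted(sources.items())
    ]


def load_score_table(table) -> dict[str, tuple[float | None, str]]:
    """Parse a score table into ``peptide -> (ranker_score, toxicity_flag)``.

    Accepts a path or a DataFrame with columns ``peptide`` and any of
    ``ranker_score`` / ``toxicity``. Scores must lie in [0, 1]; duplicate
    rows must agree. Missing values yield ``(None, "unknown")``.
    """
    if table is None:
        return {}
    if isinstance(table, (str, Path)):
        frame = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    else:
        frame = table.astype(str)
    if "peptide" not in frame.columns:
        raise ValueError("score table requires a 'peptide' column")
    out: dict[str, tuple[float | None, str]] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        pep = str(row.peptide).strip().upper()
        if not pep:
            raise ValueError(f"score table line {i}: empty peptide")
        raw_score = str(getattr(row, "ranker_score", "")).strip()
        score: float | None = None
        if raw_score:
            try:
                score = float(raw_score)
            except ValueError as exc:
                raise ValueError(
                    f"score table line {i}: bad ranker_score {raw_score!r}"
                ) from exc
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"score table line {i}: ranker_score {score} outside [0, 1]"
                )
        raw_tox = str(getattr(row, "toxicity", "")).strip().lower()
        flag = _TOXICITY_ALIASES.get(raw_tox, "unknown") if raw_tox else "unknown"
        if pep in out and out[pep] != (score, flag):
            raise ValueError(f"score table line {i}: conflicting duplicate for {pep}")
        out[pep] = (score, flag)
    return out


def attach_scores(
    candidates: Sequence[Candidate], score_table
) -> dict[str, tuple[float | None, str]]:
    """Scores for each candidate peptide; absent peptides map to unknown."""
    scores = load_score_table(score_table)
    return {
        c.peptide: scores.get(c.peptide, (None, "unknown")) for c in candidates
    }


@dataclass(frozen=True)
class CandidateReport:
    """One screened peptide with its full fate record."""

    peptide: str
    sources: tuple[CandidateSource, ...]
    known_activities: frozenset[str]
    ranker_score: float | None
    toxicity_flag: str
    solubility_class: str
    gi_fragments: tuple[str, ...]
    fate: str
    secondary_products: tuple[str, ...]

    @property
    def novel(self) -> bool:
        return not self.known_activities


def screen(
    release_profiles: Iterable[ReleaseProfile],
    dictionary: BioactiveDictionary,
    gi_rules: Sequence[CleavageRuleSet],
    k: int = 3,
    score_table=None,
    novel_only: bool = False,
    secondary_score_threshold: float = 0.5,
) -> list[CandidateReport]:
    """Run the full screening cascade over released length-k fragments.

    Reports are sorted by ranker score descending, unknown scores last,
    ties broken lexicographically by peptide. ``secondary_products`` in a
    report keeps only GI sub-fragments that are dictionary entries or
    reach ``secondary_score_threshold`` in the score table — the products
    worth following up, as opposed to every multi-residue fragment (which
    :func:`gi_stability` reports).
    """
    candidates = select_candidates(release_profiles, k, dictionary)
    if novel_only:
        candidates = [c for c in candidates if c.novel]
    scores = load_score_table(score_table)
    reports = []
    for cand in candidates:
        score, flag = scores.get(cand.peptide, (None, "unknown"))
        gi = gi_stability(cand.peptide, gi_rules)
        interesting = tuple(
            frag
            for frag in gi.secondary_products
            if dictionary.activities_of(frag)
            or (
                scores.get(frag, (None, ""))[0] is not None
                and scores[frag][0] >= secondary_score_threshold
            )
        )
        reports.append(
            CandidateReport(
                peptide=cand.peptide,
                sources=cand.sources,
                known_activities=cand.known_activities,
                ranker_score=score,
                toxicity_flag=flag,
                solubility_class=solubility_heuristic(cand.peptide),
                gi_fragments=gi.fragments,
                fate=gi.fate,
                secondary_products=interesting,
            )
        )
    reports.sort(
        key=lambda r: (
            r.ranker_score is None,
            -(r.ranker_score or 0.0),
            r.peptide,
        )
    )
    return reports


def report_rows(reports: Sequence[CandidateReport]) -> list[dict]:
    """Flatten screening reports for the TSV/JSON exports."""
    rows = []
    for rep in reports:
        rows.append(
            {
                "peptide": rep.peptide,
                "sources": ";".join(
                    f"{s.protein_id}@{s.location}({'+'.join(s.enzyme_ids)})"
                    for s in rep.sources
                ),
                "known_activities": ";".join(sorted(rep.known_activities)),
                "novel": "yes" if rep.novel else "no",
                "ranker_score": "" if rep.ranker_score is None else f"{rep.ranker_score:.4f}",
                "toxicity": rep.toxicity_flag,
                "solubility": rep.solubility_class,
                "gi_pattern": "-".join(rep.gi_fragments),
                "fate": rep.fate,
                "secondary_products": ";".join(rep.secondary_products),
            }
        )
    return rows
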