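"""Independent brute-force oracles and random-instance generators.

The oracles deliberately re-derive everything from first principles
(literal per-bond, per-pattern checks; naive substring scans) so they
stay independent of the library's aggregate implementations.
"""

from __future__ import annotations

import random

from pepmine.cleavage import CleavageRuleSet, SiteSpec
from pepmine.dictionary import BioactiveDictionary, PeptideEntry
from pepmine.seqio import STANDARD_AA

ALPHABET = "".join(sorted(STANDARD_AA))

# bond b joins 1-based residues b and b+1; 0-based context indices:
_CONTEXT = {"p2": -3, "p1": -2, "p1_prime": -1, "p2_prime": 0}


def brute_site_matches(sequence: str, bond: int, site: SiteSpec) -> bool:
    """Literal subsite check for one pattern at one bond."""
    for pos, shift in _CONTEXT.items():
        allowed = getattr(site, pos)
        if allowed is None:
            continue
        idx = bond + 1 + shift
        if not (0 <= idx < len(sequence)) or sequence[idx] not in allowed:
            return False
    for pos, residues in site.blocked:
        idx = bond + 1 + _CONTEXT[pos]
        if 0 <= idx < len(sequence) and sequence[idx] in residues:
            return False
    return True


def brute_cleavage_sites(sequence: str, rulesets) -> set[int]:
    """Every bond tested against every pattern of every enzyme."""
    cuts = set()
    for bond in range(1, len(sequence)):
        for ruleset in rulesets:
            for site in ruleset.sites:
                if brute_site_matches(sequence, bond, site):
                    cuts.add(bond)
    return cuts


def brute_occurrences(sequence: str, peptides) -> list[tuple[str, int]]:
    """Naive O(N*m) scan: (peptide, 1-based start) for every window match."""
    hits = []
    for start in range(len(sequence)):
        for pep in peptides:
            if sequence[start : start + len(pep)] == pep:
                hits.append((pep, start + 1))
    return hits


def random_sequence(rng: random.Random, max_len: int = 500, min_len: int = 2) -> str:
    return "".join(rng.choices(ALPHABET, k=rng.randint(min_len, max_len)))


def random_residue_set(rng: random.Random, k_max: int = 6) -> frozenset[str]:
    return frozenset(rng.sample(ALPHABET, rng.randint(1, k_max)))


def random_site(rng: random.Random) -> SiteSpec:
    kwargs = {"p1": random_residue_set(rng)}
    for pos in ("p2", "p1_prime", "p2_prime"):
        if rng.random() < 0.4:
            kwargs[pos] = random_residue_set(rng)
    blocked = []
    if rng.random() < 0.3:
        blocked.append(
            (rng.choice(["p2", "p1", "p1_prime", "p2_prime"]), random_residue_set(rng, 3))
        )
    return SiteSpec(blocked=tuple(blocked), **kwargs)


def random_ruleset(rng: random.Random, enzyme_id: str = "rand") -> CleavageRuleSet:
    return CleavageRuleSet(
        enzyme_id=enzyme_id,
        ec_number="0.0.0.0",
        sites=tuple(random_site(rng) for _ in range(rng.randint(1, 3))),
    )


def random_dictionary(
    rng: random.Random, n_entries: int = 40, activities=("act-A", "act-B", "act-C")
) -> BioactiveDictionary:
    entries = []
    seen = set()
    while len(entries) < n_entries:
        pep = "".join(rng.choices(ALPHABET, k=rng.randint(2, 5)))
        act = rng.choice(activities)
        if (pep, act) in seen:
            continue
        seen.add((pep, act))
        entries.append(PeptideEntry(pep, act))
    return BioactiveDictionary(entries)
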