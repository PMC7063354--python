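"""Protease specificity modelling and in-silico digestion.

A protease is a set of *site patterns* over the Schechter-Berger subsites
P2, P1, P1', P2' around a peptide bond (P1 immediately N-terminal to the
scissile bond, P1' immediately C-terminal). A bond is cut when at least
one pattern of at least one active enzyme matches:

* every non-wildcard subsite holds a residue from the pattern's allowed
  set (a subsite falling outside the sequence fails any such requirement);
* no *blocked* clause is satisfied (e.g. trypsin does not cut K/R-|-P).

Digestion is idealized and complete: every matching bond is cut, with no
kinetics or missed-cleavage probabilities. The degree of hydrolysis is
``DH = 100 * cut_bonds / (N - 1)``.

Bond indexing: bond ``b`` joins residues ``b`` and ``b+1`` (1-based),
so a protein of N residues has bonds ``1..N-1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

from pepmine.display import format4
from pepmine.seqio import STANDARD_AA, ProteinRecord, SequenceInterval

POSITIONS = ("p2", "p1", "p1_prime", "p2_prime")

# Offset of each subsite from the bond index b, as a 0-based sequence index:
# P1 = residue b = seq[b-1]; P1' = residue b+1 = seq[b].
_OFFSET = {"p2": -2, "p1": -1, "p1_prime": 0, "p2_prime": 1}

WILDCARD = "*"


def _residue_at(sequence: str, bond: int, position: str) -> str | None:
    idx = bond + _OFFSET[position]
    if 0 <= idx < len(sequence):
        return sequence[idx]
    return None


def _parse_residue_set(value: str, where: str) -> frozenset[str]:
    residues = frozenset(str(value).strip().upper())
    bad = residues - STANDARD_AA
    if bad:
        raise ValueError(f"{where}: residue letters {sorted(bad)!r} are not standard")
    if not residues:
        raise ValueError(f"{where}: empty residue set")
    return residues


@dataclass(frozen=True)
class SiteSpec:
    """One cleavage-site pattern over subsites P2..P2'.

    ``None`` means wildcard (no constraint). ``p1`` is mandatory in the
    config; ``"*"`` there expands to the full 20-letter set, so a
    non-standard residue at P1 never matches any pattern.
    ``blocked`` lists (subsite, residue set) exceptions that veto a match.
    """

    p1: frozenset[str]
    p2: frozenset[str] | None = None
    p1_prime: frozenset[str] | None = None
    p2_prime: frozenset[str] | None = None
    blocked: tuple[tuple[str, frozenset[str]], ...] = ()

    def __post_init__(self) -> None:
        if not self.p1:
            raise ValueError("site pattern requires a non-empty P1 set")
        for pos_name, allowed in self._constraints():
            bad = allowed - STANDARD_AA
            if bad:
                raise ValueError(f"{pos_name}: non-standard residues {sorted(bad)!r}")
        for pos_name, residues in self.blocked:
            if pos_name not in POSITIONS:
                raise ValueError(f"unknown blocked subsite {pos_name!r}")
            bad = residues - STANDARD_AA
            if bad:
                raise ValueError(
                    f"blocked {pos_name}: non-standard residues {sorted(bad)!r}"
                )

    def _constraints(self) -> list[tuple[str, frozenset[str]]]:
        out = []
        for pos in POSITIONS:
            allowed = getattr(self, pos)
            if allowed is not None:
                out.append((pos, allowed))
        return out

    def matches(self, sequence: str, bond: int) -> bool:
        """Does this pattern match bond ``bond`` (1..N-1) of ``sequence``?"""
        for pos, allowed in self._constraints():
            residue = _residue_at(sequence, bond, pos)
            if residue is None or residue not in allowed:
                return False
        for pos, residues in self.blocked:
            residue = _residue_at(sequence, bond, pos)
            if residue is not None and residue in residues:
                return False
        return True


@dataclass(frozen=True)
class CleavageRuleSet:
    """A protease's specificity: id, EC number, and its site patterns."""

    enzyme_id: str
    ec_number: str
    sites: tuple[SiteSpec, ...]

    def __post_init__(self) -> None:
        if not self.enzyme_id:
            raise ValueError("rule set requires an enzyme_id")
        if not self.sites:
            raise ValueError(f"enzyme {self.enzyme_id!r}: empty site list")


Rules = Union[CleavageRuleSet, Sequence[CleavageRuleSet]]


def _as_rule_list(rules: Rules) -> list[CleavageRuleSet]:
    if isinstance(rules, CleavageRuleSet):
        return [rules]
    return list(rules)


def _site_from_mapping(raw: dict, where: str) -> SiteSpec:
    unknown = set(raw) - set(POSITIONS) - {"blocked"}
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    if "p1" not in raw:
        raise ValueError(f"{where}: site lacks required subsite p1")

    def parse_pos(key: str) -> frozenset[str] | None:
        if key not in raw or raw[key] is None:
            return None
        value = str(raw[key]).strip()
        if value == WILDCARD:
            # P1 is mandatory but may be unrestricted; other subsites use None.
            return frozenset(STANDARD_AA) if key == "p1" else None
        return _parse_residue_set(value, f"{where}.{key}")

    p1 = parse_pos("p1")
    assert p1 is not None
    blocked = []
    for j, clause in enumerate(raw.get("blocked") or []):
        pos = clause.get("position")
        if pos not in POSITIONS:
            raise ValueError(f"{where}.blocked[{j}]: bad subsite {pos!r}")
        blocked.append(
            (pos, _parse_residue_set(clause.get("residues", ""), f"{where}.blocked[{j}]"))
        )
    return SiteSpec(
        p1=p1,
        p2=parse_pos("p2"),
        p1_prime=parse_pos("p1_prime"),
        p2_prime=parse_pos("p2_prime"),
        blocked=tuple(blocked),
    )


def loads_rules(text: str) -> list[CleavageRuleSet]:
    """Parse a rule config from YAML text (see the bundled configs)."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "enzymes" not in doc:
        raise ValueError("rule config must be a mapping with an 'enzymes' list")
    rulesets = []
    seen_ids = set()
    for i, raw in enumerate(doc["enzymes"] or []):
        where = f"enzymes[{i}]"
        enzyme_id = str(raw.get("enzyme_id", "")).strip()
        if not enzyme_id:
            raise ValueError(f"{where}: missing enzyme_id")
        if enzyme_id in seen_ids:
            raise ValueError(f"{where}: duplicate enzyme_id {enzyme_id!r}")
        seen_ids.add(enzyme_id)
        sites = tuple(
            _site_from_mapping(site, f"{where}.sites[{j}]")
            for j, site in enumerate(raw.get("sites") or [])
        )
        rulesets.append(
            CleavageRuleSet(
                enzyme_id=enzyme_id,
                ec_number=str(raw.get("ec_number", "")).strip(),
                sites=sites,
            )
        )
    if not rulesets:
        raise ValueError("rule config defines no enzymes")
    return rulesets


def load_rules(path) -> list[CleavageRuleSet]:
    """Load cleavage rule sets from a YAML config file."""
    return loads_rules(Path(path).read_text(encoding="utf-8"))


def _set_to_str(residues: frozenset[str] | None) -> str | None:
    if residues is None:
        return None
    if residues == STANDARD_AA:
        return WILDCARD
    return "".join(sorted(residues))


def serialize_rules(rulesets: Sequence[CleavageRuleSet]) -> str:
    """Serialize rule sets back to YAML; load(serialize(x)) == x."""
    enzymes = []
    for rs in rulesets:
        sites = []
        for site in rs.sites:
            raw: dict = {"p1": _set_to_str(site.p1)}
            for pos in ("p2", "p1_prime", "p2_prime"):
                value = _set_to_str(getattr(site, pos))
                if value is not None:
                    raw[pos] = value
            if site.blocked:
                raw["blocked"] = [
                    {"position": pos, "residues": "".join(sorted(residues))}
                    for pos, residues in site.blocked
                ]
            sites.append(raw)
        enzymes.append(
            {"enzyme_id": rs.enzyme_id, "ec_number": rs.ec_number, "sites": sites}
        )
    return yaml.safe_dump({"enzymes": enzymes}, sort_keys=False)


def _bundled(name: str) -> list[CleavageRuleSet]:
    from importlib import resources

    ref = resources.files("pepmine.data").joinpath(name)
    return loads_rules(ref.read_text(encoding="utf-8"))


def bundled_gi_rules() -> list[CleavageRuleSet]:
    """Gastrointestinal rule set: pepsin (pH > 2), trypsin, chymotrypsin A.

    Calibrated against the published worked examples of simulated GI
    digestion of tripeptides; shipped as editable config, not an
    authoritative reconstruction of any external tool's internals.
    """
    return _bundled("gi_rules.yaml")


def bundled_plant_rules() -> list[CleavageRuleSet]:
    """Best-effort papain / ficin / stem bromelain site models.

    Keil-style provisional defaults; the true encodings used by online
    digestion tools are unpublished, so these are explicitly editable
    approximations.
    """
    return _bundled("plant_rules.yaml")


def find_cleavage_sites(protein: ProteinRecord | str, rules: Rules) -> frozenset[int]:
    """All bonds cut by at least one site pattern of at least one enzyme."""
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    rule_list = _as_rule_list(rules)
    cuts = set()
    for bond in range(1, len(sequence)):
        for ruleset in rule_list:
            if any(site.matches(sequence, bond) for site in ruleset.sites):
                cuts.add(bond)
                break
    return frozenset(cuts)


@dataclass(frozen=True)
class DigestionResult:
    """Outcome of one protein x enzyme-set digestion."""

    protein_id: str
    enzyme_ids: tuple[str, ...]
    n: int
    cleaved_bonds: tuple[int, ...]
    fragments: tuple[tuple[str, SequenceInterval], ...]

    @property
    def dh(self) -> Fraction:
        """Degree of hydrolysis as an exact percentage in [0, 100]."""
        if self.n <= 1:
            return Fraction(0)
        return Fraction(100 * len(self.cleaved_bonds), self.n - 1)

    @property
    def dh_display(self) -> str:
        """DH formatted at 4 decimal places."""
        return format4(self.dh)

    @property
    def sequence(self) -> str:
        return "".join(frag for frag, _ in self.fragments)


def _fragments_from_cuts(
    sequence: str, cuts: Iterable[int]
) -> tuple[tuple[str, SequenceInterval], ...]:
    bounds = [0, *sorted(cuts), len(sequence)]
    frags = []
    for left, right in zip(bounds, bounds[1:]):
        frags.append((sequence[left:right], SequenceInterval(left + 1, right)))
    return tuple(frags)


def digest(
    protein: ProteinRecord | str,
    rules: Rules,
    mode: str = "concurrent",
    protein_id: str | None = None,
) -> DigestionResult:
    """Digest a protein with one or more enzymes.

    ``concurrent`` (default) takes the union of all enzymes' sites in a
    single pass — the model of a one-pot multi-enzyme digestion.
    ``sequential`` applies enzymes in the order given, each acting on the
    fragments left by the previous one; for patterns whose context windows
    do not cross earlier cut sites the two modes coincide.
    """
    if isinstance(protein, ProteinRecord):
        sequence, pid = protein.sequence, protein.id
    else:
        sequence, pid = protein, (protein_id or "peptide")
    rule_list = _as_rule_list(rules)
    if mode == "concurrent":
        cuts = set(find_cleavage_sites(sequence, rule_list))
    elif mode == "sequential":
        cuts = set()
        for ruleset in rule_list:
            bounds = [0, *sorted(cuts), len(sequence)]
            for left, right in zip(bounds, bounds[1:]):
                sub = sequence[left:right]
                for bond in find_cleavage_sites(sub, [ruleset]):
                    cuts.add(left + bond)
    else:
        raise ValueError(f"unknown digestion mode {mode!r}")
    return DigestionResult(
        protein_id=pid,
        enzyme_ids=tuple(rs.enzyme_id for rs in rule_list),
        n=len(sequence),
        cleaved_bonds=tuple(sorted(cuts)),
        fragments=_fragments_from_cuts(sequence, cuts),
    )


def degree_of_hydrolysis(result: DigestionResult) -> Fraction:
    """DH of a digestion as an exact percentage (0 for a single residue)."""
    return result.dh
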