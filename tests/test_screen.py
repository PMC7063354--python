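import random

import pandas as pd
import pytest

from oracle_utils import ALPHABET
from pepmine.cleavage import digest
from pepmine.profiles import profile
from pepmine.release import release_profile
from pepmine.screen import (
    attach_scores,
    classify_fate,
    gi_stability,
    load_score_table,
    screen,
    select_candidates,
    solubility_heuristic,
)
from pepmine.seqio import ProteinRecord
from pepmine.synth import PlantingSpec, generate


class TestSolubilityHeuristic:
    @pytest.mark.parametrize(
        "peptide,expected",
        [
            ("MAF", "poor"),  # all hydrophobic, no charge
            ("NMF", "poor"),
            ("HPF", "good"),  # histidine counts as charged: documented divergence
            ("DKE", "good"),  # all charged
            ("GSGS", "good"),  # hydrophilic majority
        ],
    )
    def test_classification(self, peptide, expected):
        assert solubility_heuristic(peptide) == expected

    def test_invalid_peptide_rejected(self):
        with pytest.raises(ValueError):
            solubility_heuristic("MA1")


class TestGIStability:
    @pytest.mark.parametrize(
        "peptide,pattern,fate,secondary",
        [
            ("MAF", "M-A-F", "fully_degraded", ()),
            ("NMF", "N-M-F", "fully_degraded", ()),
            ("HPF", "H-PF", "partly_hydrolyzed", ("PF",)),
            ("MCG", "M-CG", "partly_hydrolyzed", ("CG",)),
        ],
    )
    def test_tripeptide_fates(self, gi_rules, peptide, pattern, fate, secondary):
        result = gi_stability(peptide, gi_rules)
        assert result.pattern == pattern
        assert result.fate == fate
        assert result.secondary_products == secondary

    def test_single_residue_intact(self, gi_rules):
        assert gi_stability("W", gi_rules).fate == "intact"

    def test_uncleavable_peptide_intact(self, gi_rules):
        result = gi_stability("GG", gi_rules)
        assert result.fate == "intact"
        assert result.fragments == ("GG",)
        assert result.secondary_products == ()

    def test_fate_follows_from_fragments(self, gi_rules):
        rng = random.Random(13)
        for _ in range(200):
            pep = "".join(rng.choices(ALPHABET, k=rng.randint(1, 8)))
            result = gi_stability(pep, gi_rules)
            assert "".join(result.fragments) == pep
            assert result.fate == classify_fate(pep, result.fragments)
            assert set(result.secondary_products) <= set(result.fragments)


from pepmine.cleavage import loads_rules

# a releasing protease cutting on either side of lysine: frees K-flanked
# motifs without touching their internal bonds
_FLANK_CUTTER = loads_rules(
    "enzymes:\n- enzyme_id: flank_cutter\n  ec_number: 0.0.0.0\n"
    "  sites:\n  - p1: K\n  - p1: '*'\n    p1_prime: K\n"
)


def _release_profiles_for(sequences, rules, dictionary):
    profiles = []
    for i, seq in enumerate(sequences):
        protein = ProteinRecord(f"p{i}", "", seq)
        prof = profile(protein, dictionary)
        profiles.append(release_profile(protein, digest(protein, rules), dictionary, prof))
    return profiles


class TestSelectCandidates:
    def test_length_filter(self, demo_dict):
        # flank-cutter digest of KMAFKGG yields K / MAF / K / GG
        rps = _release_profiles_for(["KMAFKGG"], _FLANK_CUTTER, demo_dict)
        cands = select_candidates(rps, 3, demo_dict)
        assert [c.peptide for c in cands] == ["MAF"]
        assert cands[0].novel

    def test_known_peptide_flagged(self, demo_dict):
        rps = _release_profiles_for(["KWCYKGG"], _FLANK_CUTTER, demo_dict)
        cands = select_candidates(rps, 3, demo_dict)
        wcy = [c for c in cands if c.peptide == "WCY"]
        assert wcy and wcy[0].known_activities == {"ACE inhibitor"}

    def test_no_fragments_of_length_k(self, demo_dict):
        rps = _release_profiles_for(["GG"], _FLANK_CUTTER, demo_dict)
        assert select_candidates(rps, 3, demo_dict) == []

    def test_k_below_2_rejected(self, demo_dict):
        with pytest.raises(ValueError):
            select_candidates([], 1, demo_dict)


class TestScoreImport:
    def test_scores_joined_by_sequence(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("peptide\tranker_score\ttoxicity\nMAF\t0.9676\tNon-Toxin\n")
        scores = load_score_table(path)
        assert scores["MAF"] == (0.9676, "non-toxic")

    def test_missing_candidate_unknown(self, tmp_path, demo_dict):
        path = tmp_path / "s.tsv"
        path.write_text("peptide\tranker_score\ttoxicity\nMAF\t0.9676\tNon-Toxin\n")
        rps = _release_profiles_for(["KMAFKGGKNMFK"], _FLANK_CUTTER, demo_dict)
        cands = select_candidates(rps, 3, demo_dict)
        joined = attach_scores(cands, path)
        assert joined["MAF"] == (0.9676, "non-toxic")
        assert joined["NMF"] == (None, "unknown")

    def test_out_of_range_score_rejected(self):
        frame = pd.DataFrame([{"peptide": "MAF", "ranker_score": "1.2"}])
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            load_score_table(frame)

    def test_conflicting_duplicates_rejected(self):
        frame = pd.DataFrame(
            [
                {"peptide": "MAF", "ranker_score": "0.9"},
                {"peptide": "MAF", "ranker_score": "0.8"},
            ]
        )
        with pytest.raises(ValueError, match="conflicting"):
            load_score_table(frame)


class TestScreenCascade:
    @pytest.fixture()
    def planted_profiles(self, demo_dict):
        releaser = _FLANK_CUTTER
        spec = PlantingSpec(
            n_proteins=1,
            length_range=(200, 260),
            plants=(
                ("MAF", "candidate", 1),
                ("NMF", "candidate", 1),
                ("HPF", "candidate", 1),
                ("MCG", "candidate", 1),
                ("WCY", "candidate", 1),
            ),
            guard=True,
            release_rules=tuple(releaser),
            seed=2026,
        )
        records, _ = generate(spec)
        return _release_profiles_for([records[0].sequence], releaser, demo_dict)

    def test_top_novel_candidates_ranked_by_score(
        self, planted_profiles, demo_dict, gi_rules, tmp_path
    ):
        scores = tmp_path / "s.tsv"
        scores.write_text(
            "peptide\tranker_score\ttoxicity\n"
            "MAF\t0.9676\tNon-Toxin\nNMF\t0.9624\tNon-Toxin\n"
            "HPF\t0.9502\tNon-Toxin\nMCG\t0.9502\tNon-Toxin\n"
            "WCY\t0.9816\t\nCG\t0.9319\t\n"
        )
        reports = screen(
            planted_profiles, demo_dict, gi_rules, k=3, score_table=scores,
            novel_only=True,
        )
        assert [r.peptide for r in reports[:4]] == ["MAF", "NMF", "HPF", "MCG"]
        # the 0.9502 tie breaks lexicographically
        assert reports[2].ranker_score == reports[3].ranker_score == 0.9502
        by_pep = {r.peptide: r for r in reports}
        assert by_pep["MCG"].secondary_products == ("CG",)  # passes score threshold
        assert by_pep["HPF"].secondary_products == ("PF",)  # dictionary entry
        assert all(r.toxicity_flag == "non-toxic" for r in reports[:4])
        assert "WCY" not in by_pep  # catalogued peptide excluded from novel list

    def test_without_scores_unranked_candidates_sort_last(
        self, planted_profiles, demo_dict, gi_rules, tmp_path
    ):
        scores = tmp_path / "s.tsv"
        scores.write_text("peptide\tranker_score\ttoxicity\nHPF\t0.9502\tNon-Toxin\n")
        reports = screen(
            planted_profiles, demo_dict, gi_rules, k=3, score_table=scores
        )
        assert reports[0].peptide == "HPF"
        unscored = [r for r in reports if r.ranker_score is None]
        assert reports[-len(unscored):] == sorted(unscored, key=lambda r: r.peptide)
        # without a score for CG, MCG's secondary product needs a dictionary hit
        by_pep = {r.peptide: r for r in reports}
        assert by_pep["MCG"].secondary_products == ()

    def test_empty_release_profiles_empty_report(self, demo_dict, gi_rules):
        assert screen([], demo_dict, gi_rules, k=3) == []
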