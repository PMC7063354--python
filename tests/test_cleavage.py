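import random
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from oracle_utils import (
    ALPHABET,
    brute_cleavage_sites,
    random_ruleset,
    random_sequence,
)
from pepmine.cleavage import (
    CleavageRuleSet,
    SiteSpec,
    degree_of_hydrolysis,
    digest,
    find_cleavage_sites,
    load_rules,
    loads_rules,
    serialize_rules,
)
from pepmine.seqio import ProteinRecord


class TestRuleConfig:
    def test_bundled_gi_enzyme_roster(self, gi_rules):
        assert [rs.enzyme_id for rs in gi_rules] == [
            "pepsin_ph_gt2",
            "trypsin",
            "chymotrypsin_a",
        ]

    def test_bundled_plant_enzyme_roster(self, plant_rules):
        assert [rs.enzyme_id for rs in plant_rules] == [
            "papain",
            "ficin",
            "stem_bromelain",
        ]

    def test_site_lacking_p1_rejected(self):
        with pytest.raises(ValueError, match="p1"):
            loads_rules(
                "enzymes:\n- enzyme_id: e\n  ec_number: x\n  sites:\n  - p2: KR\n"
            )

    def test_duplicate_enzyme_id_rejected(self):
        text = (
            "enzymes:\n"
            "- {enzyme_id: e, ec_number: x, sites: [{p1: K}]}\n"
            "- {enzyme_id: e, ec_number: x, sites: [{p1: R}]}\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            loads_rules(text)

    def test_bad_residue_letter_rejected(self):
        with pytest.raises(ValueError, match="not standard"):
            loads_rules("enzymes:\n- {enzyme_id: e, ec_number: x, sites: [{p1: KJ}]}\n")

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValueError):
            loads_rules("enzymes:\n- {enzyme_id: e, ec_number: x, sites: []}\n")

    @pytest.mark.parametrize("bundle", ["gi_rules", "plant_rules"])
    def test_serialize_roundtrip_identity(self, bundle, request):
        rules = request.getfixturevalue(bundle)
        assert loads_rules(serialize_rules(rules)) == list(rules)

    def test_load_from_file(self, tmp_path, gi_rules):
        path = tmp_path / "r.yaml"
        path.write_text(serialize_rules(gi_rules))
        assert load_rules(path) == list(gi_rules)


class TestFindCleavageSites:
    def test_tripeptide_fully_cut(self, gi_rules):
        assert find_cleavage_sites("MAF", gi_rules) == {1, 2}

    def test_tripeptide_single_cut(self, gi_rules):
        assert find_cleavage_sites("MCG", gi_rules) == {1}

    def test_no_enzymes_no_cuts(self):
        assert find_cleavage_sites("MAFKRW", []) == frozenset()

    def test_proline_block_of_trypsin(self, gi_rules):
        trypsin = [rs for rs in gi_rules if rs.enzyme_id == "trypsin"]
        assert find_cleavage_sites("AKAP", trypsin) == {2}
        assert find_cleavage_sites("AKPA", trypsin) == frozenset()

    def test_terminal_subsites_fail_closed(self):
        # a pattern requiring P2 can never match bond 1 (no residue at P2)
        rs = CleavageRuleSet(
            "e", "x", (SiteSpec(p1=frozenset(ALPHABET), p2=frozenset(ALPHABET)),)
        )
        assert find_cleavage_sites("AA", rs) == frozenset()
        assert find_cleavage_sites("AAA", rs) == {2}

    def test_agrees_with_bruteforce_on_random_instances(self):
        rng = random.Random(20260921)
        for _ in range(200):
            seq = random_sequence(rng, max_len=120)
            rules = [random_ruleset(rng, f"e{j}") for j in range(rng.randint(1, 3))]
            assert find_cleavage_sites(seq, rules) == brute_cleavage_sites(seq, rules)


class TestDigest:
    def test_partial_digest_fragments_and_dh(self, gi_rules):
        result = digest("HPF", gi_rules)
        assert [(f, (iv.start, iv.end)) for f, iv in result.fragments] == [
            ("H", (1, 1)),
            ("PF", (2, 3)),
        ]
        assert result.dh == 50

    def test_complete_degradation(self, gi_rules):
        result = digest("NMF", gi_rules)
        assert [f for f, _ in result.fragments] == ["N", "M", "F"]
        assert result.dh == 100

    def test_no_matching_sites_single_fragment(self, gi_rules):
        result = digest("GGGG", gi_rules)
        assert [(f, (iv.start, iv.end)) for f, iv in result.fragments] == [
            ("GGGG", (1, 4))
        ]
        assert result.dh == 0

    def test_protein_record_id_propagates(self, gi_rules):
        rec = ProteinRecord("prot1", "", "HPF")
        assert digest(rec, gi_rules).protein_id == "prot1"

    def test_unknown_mode_rejected(self, gi_rules):
        with pytest.raises(ValueError, match="mode"):
            digest("HPF", gi_rules, mode="kinetic")

    @given(st.text(st.sampled_from(ALPHABET), min_size=1, max_size=150), st.integers(0, 2**31))
    def test_fragment_concatenation_identity(self, seq, seed):
        """Fragments always reassemble the input; boundaries = cut bonds."""
        rng = random.Random(seed)
        rules = [random_ruleset(rng)]
        result = digest(seq, rules)
        assert result.sequence == seq
        assert len(result.fragments) == len(result.cleaved_bonds) + 1
        for frag, iv in result.fragments:
            assert iv.extract(seq) == frag

    def test_sequential_equals_concurrent_for_bundled_gi(self, gi_rules):
        rng = random.Random(7)
        for _ in range(100):
            seq = random_sequence(rng, max_len=80)
            conc = digest(seq, gi_rules, mode="concurrent")
            seq_mode = digest(seq, gi_rules, mode="sequential")
            assert conc.cleaved_bonds == seq_mode.cleaved_bonds

    def test_enzyme_superset_monotonicity(self, gi_rules):
        rng = random.Random(11)
        for _ in range(100):
            seq = random_sequence(rng, max_len=100)
            small = digest(seq, gi_rules[:1])
            big = digest(seq, gi_rules)
            assert set(small.cleaved_bonds) <= set(big.cleaved_bonds)
            assert small.dh <= big.dh


class TestDegreeOfHydrolysis:
    def test_exact_rational_value(self, gi_rules):
        result = digest("HPF", gi_rules)
        assert degree_of_hydrolysis(result) == Fraction(100, 2)

    def test_all_bonds_cleaved_is_100(self, gi_rules):
        assert digest("FFFF", gi_rules).dh == 100

    def test_no_bonds_cleaved_is_0(self, gi_rules):
        assert digest("GGG", gi_rules).dh == 0

    def test_single_residue_is_0_by_convention(self, gi_rules):
        assert digest("F", gi_rules).dh == 0

    def test_dh_is_rational_with_denominator_n_minus_1(self, gi_rules):
        rng = random.Random(3)
        for _ in range(50):
            seq = random_sequence(rng, max_len=60, min_len=2)
            dh = digest(seq, gi_rules).dh
            assert 0 <= dh <= 100
            assert (dh * (len(seq) - 1) / 100).denominator == 1
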