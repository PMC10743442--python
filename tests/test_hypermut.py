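"""TR/VR alignment, substitution spectra, reachable residues."""

from itertools import product

import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from dgrscan.hypermut import (
    achievable_residues,
    align_tr_vr,
    codon_position_bias,
    compare_vr1_vr2,
    count_tr_adenines,
    substitution_profile,
)
from dgrscan.simulate import SimulationParams, simulate_genome

dna = st.text(alphabet="ACGT", min_size=3, max_size=60)


class TestAlignTrVr:
    def test_positional_pairing_classes(self):
        aln = align_tr_vr("AACGGT", "TACGGT")
        assert aln.column_class == ["A_sub"] + ["match"] * 5

    def test_b_sub_class(self):
        aln = align_tr_vr("GGC", "GTC")
        assert aln.column_class == ["match", "B_sub", "match"]

    def test_n_column_is_ambiguous(self):
        aln = align_tr_vr("ANC", "AGC")
        assert aln.column_class == ["match", "ambiguous", "match"]

    def test_semiglobal_places_shorter_inside_longer(self):
        aln = align_tr_vr("AACAAC", "AAC")
        prof = substitution_profile(aln)
        assert len(aln.tr_seq) == 3
        assert prof.n_tr_adenines == 4
        assert prof.n_tr_adenines_covered == 2

    def test_length_ratio_guard(self):
        with pytest.raises(ValueError):
            align_tr_vr("A" * 30, "ACG")

    @given(st.data())
    def test_class_conservation_invariant(self, data):
        tr = data.draw(dna)
        vr = data.draw(st.text(alphabet="ACGTN", min_size=len(tr), max_size=len(tr)))
        aln = align_tr_vr(tr, vr)
        prof = substitution_profile(aln)
        n_match = sum(c == "match" for c in aln.column_class)
        assert n_match + prof.n_A_sub + prof.n_B_sub + prof.n_ambiguous == len(tr)


class TestCountAdenines:
    @pytest.mark.parametrize("tr,n", [("AACAAT", 4), ("", 0), ("CGTCGT", 0)])
    def test_counts(self, tr, n):
        assert count_tr_adenines(tr) == n


class TestSubstitutionProfile:
    def test_single_codon_substitution(self):
        prof = substitution_profile(align_tr_vr("AAC", "TAC"))
        assert prof.aa_substitutions == [(0, "N", "Y")]
        assert prof.aa_category_counts["aromatic"] == 1

    def test_identity_gives_zero_profile(self):
        prof = substitution_profile(align_tr_vr("AACGGTTAC", "AACGGTTAC"))
        assert prof.n_A_sub == prof.n_B_sub == 0
        assert prof.aa_substitutions == []
        assert all(v == 0 for v in prof.aa_category_counts.values())

    def test_simulated_cassette_matches_truth(self, sim7):
        genome, orfs, truth = sim7
        for t in truth.targets:
            aln = align_tr_vr(truth.tr_seq, t.vr_seq, tr_frame_offset=t.frame_offset)
            prof = substitution_profile(aln)
            assert prof.n_A_sub == len(t.a_substitutions)
            assert prof.n_B_sub == len(t.b_substitutions)
            assert prof.aa_substitutions == [tuple(x) for x in t.aa_substitutions]
            for pos, tr_base, vr_base in t.a_substitutions:
                assert prof.per_position_A_fate[pos] == vr_base

    def test_frame_shift_consistency(self):
        # dropping one leading codon and keeping the frame yields the same
        # substitutions shifted by one codon index
        tr, vr = "GGGAACTTTAAC", "GGGTACTTTGAC"
        full = substitution_profile(align_tr_vr(tr, vr)).aa_substitutions
        trimmed = substitution_profile(align_tr_vr(tr[3:], vr[3:])).aa_substitutions
        assert [(i + 1, a, b) for i, a, b in trimmed] == full

    def test_zero_profile_on_simulated_tr_against_itself(self, sim7):
        _, _, truth = sim7
        prof = substitution_profile(align_tr_vr(truth.tr_seq, truth.tr_seq))
        assert prof.n_A_sub == prof.n_B_sub == 0
        assert prof.aa_substitutions == []


class TestAchievableResidues:
    def _bruteforce(self, codon):
        residues, stop = set(), False
        choices = ["ACGT" if b == "A" else b for b in codon]
        for var in product(*choices):
            aa = str(Seq("".join(var)).translate(table=11))
            if aa == "*":
                stop = True
            else:
                residues.add(aa)
        return residues, stop

    def test_asn_codons_reach_15_residues(self):
        for codon in ("AAC", "AAT"):
            res = achievable_residues(codon)
            assert len(res.residues) == 15
            assert not res.residues & set("QMKEW")
        assert achievable_residues("AAC").residues == achievable_residues("AAT").residues

    def test_matches_bruteforce_for_all_codons(self):
        for codon in map("".join, product("ACGT", repeat=3)):
            res = achievable_residues(codon)
            expected, stop = self._bruteforce(codon)
            assert res.residues == frozenset(expected), codon
            assert res.stop_reachable == stop, codon

    @given(st.text(alphabet="CGT", min_size=3, max_size=3))
    def test_no_adenine_codon_is_singleton(self, codon):
        assert len(achievable_residues(codon).residues) == 1

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            achievable_residues("ANC")


class TestCodonPositionBias:
    def test_single_substitution_counted_at_position_one(self):
        prof = substitution_profile(align_tr_vr("AAC", "CAC"))
        table = codon_position_bias([prof])
        assert table.loc[("AAC", 1), "A_to_C"] == 1
        assert table.loc[("AAC", 2), "A_to_C"] == 0

    def test_empty_input_all_zero(self):
        table = codon_position_bias([])
        assert (table[["A_to_C", "A_to_G", "A_to_T"]] == 0).all().all()
        assert table["pos1_over_pos2_A_to_C"].isna().all()

    def test_position_asymmetric_simulation_recovered(self):
        params = SimulationParams(
            seed=13,
            p_sub=0.8,
            base_weights_by_position={
                1: {"C": 1.0, "G": 0.0, "T": 0.0},
                2: {"C": 0.0, "G": 0.5, "T": 0.5},
            },
        )
        genome, orfs, truth = simulate_genome(params)
        profs = []
        expected = {}
        for t in truth.targets:
            aln = align_tr_vr(truth.tr_seq, t.vr_seq, tr_frame_offset=t.frame_offset)
            profs.append(substitution_profile(aln))
            for pos, _, vr_base in t.a_substitutions:
                codon = truth.tr_seq[pos - pos % 3 : pos - pos % 3 + 3]
                if codon in ("AAC", "AAT"):
                    key = (codon, pos % 3 + 1, vr_base)
                    expected[key] = expected.get(key, 0) + 1
        table = codon_position_bias(profs)
        for codon in ("AAC", "AAT"):
            for pos in (1, 2):
                for base in "CGT":
                    assert table.loc[(codon, pos), f"A_to_{base}"] == expected.get(
                        (codon, pos, base), 0
                    )
        # position-1 substitutions are all to C, position-2 never to C
        assert table.loc[("AAC", 2), "A_to_C"] == table.loc[("AAT", 2), "A_to_C"] == 0


class TestCompareVrs:
    def test_identical_vrs_share_nothing(self):
        tr = "AACGGTAAC"
        rep = compare_vr1_vr2(align_tr_vr(tr, tr), align_tr_vr(tr, tr))
        assert rep.n_both_mutated == rep.n_only_one_mutated == 0
        assert rep.n_positions == 4

    def test_coincident_mutation_counted(self):
        tr = "CCGGATCC"  # single adenine at position 4
        vr = "CCGGTTCC"
        rep = compare_vr1_vr2(align_tr_vr(tr, vr), align_tr_vr(tr, vr))
        assert rep.n_both_mutated == rep.n_both_same_base == 1

    def test_mismatched_templates_rejected(self):
        with pytest.raises(ValueError):
            compare_vr1_vr2(align_tr_vr("AAC", "AAC"), align_tr_vr("AAT", "AAT"))

    def test_simulated_independent_vrs_match_enumeration(self):
        genome, orfs, truth = simulate_genome(SimulationParams(seed=3, p_sub=0.5))
        t1, t2 = truth.targets
        rep = compare_vr1_vr2(
            align_tr_vr(truth.tr_seq, t1.vr_seq),
            align_tr_vr(truth.tr_seq, t2.vr_seq),
        )
        fate1 = {p: b for p, _, b in t1.a_substitutions}
        fate2 = {p: b for p, _, b in t2.a_substitutions}
        adenines = {i for i, b in enumerate(truth.tr_seq) if b == "A"}
        both = {p for p in adenines if p in fate1 and p in fate2}
        assert rep.n_positions == len(adenines)
        assert rep.n_both_mutated == len(both)
        assert rep.n_both_same_base == sum(fate1[p] == fate2[p] for p in both)
        assert rep.n_only_one_mutated == len(
            (set(fate1) | set(fate2)) - both
        )
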