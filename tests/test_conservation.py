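import numpy as np
import pytest

from iuorfkit.conservation import (
    GAP,
    align_pair,
    alignment_score,
    analyze_orthologs,
    conservation_report,
    extract_feature_vector,
    feature_vector_from_candidate,
    pairwise_identity,
    project_position,
    select_closest_ortholog,
    translate_sorf,
)
from iuorfkit.io import SequenceRecord
from iuorfkit.simulate import PlantSpec, generate_ortholog_trio, generate_transcript

from conftest import random_rna


def nw_score_oracle(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Independent Needleman-Wunsch scorer (plain DP, linear gaps)."""
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * gap] + [0.0] * m
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            cur[j] = max(diag, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("AUGCGU", "AUGCGU") == 1.0

    def test_disjoint(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGU")

    def test_score_matches_dp_oracle(self, rng):
        for _ in range(40):
            a = random_rna(rng, int(rng.integers(5, 60)))
            b = random_rna(rng, int(rng.integers(5, 60)))
            assert alignment_score(a, b) == pytest.approx(nw_score_oracle(a, b))

    def test_identity_bounds(self, rng):
        for _ in range(20):
            a = random_rna(rng, 30)
            b = random_rna(rng, 35)
            assert 0.0 <= pairwise_identity(a, b) <= 1.0


class TestSelectClosestOrtholog:
    def test_single_candidate(self):
        ref = SequenceRecord(id="ref", seq="AUGCAUGC")
        only = SequenceRecord(id="x", seq="AUGCAUGC")
        assert select_closest_ortholog(ref, [only]) is only

    def test_higher_identity_wins(self):
        ref = SequenceRecord(id="ref", seq="AUGCAUGCAUGC")
        close = SequenceRecord(id="close", seq="AUGCAUGCAUGG")
        far = SequenceRecord(id="far", seq="AUGCCCCCGGGG")
        assert select_closest_ortholog(ref, [far, close]) is close

    def test_empty_candidates(self):
        ref = SequenceRecord(id="ref", seq="AUGC")
        with pytest.raises(ValueError):
            select_closest_ortholog(ref, [])

    def test_decoy_paralog_rejected(self, rng):
        ref_seq = random_rna(rng, 200)

        def mutate(seq, rate):
            out = list(seq)
            for i in range(len(out)):
                if rng.random() < rate:
                    out[i] = {"A": "C", "C": "G", "G": "U", "U": "A"}[out[i]]
            return "".join(out)

        true_ortholog = SequenceRecord(id="b_true", seq=mutate(ref_seq, 0.10))
        decoy = SequenceRecord(id="a_decoy", seq=mutate(ref_seq, 0.30))
        ref = SequenceRecord(id="ref", seq=ref_seq)
        assert select_closest_ortholog(ref, [decoy, true_ortholog]).id == "b_true"


class TestProjectPosition:
    def test_identity_mapping(self):
        aln = {"a": "AUGCUU", "b": "AUGCUU"}
        for p in range(1, 7):
            assert project_position(aln, "a", p, "b") == p

    def test_deletion_offsets(self):
        # b lacks a 3-nt block 5' of the queried position
        aln = {"a": "AAACCCGGG", "b": "AAA---GGG"}
        assert project_position(aln, "a", 8, "b") == 5

    def test_gap_column(self):
        aln = {"a": "AAACCCGGG", "b": "AAA---GGG"}
        assert project_position(aln, "a", 5, "b") == GAP

    def test_unknown_id(self):
        with pytest.raises(KeyError):
            project_position({"a": "AC"}, "a", 1, "z")

    def test_roundtrip_on_random_indel_fixtures(self, rng):
        for _ in range(30):
            a = random_rna(rng, 80)
            b_seq = list(a)
            # random 1-6 nt deletion and substitutions
            start = int(rng.integers(10, 60))
            dlen = int(rng.integers(1, 7))
            del b_seq[start : start + dlen]
            b = "".join(b_seq)
            ga, gb = align_pair(a, b)
            aln = {"a": ga, "b": gb}
            for p in range(1, len(b) + 1):
                back = project_position(aln, "b", p, "a")
                if back != GAP:
                    assert project_position(aln, "a", back, "b") == p


class TestFeatureVectors:
    def test_reference_self_consistency(self):
        spec = PlantSpec(klass="upstream", iuORF_len_codons=12, spacer_nt=8,
                         iu_kozak_tier="adequate", nt_kozak_tier="strong")
        rec, calls, truth = generate_transcript(spec, seed=31)
        cand = truth.candidate
        vec = feature_vector_from_candidate(rec, cand)
        assert vec.iu_start_codon == "AUG"
        assert vec.nt_start_codon == "AUG"
        assert vec.iu_context_tier == cand.iu_kozak
        assert vec.nt_context_tier == cand.nt_kozak
        assert vec.iuORF_len_codons == cand.iuORF_len_codons
        assert vec.spacer_nt == cand.spacer_nt
        assert vec.dist_cTIS_to_iuTIS == cand.iuTIS - cand.cTIS

    def test_spacer_shift_plus6(self):
        spec = PlantSpec(klass="upstream", iuORF_len_codons=10, spacer_nt=9)
        rec, _, truth = generate_transcript(spec, seed=33)
        cand = truth.candidate
        # ortholog with 6 extra nt inserted inside the spacer region
        cut = cand.iuSTOP_end + 2
        ortho = SequenceRecord(id="shifted", seq=rec.seq[:cut] + "CCCCCC" + rec.seq[cut:])
        ga, gb = align_pair(rec.seq, ortho.seq)
        aln = {"ref": ga, "shifted": gb}
        anchors = [
            project_position(aln, "ref", p, "shifted")
            for p in (cand.cTIS, cand.iuTIS, cand.ntTIS)
        ]
        vec = extract_feature_vector(ortho, "shifted", *anchors)
        assert vec.spacer_nt == cand.spacer_nt + 6
        assert vec.iuORF_len_codons == cand.iuORF_len_codons

    def test_gap_anchor_marks_absent(self):
        rec = SequenceRecord(id="t", seq="AUGCCCUAA" * 5)
        vec = extract_feature_vector(rec, "sp", GAP, GAP, 10)
        assert vec.iu_start_codon == "absent"
        assert vec.iuORF_len_codons is None

    def test_cug_at_projected_nttis(self):
        # primate-like ortholog: CUG in an optimal context at the ntTIS
        spec = PlantSpec(klass="upstream", iuORF_len_codons=10, spacer_nt=9,
                         nt_kozak_tier="strong")
        rec, _, truth = generate_transcript(spec, seed=35)
        cand = truth.candidate
        seq = list(rec.seq)
        nt = cand.ntTIS
        seq[nt - 7 : nt - 1] = "GCCACC"
        seq[nt - 1 : nt + 2] = "CUG"
        seq[nt + 2] = "G"
        ortho = SequenceRecord(id="primate", seq="".join(seq))
        vec = extract_feature_vector(ortho, "primate", cand.cTIS, cand.iuTIS, cand.ntTIS)
        assert vec.nt_start_codon == "CUG"
        assert vec.nt_context_tier == "optimal"


class TestConservationReport:
    def test_identical_vectors_all_true(self):
        spec = PlantSpec(klass="upstream", iuORF_len_codons=10, spacer_nt=9)
        rec, _, truth = generate_transcript(spec, seed=37)
        vec = feature_vector_from_candidate(rec, truth.candidate)
        rep = conservation_report(vec, [vec, vec])
        assert all(rep.flags.values())
        assert rep.sorf_peptide_identity == 1.0

    def test_missing_iu_start_not_conserved(self):
        spec = PlantSpec(klass="upstream", iuORF_len_codons=10, spacer_nt=9)
        rec, _, truth = generate_transcript(spec, seed=37)
        vec = feature_vector_from_candidate(rec, truth.candidate)
        import dataclasses

        broken = dataclasses.replace(vec, iu_start_codon="absent", species="other")
        rep = conservation_report(vec, [broken])
        assert not rep.flags["iu_start_codon"]

    def test_permutation_invariance(self):
        trio, truth = generate_ortholog_trio(
            PlantSpec(klass="upstream", iuORF_len_codons=15, spacer_nt=9), 0.08, seed=39
        )
        ref_vec, others, _ = analyze_orthologs(trio.reference, truth.candidate, trio.others)
        rep1 = conservation_report(ref_vec, others)
        rep2 = conservation_report(ref_vec, list(reversed(others)))
        assert rep1.flags == rep2.flags
        assert rep1.sorf_peptide_identity == pytest.approx(rep2.sorf_peptide_identity)

    def test_divergent_trio_conserves_geometry_not_peptide(self):
        trio, truth = generate_ortholog_trio(
            PlantSpec(klass="upstream", iuORF_len_codons=25, spacer_nt=14), 0.12, seed=41
        )
        _, _, rep = analyze_orthologs(trio.reference, truth.candidate, trio.others)
        for geo in ("iu_start_codon", "nt_start_codon", "iuORF_len_codons",
                    "spacer_nt", "dist_cTIS_to_iuTIS"):
            assert rep.flags[geo], geo
        assert rep.sorf_peptide_identity < 1.0

    def test_zero_divergence_full_conservation(self):
        trio, truth = generate_ortholog_trio(
            PlantSpec(klass="upstream", iuORF_len_codons=20, spacer_nt=14), 0.0, seed=43
        )
        assert all(o.seq == trio.reference.seq for o in trio.others)
        _, _, rep = analyze_orthologs(trio.reference, truth.candidate, trio.others)
        assert all(rep.flags.values())
        assert rep.sorf_peptide_identity == 1.0


class TestTranslateSorf:
    def test_excludes_stop(self):
        rec = SequenceRecord(id="t", seq="AUGGCUUAA")
        assert translate_sorf(rec, 1, 9) == "MA"
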