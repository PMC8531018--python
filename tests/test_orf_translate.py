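import random

import pytest

from pantx.io_model import ProteinHit, TranscriptRecord
from pantx.orf_translate import (
    Evidence,
    OrfParams,
    VoteStatus,
    call_orf,
    find_orfs_six_frame,
    split_chimeras,
    translate_transcriptome,
    vote_frame,
)
from pantx.synthetic_fixtures import random_seq

from .oracles import orf_scan_oracle


def _as_tuples(orfs):
    return sorted((o.frame, o.nt_start, o.nt_end, o.protein) for o in orfs)


class TestFindOrfs:
    def test_simple_orf_with_terminal_stop(self):
        orfs = [o for o in find_orfs_six_frame("ATGAAATAA") if o.frame == 1]
        assert [(o.nt_start, o.nt_end, o.protein) for o in orfs] == [(0, 9, "MK")]

    def test_methionine_required_after_upstream_stop(self):
        seq = "TAAGGGATGAAAAAATAA"
        orfs = [o for o in find_orfs_six_frame(seq) if o.frame == 1]
        assert [(o.nt_start, o.nt_end, o.protein) for o in orfs] == [(6, 18, "MKK")]

    def test_no_methionine_needed_without_upstream_stop(self):
        orfs = [o for o in find_orfs_six_frame("AAAAAATAA") if o.frame == 1]
        assert [(o.nt_start, o.nt_end, o.protein) for o in orfs] == [(0, 9, "KK")]

    def test_segment_without_atg_after_stop_yields_nothing(self):
        # frame +1: stop, then codons with no ATG
        orfs = [o for o in find_orfs_six_frame("TAAAAAAAA") if o.frame == 1]
        assert orfs == []

    def test_n_codons_translate_to_x(self):
        orfs = [o for o in find_orfs_six_frame("ATGANATAA") if o.frame == 1]
        assert orfs[0].protein == "MX"

    def test_sub_codon_sequence_is_empty(self):
        assert find_orfs_six_frame("AC") == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        for _ in range(100):
            seq = random_seq(rng, 300, gc=rng.choice([0.4, 0.5, 0.68]))
            assert _as_tuples(find_orfs_six_frame(seq)) == sorted(orf_scan_oracle(seq))

    def test_oracle_agreement_with_n_bases(self):
        rng = random.Random(5)
        for _ in range(50):
            seq = "".join(rng.choice("ACGTN") for _ in range(120))
            assert _as_tuples(find_orfs_six_frame(seq)) == sorted(orf_scan_oracle(seq))

    def test_proteins_are_stop_free(self):
        rng = random.Random(9)
        for _ in range(50):
            for o in find_orfs_six_frame(random_seq(rng, 400)):
                assert "*" not in o.protein


def _hit(frame, rank=1, qs=0, qe=90, qid="t"):
    return ProteinHit(query_id=qid, rank=rank, frame=frame, q_start=qs, q_end=qe,
                      subject_id=f"s{rank}")


class TestVoteFrame:
    def test_two_of_three_majority(self):
        v = vote_frame([_hit(2, 1), _hit(2, 2), _hit(-3, 3)])
        assert v.status is VoteStatus.VOTE and v.frame == 2

    def test_three_different_frames_no_majority(self):
        v = vote_frame([_hit(1, 1), _hit(2, 2), _hit(3, 3)])
        assert v.status is VoteStatus.NO_MAJORITY

    def test_single_hit_trivial_majority(self):
        v = vote_frame([_hit(-1)])
        assert v.status is VoteStatus.VOTE and v.frame == -1

    def test_no_hits(self):
        assert vote_frame([]).status is VoteStatus.NO_HITS

    def test_coords_are_union_of_agreeing_hits(self):
        v = vote_frame([_hit(2, 1, qs=10, qe=50), _hit(2, 2, qs=40, qe=120)])
        assert v.coords == (10, 120)


class TestCallOrf:
    def test_fixture_vote_recovery(self, orf_fixture):
        fx = orf_fixture
        for rid, planted in fx.truth_orfs.items():
            rec = next(r for r in fx.records if r.id == rid)
            call = call_orf(rec, fx.hits_by_query[rid])
            assert call.evidence is Evidence.BLAST_VOTE
            assert (call.frame, call.nt_start, call.nt_end, call.protein) == (
                planted.frame, planted.nt_start, planted.nt_end, planted.protein
            )
            assert call.coding

    def test_no_hits_uses_longest_orf(self, orf_fixture):
        fx = orf_fixture
        rid, planted = next(iter(fx.truth_orfs.items()))
        rec = next(r for r in fx.records if r.id == rid)
        call = call_orf(rec, [])
        assert call.evidence is Evidence.LONGEST_ORF
        # the planted ORF dominates the record, so it also wins by length
        assert call.protein == planted.protein

    def test_short_orf_flags_noncoding(self):
        rec = TranscriptRecord("t", "ATG" + "AAA" * 20 + "TAA")  # 21 aa
        call = call_orf(rec, [])
        assert not call.coding

    def test_plastid_whitelist_exempts_short_orf(self):
        rec = TranscriptRecord("t", "ATG" + "AAA" * 20 + "TAA")
        params = OrfParams(plastid_whitelist=frozenset({"t"}))
        assert call_orf(rec, [], params).coding

    def test_no_majority_falls_back_to_longest_matching(self):
        rng = random.Random(13)
        seq = "TAA" + "ATG" + "GGC" * 100 + "TAA" + random_seq(rng, 60)
        rec = TranscriptRecord("t", seq)
        hits = [_hit(1, 1, qs=3, qe=200), _hit(2, 2, qs=3, qe=200),
                _hit(3, 3, qs=3, qe=200)]
        call = call_orf(rec, hits)
        assert call.evidence is Evidence.BLAST_LONGEST_MATCHING
        # expected: longest oracle ORF among the hit frames overlapping a hit
        candidates = [
            (f, lo, hi, prot)
            for (f, lo, hi, prot) in orf_scan_oracle(seq)
            if f in (1, 2, 3) and lo < 200 and 3 < hi
        ]
        exp = max(candidates, key=lambda t: len(t[3]))
        assert (call.frame, call.nt_start, call.nt_end, call.protein) == exp


class TestSplitChimeras:
    def test_planted_fusions_split_and_conserve_sequence(self, orf_fixture):
        fx = orf_fixture
        n_splits = 0
        for rec in fx.records:
            orfs = find_orfs_six_frame(rec.seq)
            parts = split_chimeras(rec, orfs)
            if len(parts) > 1:
                n_splits += 1
                assert rec.id in fx.chimera_truth
                assert len(parts) == fx.chimera_truth[rec.id]
                assert "".join(p.seq for p in parts) == rec.seq
        assert n_splits == len(fx.chimera_truth)

    def test_dominant_orf_is_not_a_candidate(self):
        # 2502 bp with a single ~84% ORF: not screened
        seq = "ATG" + "GGC" * 699 + "TAA" + "C" * 399
        rec = TranscriptRecord("t", seq)
        parts = split_chimeras(rec, find_orfs_six_frame(seq))
        assert parts == [rec]

    def test_second_orf_below_300aa_blocks_split(self, orf_fixture):
        # one long ORF + one 250 aa ORF in a >2000 bp transcript: unchanged
        rng = random.Random(21)
        a = "TAA" + "ATG" + "GGC" * 320 + "TAA"
        b = "TAA" + "ATG" + "GGC" * 250 + "TAA"
        pad = random_seq(rng, 600)
        seq = a + b + pad
        rec = TranscriptRecord("t", seq)
        orfs = find_orfs_six_frame(seq)
        longest = max(o.nt_span for o in orfs)
        assert len(seq) > 2000 and longest < 0.8 * len(seq)
        assert split_chimeras(rec, orfs) == [rec]


class TestTranslateTranscriptome:
    def test_noncoding_records_flagged(self, orf_fixture):
        fx = orf_fixture
        res = translate_transcriptome(fx.records, fx.hits_by_query)
        assert sorted(res.noncoding_ids) == sorted(fx.noncoding_ids)

    def test_every_emitted_protein_meets_length_floor(self, orf_fixture):
        fx = orf_fixture
        res = translate_transcriptome(fx.records, fx.hits_by_query)
        for call in res.proteins:
            assert len(call.protein) >= 50
            assert "*" not in call.protein
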