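import random

import pytest

from pantx.io_model import AlignmentHit, Source, Strand, TranscriptRecord
from pantx.merge_engine import (
    DecisionCategory,
    MergeParams,
    build_merged_transcript,
    classify_query_transcript,
    integrate_manual_genes,
    unify,
)
from pantx.naive_align import align_pair, revcomp
from pantx.synthetic_fixtures import gen_unify_fixture, random_seq

PARAMS = MergeParams()


def _hit(qid, tid, qs, qe, ts, te, matches=None, mismatches=0, strand=Strand.FORWARD,
         gaps=0):
    return AlignmentHit(
        query_id=qid, target_id=tid, strand=strand,
        matches=matches if matches is not None else qe - qs,
        mismatches=mismatches, q_start=qs, q_end=qe, t_start=ts, t_end=te,
        q_gap_bases=gaps,
    )


class TestClassify:
    def setup_method(self):
        rng = random.Random(0)
        self.gene = random_seq(rng, 3000)
        self.a5 = TranscriptRecord("A", self.gene[:1400])
        self.a3 = TranscriptRecord("B", self.gene[1600:])
        self.bridge = TranscriptRecord("q", self.gene[1200:1900], Source.QUERY)
        self.lengths = {"A": 1400, "B": 1400, "C": 2000}

    def test_no_hits_is_unique(self):
        d = classify_query_transcript(self.bridge, [], PARAMS, self.lengths)
        assert d.category is DecisionCategory.UNIQUE

    def test_contained_high_score_hit_is_redundant(self):
        hit = _hit("q", "C", 0, 250, 500, 750)
        d = classify_query_transcript(self.bridge, [hit], PARAMS, self.lengths)
        assert d.category is DecisionCategory.REDUNDANT

    def test_two_anchor_geometry_is_merge(self):
        h5 = _hit("q", "A", 0, 200, 1200, 1400)
        h3 = _hit("q", "B", 400, 700, 0, 300)
        d = classify_query_transcript(self.bridge, [h5, h3], PARAMS, self.lengths)
        assert d.category is DecisionCategory.MERGE
        assert (d.anchor5_id, d.anchor3_id) == ("A", "B")

    def test_score_100_passes_but_99_does_not(self):
        h5 = _hit("q", "A", 0, 100, 1300, 1400)  # score exactly 100
        h3 = _hit("q", "B", 400, 700, 0, 300)
        d = classify_query_transcript(self.bridge, [h5, h3], PARAMS, self.lengths)
        assert d.category is DecisionCategory.MERGE
        h5_low = _hit("q", "A", 0, 100, 1300, 1400, matches=100, mismatches=1)
        assert h5_low.score == 99
        d = classify_query_transcript(self.bridge, [h5_low, h3], PARAMS, self.lengths)
        assert d.category is DecisionCategory.REDUNDANT

    def test_excess_internal_gap_blocks_merge(self):
        h5 = _hit("q", "A", 0, 200, 1200, 1400, gaps=201)
        h3 = _hit("q", "B", 400, 700, 0, 300)
        d = classify_query_transcript(self.bridge, [h5, h3], PARAMS, self.lengths)
        assert d.category is DecisionCategory.REDUNDANT

    def test_excess_end_overhang_blocks_merge(self):
        # 150 unmatched bases at the query 5' end exceed the 100 bp allowance
        h5 = _hit("q", "A", 150, 350, 1150, 1350)
        h3 = _hit("q", "B", 400, 700, 0, 300)
        d = classify_query_transcript(self.bridge, [h5, h3], PARAMS, self.lengths)
        assert d.category is DecisionCategory.REDUNDANT

    def test_strand_disagreement_blocks_merge(self):
        h5 = _hit("q", "A", 0, 200, 1200, 1400)
        h3 = _hit("q", "B", 400, 700, 0, 300, strand=Strand.REVERSE)
        d = classify_query_transcript(self.bridge, [h5, h3], PARAMS, self.lengths)
        assert d.category is DecisionCategory.REDUNDANT

    def test_unknown_base_transcript_is_hard_error(self):
        with pytest.raises(ValueError, match="unknown base"):
            classify_query_transcript(
                self.bridge, [_hit("q", "nope", 0, 200, 0, 200)], PARAMS, self.lengths
            )


class TestBuildMerged:
    def _planted(self, seed=0):
        rng = random.Random(seed)
        gene = random_seq(rng, 3000)
        a5 = TranscriptRecord("A", gene[:1400])
        a3 = TranscriptRecord("B", gene[1600:])
        bridge = TranscriptRecord("q", gene[1200:1900], Source.QUERY)
        h5 = _hit("q", "A", 0, 200, 1200, 1400)
        h3 = _hit("q", "B", 400, 700, 0, 300)
        return gene, a5, a3, bridge, h5, h3

    def test_reconstructs_planted_gene_exactly(self):
        gene, a5, a3, bridge, h5, h3 = self._planted()
        mt = build_merged_transcript(a5, bridge, a3, h5, h3)
        assert mt.seq == gene

    def test_provenance_tiles_and_maps_to_sources(self):
        gene, a5, a3, bridge, h5, h3 = self._planted()
        mt = build_merged_transcript(a5, bridge, a3, h5, h3)
        cursor = 0
        sources = {"A": a5.seq, "B": a3.seq, "q": bridge.seq}
        for part in mt.parts:
            lo, hi = part.merged_interval
            assert lo == cursor
            cursor = hi
            src = sources[part.source_id][part.source_interval[0]:part.source_interval[1]]
            if part.strand is Strand.REVERSE:
                src = revcomp(src)
            assert mt.seq[lo:hi] == src
        assert cursor == len(mt.seq)

    def test_zero_overlap_is_pure_concatenation(self):
        a5 = TranscriptRecord("A", "A" * 100 + "ACGTACGTACGT" * 10)
        bridge = TranscriptRecord("q", "ACGTACGTACGT" * 10 + "GGCC" * 25, Source.QUERY)
        a3 = TranscriptRecord("B", "GGCC" * 25 + "T" * 100)
        h5 = _hit("q", "A", 0, 120, 100, 220)
        h3 = _hit("q", "B", 120, 220, 0, 100)
        mt = build_merged_transcript(a5, bridge, a3, h5, h3)
        # bridge's aligned ends touch, so the merge is anchor5 + anchor3 verbatim
        assert mt.seq == a5.seq + a3.seq
        assert len(mt.seq) >= max(len(a5), len(a3))

    def test_reverse_strand_bridge(self):
        gene, a5, a3, bridge, h5, h3 = self._planted(seed=3)
        rc_bridge = TranscriptRecord("q", revcomp(bridge.seq), Source.QUERY)
        hits = align_pair("q", rc_bridge.seq, "A", a5.seq) + align_pair(
            "q", rc_bridge.seq, "B", a3.seq
        )
        assert all(h.strand is Strand.REVERSE for h in hits)
        h5r = next(h for h in hits if h.target_id == "A")
        h3r = next(h for h in hits if h.target_id == "B")
        mt = build_merged_transcript(a5, rc_bridge, a3, h5r, h3r)
        assert mt.seq == gene

    def test_incompatible_junction_overlap_is_hard_error(self):
        a5 = TranscriptRecord("A", random_seq(random.Random(1), 500))
        a3 = TranscriptRecord("B", random_seq(random.Random(2), 500))
        bridge = TranscriptRecord("q", random_seq(random.Random(3), 400), Source.QUERY)
        # anchor hits overlap by 50 bp on the bridge but anchors disagree
        h5 = _hit("q", "A", 0, 250, 250, 500)
        h3 = _hit("q", "B", 200, 400, 0, 200)
        with pytest.raises(ValueError, match="incompatible merge"):
            build_merged_transcript(a5, bridge, a3, h5, h3)


class TestManualIntegration:
    def _setup(self):
        rng = random.Random(5)
        auto = [TranscriptRecord(f"t{i}", random_seq(rng, 500)) for i in range(3)]
        manual = [TranscriptRecord("M", random_seq(rng, 600), Source.MANUAL)]
        return auto, manual

    def test_score_210_displaces(self):
        auto, manual = self._setup()
        hits = [_hit("M", "t0", 0, 210, 0, 210)]
        kept, named, log = integrate_manual_genes(auto, manual, hits, PARAMS)
        assert [r.id for r in kept] == ["t1", "t2"]
        assert log == [("t0", "M")]
        assert named[0].id == "comp17050001_c0_seq1"

    def test_score_199_retained(self):
        auto, manual = self._setup()
        hits = [_hit("M", "t0", 0, 199, 0, 199)]
        kept, _named, log = integrate_manual_genes(auto, manual, hits, PARAMS)
        assert len(kept) == 3 and log == []

    def test_no_hits_appends_manual_only(self):
        auto, manual = self._setup()
        kept, named, log = integrate_manual_genes(auto, manual, [], PARAMS)
        assert len(kept) == 3 and len(named) == 1 and log == []


class TestUnify:
    def test_fixture_truth_recovered(self, unify_fixture):
        fx = unify_fixture
        res = unify(fx.base, fx.query, fx.hits)
        got = {d.query_id: d.category.value for d in res.decisions}
        assert got == fx.truth
        assert res.decision_counts() == {"UNIQUE": 3, "REDUNDANT": 2, "MERGE": 1}

    def test_merged_transcript_matches_planted_gene(self, unify_fixture):
        fx = unify_fixture
        res = unify(fx.base, fx.query, fx.hits)
        (mt,) = res.merged
        (_bid, (_a5, _a3, gene)) = next(iter(fx.bridge_truth.items()))
        assert mt.seq == gene
        assert mt.name == "comp17000000_c0_seq1"

    def test_anchors_consumed_not_standalone(self, unify_fixture):
        fx = unify_fixture
        res = unify(fx.base, fx.query, fx.hits)
        out_ids = {r.id for r in res.records}
        for _bid, (a5, a3, _gene) in fx.bridge_truth.items():
            assert a5 not in out_ids and a3 not in out_ids

    def test_every_query_has_exactly_one_decision(self, unify_fixture):
        fx = unify_fixture
        res = unify(fx.base, fx.query, fx.hits)
        assert sorted(d.query_id for d in res.decisions) == sorted(q.id for q in fx.query)

    def test_idempotence_self_unification(self, unify_fixture):
        fx = unify_fixture
        first = unify(fx.base, fx.query, fx.hits)
        unified = first.records
        as_query = [
            TranscriptRecord(f"copy_{r.id}", r.seq, Source.QUERY) for r in unified
        ]
        from pantx.naive_align import align_all

        hits = align_all(
            [(q.id, q.seq) for q in as_query],
            [(t.id, t.seq) for t in unified],
            skip_self=False,
        )
        second = unify(unified, as_query, hits)
        counts = second.decision_counts()
        assert counts["MERGE"] == 0 and counts["UNIQUE"] == 0
        assert [r.id for r in second.records] == [r.id for r in unified]

    def test_duplicate_ids_across_inputs_rejected(self, unify_fixture):
        fx = unify_fixture
        with pytest.raises(ValueError, match="not distinct"):
            unify(fx.base, fx.base, [])

    def test_deterministic(self, unify_fixture):
        fx = unify_fixture
        r1 = unify(fx.base, fx.query, fx.hits)
        r2 = unify(fx.base, fx.query, fx.hits)
        assert [(r.id, r.seq) for r in r1.records] == [(r.id, r.seq) for r in r2.records]
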