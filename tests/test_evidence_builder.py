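import pytest

from isgap import evidence_builder as eb
from isgap.formats_io import ProteinAlignmentRecord
from isgap.seqcore import ExonBlock, GeneModel, Transcript, cds_of

TR = Transcript("T1", "CCATGGCTGTAAGTTTTTAGAAATAAGG")
TMAP = {"T1": TR}


def _rec(blocks, percent=85.0, score=400.0, pid="P1", strand="+", phase=0, **kw):
    return ProteinAlignmentRecord(
        protein_id=pid,
        protein_length=100,
        transcript_id="T1",
        strand=strand,
        blocks=tuple(ExonBlock(s, e) for s, e in blocks),
        phase=phase,
        percent=percent,
        raw_score=score,
        **kw,
    )


class TestStructuresFromAlignments:
    def test_percent_threshold(self):
        assert eb.structures_from_alignments([_rec([(2, 8)], percent=29.9)], TMAP) == []
        assert len(eb.structures_from_alignments([_rec([(2, 8)], percent=30.0)], TMAP)) == 1

    def test_spliced_model_from_blocks(self):
        (m,) = eb.structures_from_alignments([_rec([(2, 8), (20, 26)])], TMAP)
        assert cds_of(m, TR) == "ATGGCTAAATAA"
        assert m.is_complete and m.support == 1 and m.score == 400.0
        assert m.evidence_ids == ("P1",)

    def test_max_intron_ceiling(self):
        long_t = Transcript("T1", "A" * 70000)
        recs = [_rec([(0, 6), (60007, 60013)])]
        assert eb.structures_from_alignments(recs, {"T1": long_t}) == []
        assert len(
            eb.structures_from_alignments(recs, {"T1": long_t}, max_intron=70000)
        ) == 1

    def test_flagged_records_dropped(self):
        assert eb.structures_from_alignments(
            [_rec([(2, 8)], earlystop_flag=True)], TMAP
        ) == []


def _model(exons, pid, strand="+", phase=0, score=100.0):
    m = GeneModel(
        id=f"x.{pid}",
        transcript_id="T1",
        strand=strand,
        exons=tuple(ExonBlock(s, e) for s, e in exons),
        phase=phase,
        support=1,
        score=score,
        evidence_ids=(pid,),
    )
    return m


class TestMergeSameJunctions:
    def test_consensus_boundaries_tie_outermost(self):
        a = _model([(2, 8), (20, 26)], "P1")
        b = _model([(4, 8), (20, 24)], "P2")
        (m,) = eb.merge_same_junctions([a, b], TMAP)
        assert m.exons == (ExonBlock(2, 8), ExonBlock(20, 26))
        assert m.support == 2 and m.source == "merged"
        assert m.score == 200.0

    def test_majority_boundary_wins(self):
        ms = [
            _model([(4, 8), (20, 26)], "P1"),
            _model([(4, 8), (20, 26)], "P2"),
            _model([(2, 8), (20, 26)], "P3"),
        ]
        (m,) = eb.merge_same_junctions(ms, TMAP)
        assert m.exons[0] == ExonBlock(4, 8)

    def test_singleton_only_changes_source(self):
        a = _model([(2, 8), (20, 26)], "P1")
        (m,) = eb.merge_same_junctions([a], TMAP)
        assert m.exons == a.exons and m.support == 1 and m.source == "merged"

    def test_different_junctions_do_not_merge(self):
        a = _model([(2, 8), (20, 26)], "P1")
        b = _model([(2, 9), (21, 26)], "P2")
        assert len(eb.merge_same_junctions([a, b], TMAP)) == 2

    def test_single_exon_merge_requires_same_frame(self):
        a = _model([(2, 14)], "P1")
        b = _model([(5, 14)], "P2")  # same frame (5 = 2 mod 3)
        c = _model([(3, 15)], "P3")  # different frame
        out = eb.merge_same_junctions([a, b, c], TMAP)
        assert len(out) == 2
        merged = next(m for m in out if m.support == 2)
        assert merged.exons == (ExonBlock(2, 14),)

    def test_junctions_never_altered_and_support_conserved(self, noise_free):
        asm = noise_free.assembly_a
        cands = eb.structures_from_alignments(noise_free.alignments, asm)
        merged = eb.merge_same_junctions(cands, asm)
        assert len(merged) <= len(cands)
        assert sum(m.support for m in merged) == len(cands)
        in_j = {(m.transcript_id, m.strand, m.junctions()) for m in cands if m.multiexon}
        out_j = {(m.transcript_id, m.strand, m.junctions()) for m in merged if m.multiexon}
        assert in_j == out_j


class TestFilterInvalidCds:
    def test_internal_stop_removed(self):
        t = Transcript("T1", "ATGTAAGCTTAA")
        m = GeneModel("g", "T1", "+", (ExonBlock(0, 12),))
        assert eb.filter_invalid_cds([m], {"T1": t}) == []

    def test_clean_model_kept(self):
        m = _model([(2, 8), (20, 26)], "P1")
        assert eb.filter_invalid_cds([m], TMAP) == [m]

    def test_frameshift_by_length_removed(self):
        # complete flags but CDS length 1 mod 3
        t = Transcript("T1", "ATGGCTTAAA" * 3)
        m = GeneModel(
            "g", "T1", "+", (ExonBlock(0, 4), ExonBlock(10, 16)),
            has_start=True, has_stop=True,
        )
        assert eb.filter_invalid_cds([m], {"T1": t}) == []


class TestResolveOverlaps:
    def _m(self, mid, exons, support, score, strand="+"):
        return GeneModel(
            id=mid, transcript_id="T1", strand=strand,
            exons=tuple(ExonBlock(s, e) for s, e in exons),
            support=support, score=score,
        )

    def test_support_dominates_score(self):
        a = self._m("A", [(0, 100)], 3, 500)
        b = self._m("B", [(50, 200)], 1, 900)
        assert eb.resolve_overlaps([a, b]) == [a]

    def test_opposite_strands_both_kept(self):
        a = self._m("A", [(0, 100)], 1, 100)
        b = self._m("B", [(0, 100)], 1, 100, strand="-")
        assert len(eb.resolve_overlaps([a, b])) == 2
        assert len(eb.resolve_overlaps([a, b], strandless=True)) == 1

    def test_score_breaks_support_ties(self):
        a = self._m("A", [(0, 100)], 2, 400)
        b = self._m("B", [(50, 200)], 2, 500)
        assert eb.resolve_overlaps([a, b]) == [b]

    def test_transitive_clusters_leave_an_antichain(self, noisy):
        asm = noisy.assembly_a
        cands = eb.structures_from_alignments(noisy.alignments, asm)
        merged = eb.merge_same_junctions(cands, asm)
        out = eb.resolve_overlaps(eb.filter_invalid_cds(merged, asm))
        by_key = {}
        for m in out:
            by_key.setdefault((m.transcript_id, m.strand), []).append(m)
        for models in by_key.values():
            for i, a in enumerate(models):
                for b in models[i + 1 :]:
                    assert not a.span_overlaps(b)


def test_junction_key_of_models():
    multi = _model([(2, 8), (20, 26)], "P1")
    single = _model([(2, 14)], "P1")
    k1 = eb.JunctionKey.of(multi)
    assert k1.junctions == ((8, 20),) and k1.frame is None
    k2 = eb.JunctionKey.of(single)
    assert k2.junctions == () and k2.frame == 2
    with pytest.raises(ValueError):
        eb.JunctionKey("T1", "+", ((20, 8),))


def test_step1_recovers_true_junction_sets(noise_free):
    truth = noise_free
    asm = truth.assembly_a
    cands = eb.structures_from_alignments(truth.alignments, asm)
    merged = eb.merge_same_junctions(cands, asm)
    step1 = eb.resolve_overlaps(eb.filter_invalid_cds(merged, asm))
    true_with_ev = [
        tm for tm in truth.true_models
        if any(m.transcript_id == tm.transcript_id for m in step1)
    ]
    hits = sum(
        any(
            m.transcript_id == tm.transcript_id
            and m.strand == tm.strand
            and m.junctions() == tm.junctions()
            for m in step1
        )
        for tm in true_with_ev
    )
    assert hits == len(true_with_ev)
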