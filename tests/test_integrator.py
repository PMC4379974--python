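import numpy as np
import pytest

from isgap import integrator as ig
from isgap.seqcore import ExonBlock, GeneModel, Transcript, cds_of, validate_model


def _complete(mid, length, multi=False, support=1):
    exons = (
        (ExonBlock(0, length // 2), ExonBlock(length // 2 + 50, length + 50))
        if multi
        else (ExonBlock(0, length),)
    )
    return GeneModel(
        id=mid, transcript_id=f"t.{mid}", strand="+", exons=exons,
        has_start=True, has_stop=True, support=support,
    )


class TestSelectTrainingGenes:
    def test_exact_count_all_complete(self):
        models = [_complete(f"m{i}", 300) for i in range(5000)]
        out = ig.select_training_genes(models, n=2000, seed=0)
        assert len(out) == 2000 and all(m.is_complete for m in out)

    def test_fallback_when_too_few(self, caplog):
        models = [_complete(f"m{i}", 300) for i in range(1500)]
        with caplog.at_level("WARNING"):
            out = ig.select_training_genes(models, n=2000, seed=0)
        assert len(out) == 1500
        assert "1500" in caplog.text

    def test_deterministic_given_seed(self):
        models = [_complete(f"m{i}", 300 + 3 * (i % 7), multi=i % 2 == 0) for i in range(400)]
        a = ig.select_training_genes(models, n=100, seed=5)
        b = ig.select_training_genes(models, n=100, seed=5)
        c = ig.select_training_genes(models, n=100, seed=6)
        assert a == b
        assert a != c

    def test_no_complete_models_is_an_error(self):
        m = GeneModel("m", "t", "+", (ExonBlock(0, 30),))
        with pytest.raises(ValueError):
            ig.select_training_genes([m], n=10, seed=0)


class TestFilterAbnormalAbinitio:
    def _t(self, seq="ATG" + "GCT" * 60 + "TAA"):
        return Transcript("T1", seq)

    def _m(self, exons, **kw):
        return GeneModel(
            "a1", "T1", "+", tuple(ExonBlock(s, e) for s, e in exons),
            source="abinitio", **kw,
        )

    def test_internal_stop_removed(self):
        t = Transcript("T1", "ATGTAA" + "GCT" * 60 + "TAA")
        assert ig.filter_abnormal_abinitio([self._m([(0, 189)])], {"T1": t}) == []

    def test_min_cds_boundary(self):
        t = self._t()
        short = self._m([(0, 149)])
        exact = self._m([(0, 150)])
        assert ig.filter_abnormal_abinitio([short], {"T1": t}) == []
        assert len(ig.filter_abnormal_abinitio([exact], {"T1": t})) == 1

    def test_out_of_bounds_removed(self):
        t = self._t()
        assert ig.filter_abnormal_abinitio([self._m([(0, 10000)])], {"T1": t}) == []

    def test_completeness_flags_recomputed(self):
        t = self._t()
        (m,) = ig.filter_abnormal_abinitio([self._m([(0, 186)])], {"T1": t})
        assert m.is_complete


class TestIntegrate:
    T = Transcript("T1", ("ATGGCA" * 200))  # 1200 nt, stop-free in frame 0
    TMAP = {"T1": T}

    def _ev(self, exons, mid="ev1", support=2):
        return GeneModel(
            mid, "T1", "+", tuple(ExonBlock(s, e) for s, e in exons), support=support
        )

    def _ab(self, exons, mid="ab1"):
        return GeneModel(
            mid, "T1", "+", tuple(ExonBlock(s, e) for s, e in exons), source="abinitio"
        )

    def test_disjoint_models_both_kept(self):
        out = ig.integrate(
            [self._ev([(99, 399)])], [self._ab([(600, 900)])], self.TMAP
        )
        assert {m.id for m in out} == {"ev1", "ab1"}

    def test_same_frame_overlap_extends_to_union(self):
        out = ig.integrate(
            [self._ev([(99, 399)])], [self._ab([(249, 699)])], self.TMAP
        )
        (m,) = out
        assert m.id == "ev1" and m.source == "merged"
        assert m.exons == (ExonBlock(99, 699),)
        assert m.support == 2

    def test_conflicting_junctions_discard_abinitio(self):
        ev = self._ev([(99, 200), (300, 399)])
        ab = self._ab([(99, 210), (290, 399)])
        out = ig.integrate([ev], [ab], self.TMAP)
        assert out == [ev]

    def test_incompatible_frame_discard_abinitio(self):
        out = ig.integrate(
            [self._ev([(99, 399)])], [self._ab([(250, 700)])], self.TMAP
        )
        assert [m.id for m in out] == ["ev1"]
        assert out[0].exons == (ExonBlock(99, 399),)

    def test_abinitio_never_bridges_two_evidence_models(self):
        ev1 = self._ev([(0, 300)], "ev1")
        ev2 = self._ev([(600, 900)], "ev2")
        ab = self._ab([(150, 750)])
        out = ig.integrate([ev1, ev2], [ab], self.TMAP)
        assert {m.id for m in out} == {"ev1", "ev2"}
        assert all(m.exons in ((ExonBlock(0, 300),), (ExonBlock(600, 900),)) for m in out)

    def test_output_is_same_strand_antichain(self, noisy, noisy_result):
        by_key = {}
        for m in noisy_result.integrated:
            by_key.setdefault((m.transcript_id, m.strand), []).append(m)
        for models in by_key.values():
            models.sort(key=lambda m: m.start)
            for a, b in zip(models, models[1:]):
                assert a.end <= b.start

    def test_abinitio_only_genes_recovered(self, noisy, noisy_result):
        # genes with no protein evidence are adopted from ab initio models
        asm = noisy.assembly_a
        with_ev = {a.transcript_id for a in noisy.alignments}
        ab_tids = {m.transcript_id for m in noisy.abinitio}
        orphan = [
            tm for tm in noisy.true_models
            if tm.transcript_id not in with_ev and tm.transcript_id in ab_tids
        ]
        assert len(orphan) >= 20
        by_tid = {}
        for m in noisy_result.final:
            by_tid.setdefault(m.transcript_id, []).append(m)
        hits = sum(
            any(
                cds_of(m, asm[m.transcript_id]) == cds_of(tm, asm[tm.transcript_id])
                for m in by_tid.get(tm.transcript_id, [])
            )
            for tm in orphan
        )
        assert hits / len(orphan) >= 0.9


class TestFinalFilter:
    def test_default_predicate_is_identity(self):
        models = [_complete("m1", 300), _complete("m2", 300)]
        assert ig.final_filter(models) == models

    def test_hitlist_keeps_exactly_listed_ids(self, tmp_path):
        models = [_complete(f"m{i}", 300) for i in range(4)]
        hit = tmp_path / "hits.txt"
        hit.write_text("m0\nm2\n")
        out = ig.final_filter(models, ig.hitlist_predicate(hit))
        assert [m.id for m in out] == ["m0", "m2"]

    def test_empty_hitlist_with_require_hit(self, tmp_path, caplog):
        models = [_complete("m1", 300)]
        hit = tmp_path / "hits.txt"
        hit.write_text("")
        with caplog.at_level("WARNING"):
            out = ig.final_filter(models, ig.hitlist_predicate(hit, require_hit=True))
        assert out == [] and "empty" in caplog.text


class TestSelectRepresentatives:
    def _m(self, mid, exons, complete, support=1):
        return GeneModel(
            mid, "T1", "+", tuple(ExonBlock(s, e) for s, e in exons),
            has_start=complete, has_stop=complete, support=support,
        )

    def test_longest_complete_beats_longer_partial(self):
        a = self._m("a", [(0, 300)], True)
        b = self._m("b", [(100, 550)], True)
        c = self._m("c", [(200, 800)], False)
        assert [m.id for m in ig.select_representatives([a, b, c])] == ["b"]

    def test_longest_partial_when_no_complete(self):
        a = self._m("a", [(0, 600)], False)
        b = self._m("b", [(100, 300)], False)
        assert [m.id for m in ig.select_representatives([a, b])] == ["a"]

    def test_non_overlapping_models_are_separate_loci(self):
        a = self._m("a", [(0, 300)], True)
        b = self._m("b", [(400, 700)], False)
        assert len(ig.select_representatives([a, b])) == 2

    def test_one_representative_per_locus_on_pipeline_output(self, noisy_result):
        final = noisy_result.final
        reps = noisy_result.representatives
        loci = ig.build_loci(final)
        assert len(reps) == len(loci)
        rep_ids = {m.id for m in reps}
        for locus, members in loci:
            chosen = [m for m in members if m.id in rep_ids]
            assert len(chosen) == 1
            if any(m.is_complete for m in members):
                assert chosen[0].is_complete


class TestGeneSetStats:
    def test_two_exon_arithmetic(self):
        m = GeneModel("m", "t", "+", (ExonBlock(0, 6), ExonBlock(18, 24)))
        s = ig.gene_set_stats([m])
        assert s.n_genes == 1 and s.n_multiexon == 1 and s.n_introns == 1
        assert s.mean_exon_len == 6.0 and s.mean_intron_len == 12.0
        assert s.total_len == 12 and s.mean_len == 12.0

    def test_all_single_exon_flags_no_introns(self):
        m = GeneModel("m", "t", "+", (ExonBlock(0, 30),))
        s = ig.gene_set_stats([m])
        assert s.n_multiexon == 0 and s.mean_intron_len == 0.0 and s.no_introns

    def test_totals_additive_over_disjoint_sets(self):
        a = [GeneModel(f"a{i}", "t", "+", (ExonBlock(0, 30 + 3 * i),)) for i in range(5)]
        b = [
            GeneModel(f"b{i}", "t", "+", (ExonBlock(0, 9), ExonBlock(20, 35)))
            for i in range(3)
        ]
        sa, sb, sab = (
            ig.gene_set_stats(a),
            ig.gene_set_stats(b),
            ig.gene_set_stats(a + b),
        )
        assert sab.total_len == sa.total_len + sb.total_len
        assert sab.n_introns == sa.n_introns + sb.n_introns
        assert sab.n_genes == sa.n_genes + sb.n_genes

    def test_empty_set_gives_zeros(self):
        s = ig.gene_set_stats([])
        assert s.n_genes == 0 and s.total_len == 0


def test_every_final_model_passes_all_invariants(noisy, noisy_result):
    asm = noisy.assembly_a
    for m in noisy_result.final:
        validate_model(m, asm[m.transcript_id])
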