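import numpy as np
import pytest

from isgap import formats_io as fio
from isgap.seqcore import ExonBlock, GeneModel, Transcript


def test_tsv_line_parses_to_record(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text("P1\t100\tT1\t+\t85.0\t412\t2-8;20-26\t0\t-\t-\n")
    (rec,) = fio.read_alignment_tsv(p)
    assert rec.protein_id == "P1"
    assert rec.blocks == (ExonBlock(2, 8), ExonBlock(20, 26))
    assert rec.percent == 85.0
    assert rec.raw_score == 412
    assert not rec.frameshift_flag and not rec.earlystop_flag


def test_tsv_unparseable_line_is_hard_error(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text("P1\t100\tT1\n")
    with pytest.raises(ValueError, match=":1"):
        fio.read_alignment_tsv(p)


def test_tsv_overlapping_blocks_rejected_with_warning(tmp_path, caplog):
    p = tmp_path / "a.tsv"
    p.write_text(
        "P1\t100\tT1\t+\t85.0\t412\t2-8;5-26\t0\t-\t-\n"
        "P2\t100\tT1\t+\t85.0\t412\t2-8\t0\t-\t-\n"
    )
    with caplog.at_level("WARNING"):
        recs = fio.read_alignment_tsv(p)
    assert [r.protein_id for r in recs] == ["P2"]
    assert "rejected" in caplog.text


def test_gff2_single_exon_alignment(tmp_path):
    p = tmp_path / "a.gff2"
    p.write_text(
        "T1\texonerate:protein2genome:local\tgene\t3\t26\t412\t+\t.\t"
        "gene_id 1 ; sequence P1 ; percent 85.0 ; protein_length 100\n"
        "T1\texonerate:protein2genome:local\texon\t3\t26\t.\t+\t.\tinsertions 0\n"
    )
    (rec,) = fio.read_exonerate_gff(p)
    assert rec.blocks == (ExonBlock(2, 26),)
    assert rec.percent == 85.0


def test_gff2_early_stop_detected_by_translation(tmp_path):
    # CDS ATG TAA GCT TAA has an internal stop
    t = Transcript("T1", "ATGTAAGCTTAA")
    p = tmp_path / "a.gff2"
    p.write_text(
        "T1\texonerate\tgene\t1\t12\t100\t+\t.\tsequence P1 ; protein_length 4\n"
        "T1\texonerate\texon\t1\t12\t.\t+\t.\t\n"
    )
    (rec,) = fio.read_exonerate_gff(p, {"T1": t})
    assert rec.earlystop_flag


def test_gff2_frameshift_detected_from_block_arithmetic(tmp_path):
    p = tmp_path / "a.gff2"
    p.write_text(
        "T1\texonerate\tgene\t1\t13\t100\t+\t.\tsequence P1\n"
        "T1\texonerate\texon\t1\t13\t.\t+\t.\t\n"  # 13 nt, not 0 mod 3
    )
    (rec,) = fio.read_exonerate_gff(p)
    assert rec.frameshift_flag


def test_tsv_and_gff2_readers_agree_on_paired_fixture(tmp_path, noise_free):
    tsv, gff2 = tmp_path / "a.tsv", tmp_path / "a.gff2"
    fio.write_alignment_tsv(noise_free.alignments, tsv)
    fio.write_exonerate_gff(noise_free.alignments, gff2)
    r1 = fio.read_alignment_tsv(tsv)
    r2 = fio.read_exonerate_gff(gff2, noise_free.assembly_a)
    assert r1 == r2


class TestAbinitioReader:
    def test_two_cds_lines_make_one_model(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(
            'T1\tAUGUSTUS\tCDS\t3\t8\t.\t+\t0\ttranscript_id "g1.t1"; gene_id "g1";\n'
            'T1\tAUGUSTUS\tCDS\t21\t26\t.\t+\t0\ttranscript_id "g1.t1"; gene_id "g1";\n'
        )
        (m,) = fio.read_abinitio_gff(p)
        assert m.exons == (ExonBlock(2, 8), ExonBlock(20, 26))
        assert m.source == "abinitio" and m.support == 0

    def test_phase_column_honoured(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text('T1\tAUGUSTUS\tCDS\t3\t11\t.\t+\t2\ttranscript_id "g1.t1";\n')
        (m,) = fio.read_abinitio_gff(p)
        assert m.phase == 2

    def test_minus_strand_phase_taken_from_rightmost_cds(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(
            'T1\tAUGUSTUS\tCDS\t3\t8\t.\t-\t1\ttranscript_id "g1.t1";\n'
            'T1\tAUGUSTUS\tCDS\t21\t26\t.\t-\t2\ttranscript_id "g1.t1";\n'
        )
        (m,) = fio.read_abinitio_gff(p)
        assert m.phase == 2

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("")
        assert fio.read_abinitio_gff(p) == []

    def test_inconsistent_strand_rejected_with_warning(self, tmp_path, caplog):
        p = tmp_path / "a.gff"
        p.write_text(
            'T1\tAUGUSTUS\tCDS\t3\t8\t.\t+\t0\ttranscript_id "g1.t1";\n'
            'T1\tAUGUSTUS\tCDS\t21\t26\t.\t-\t0\ttranscript_id "g1.t1";\n'
        )
        with caplog.at_level("WARNING"):
            assert fio.read_abinitio_gff(p) == []
        assert "inconsistent strand" in caplog.text


def _random_models(rng, n):
    models = []
    for i in range(n):
        tid = f"T{rng.integers(0, 5)}"
        nx = int(rng.integers(1, 4))
        exons, pos = [], int(rng.integers(0, 50))
        for _ in range(nx):
            length = int(rng.integers(3, 120))
            exons.append(ExonBlock(pos, pos + length))
            pos += length + int(rng.integers(10, 200))
        models.append(
            GeneModel(
                id=f"m{i}",
                transcript_id=tid,
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
                phase=int(rng.integers(0, 3)),
                has_start=bool(rng.random() < 0.5),
                has_stop=bool(rng.random() < 0.5),
                source=["evidence", "merged", "abinitio"][int(rng.integers(0, 3))],
                support=int(rng.integers(0, 9)),
                score=float(round(rng.uniform(0, 900), 3)),
                evidence_ids=tuple(f"p{j}" for j in range(int(rng.integers(0, 3)))),
            )
        )
    return models


def test_gff3_round_trip_is_lossless_on_randomized_model_sets(tmp_path):
    rng = np.random.default_rng(0)
    for trial in range(100):
        models = _random_models(rng, int(rng.integers(1, 12)))
        path = tmp_path / f"rt{trial}.gff3"
        fio.write_gff3(models, path)
        assert fio.read_gff3(path) == models


def test_gff3_coordinates_are_one_based_inclusive(tmp_path):
    m = GeneModel("g1", "T1", "+", (ExonBlock(2, 8),))
    path = tmp_path / "x.gff3"
    fio.write_gff3([m], path)
    cds_line = [l for l in path.read_text().splitlines() if "\tCDS\t" in l][0]
    assert cds_line.split("\t")[3:5] == ["3", "8"]


def test_gff3_minus_strand_phases_walk_three_prime_to_five_prime(tmp_path):
    # minus-strand model: 5' exon is the rightmost; phase propagates leftward
    m = GeneModel("g1", "T1", "-", (ExonBlock(0, 4), ExonBlock(10, 17)), phase=0)
    path = tmp_path / "x.gff3"
    fio.write_gff3([m], path)
    lines = [l.split("\t") for l in path.read_text().splitlines() if "\tCDS\t" in l]
    phases = {(int(f[3]), int(f[4])): int(f[7]) for f in lines}
    assert phases[(11, 17)] == 0  # 5'-most part carries the model phase
    assert phases[(1, 4)] == (3 - (7 - 0) % 3) % 3 == 2


def test_gff3_duplicate_ids_are_a_hard_error(tmp_path):
    m = GeneModel("g1", "T1", "+", (ExonBlock(2, 8),))
    with pytest.raises(ValueError, match="duplicate"):
        fio.write_gff3([m, m], tmp_path / "x.gff3")


class TestVcf:
    def _write(self, tmp_path, body):
        p = tmp_path / "x.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "##contig=<ID=T1,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + body
        )
        return p

    def test_snp_position_is_zero_based(self, tmp_path):
        p = self._write(tmp_path, "T1\t10\t.\tA\tG\t50\tPASS\tDP=9\n")
        (v,) = fio.read_vcf(p)
        assert (v.pos, v.ref, v.alt, v.vtype, v.depth) == (9, "A", "G", "SNP", 9)

    def test_deletion_type(self, tmp_path):
        p = self._write(tmp_path, "T1\t10\t.\tAT\tA\t50\tPASS\tDP=9\n")
        (v,) = fio.read_vcf(p)
        assert v.vtype == "DEL"

    def test_multiallelic_site_split(self, tmp_path):
        p = self._write(tmp_path, "T1\t10\t.\tA\tG,C\t50\tPASS\tDP=9\n")
        vs = fio.read_vcf(p)
        assert [v.alt for v in vs] == ["G", "C"]
        assert all(v.vtype == "SNP" for v in vs)

    def test_unknown_chrom_dropped_with_warning(self, tmp_path, caplog):
        p = self._write(tmp_path, "TX\t10\t.\tA\tG\t50\tPASS\tDP=9\n")
        with caplog.at_level("WARNING"):
            assert fio.read_vcf(p, {"T1": Transcript("T1", "A" * 100)}) == []

    def test_record_count_is_site_times_alt(self, tmp_path, noise_free):
        p = tmp_path / "planted.vcf"
        fio.write_vcf(
            (pv.record for pv in noise_free.variants), noise_free.assembly_a, p
        )
        assert len(fio.read_vcf(p)) == len(noise_free.variants)
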