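"""Synthetic fixture generator with known ground truth.

Emulates the structures a de novo transcriptome assembly presents to a
structural annotator: transcripts carrying a single protein-coding gene with
UTRs, a fraction of them with one or more *retained* GT..AG introns
interrupting the CDS, some truncated at either end (partial genes), and
non-coding decoy transcripts. For each coding gene it fabricates the inputs
the pipeline consumes — spliced protein-alignment records (true exon blocks
with terminal boundary jitter, mutated evidence proteins), ab initio models
(truth perturbed by truncation / omission / spurious calls) — plus a paired
second assembly with planted SNPs/InDels, half of which sit inside diverged
flank zones so that flank confirmation has guaranteed negatives.

Planted introns disrupt the reading frame (length forced to != 0 mod 3) and
land in the middle 20–80% of the CDS: a frame-preserving, stop-free retained
intron would be read through silently by six-frame translation, which is not
the failure mode this generator exists to exercise, and real retained introns
overwhelmingly do disrupt the frame. Default lengths loosely mirror a typical
plant transcriptome (intron ~60–500 bp, exon ~300–900 bp) without claiming to
reproduce any particular dataset.

Identical parameters + seed give byte-identical fixture files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import formats_io, seqcore
from .evaluator import QueryRegion, _codon_set, evaluate_gene_set
from .formats_io import ProteinAlignmentRecord, VariantRecord
from .seqcore import (
    CODON_TABLE,
    START_CODON,
    STOP_CODONS,
    ExonBlock,
    GeneModel,
    Transcript,
    cds_of,
    revcomp,
    translate,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)
_STOPS = sorted(STOP_CODONS)
_AA = sorted(set(CODON_TABLE.values()))


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated assembly (defaults = noisy preset)."""

    n_transcripts: int = 500
    gene_probability: float = 0.7
    intron_retention_rate: float = 0.3
    introns_per_gene: tuple[int, int] = (1, 2)
    intron_length: tuple[int, int] = (60, 500)
    cds_length: tuple[int, int] = (360, 1500)
    partial5_rate: float = 0.05
    partial3_rate: float = 0.05
    minus_strand_rate: float = 0.5
    utr_length: tuple[int, int] = (30, 300)
    n_evidence_proteins: tuple[int, int] = (2, 4)
    evidence_dropout: float = 0.15
    protein_mutation_rate: float = 0.02
    alignment_boundary_jitter: int = 6
    abinitio_shift_rate: float = 0.05
    abinitio_miss_rate: float = 0.1
    abinitio_spurious_rate: float = 0.05
    snp_rate: float = 0.3
    indel_rate: float = 0.1
    diverged_flank_zone_rate: float = 0.5
    flank_k: int = 50
    seed: int = 7

    def __post_init__(self) -> None:
        for name in (
            "gene_probability",
            "intron_retention_rate",
            "partial5_rate",
            "partial3_rate",
            "minus_strand_rate",
            "evidence_dropout",
            "protein_mutation_rate",
            "abinitio_shift_rate",
            "abinitio_miss_rate",
            "abinitio_spurious_rate",
            "diverged_flank_zone_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cds_length[0] < 6:
            raise ValueError("cds_length lower bound must allow ATG + stop")


PRESETS: dict[str, SimParams] = {
    "default": SimParams(),
    "noise-free": SimParams(
        n_transcripts=200,
        protein_mutation_rate=0.0,
        alignment_boundary_jitter=0,
        abinitio_shift_rate=0.0,
        abinitio_miss_rate=0.0,
        abinitio_spurious_rate=0.0,
        seed=42,
    ),
    "hard": SimParams(
        intron_retention_rate=0.5,
        protein_mutation_rate=0.05,
        alignment_boundary_jitter=12,
        abinitio_shift_rate=0.1,
        abinitio_miss_rate=0.2,
        abinitio_spurious_rate=0.1,
        seed=13,
    ),
}


@dataclass(frozen=True)
class PlantedVariant:
    record: VariantRecord
    region: str  # truth label: exon | intron | others
    flank_conserved: bool


@dataclass
class TruthSet:
    """Ground truth for one simulated pair of assemblies."""

    params: SimParams
    transcripts_a: list[Transcript]
    transcripts_b: list[Transcript]
    true_models: list[GeneModel]
    introns: dict[str, list[tuple[int, int]]]
    variants: list[PlantedVariant]
    alignments: list[ProteinAlignmentRecord]
    abinitio: list[GeneModel]

    @property
    def assembly_a(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts_a}

    @property
    def assembly_b(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts_b}


# ---------------------------------------------------------------------------
# sequence fabrication
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, lo: int, hi: int) -> str:
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    n_codons = max(n_codons, 2)
    body = rng.choice(_NONSTOP_CODONS, n_codons - 2)
    stop = _STOPS[rng.integers(0, 3)]
    return START_CODON + "".join(body) + stop

def _random_intron(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    if n % 3 == 0:
        n += 1  # frame-disrupting by construction
    return "GT" + _random_dna(rng, n - 4) + "AG"


def _mutate_protein(rng: np.random.Generator, prot: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return prot, 0
    out = list(prot)
    n_mut = 0
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _AA[rng.integers(0, len(_AA))]
            n_mut += 1
    return "".join(out), n_mut


@dataclass
class _Gene:
    """Internal bookkeeping for one simulated coding transcript."""

    tid: str
    gid: str
    strand: str
    mrna_exons: list[tuple[int, int]]  # CDS pieces in mRNA(+) coords
    introns: list[tuple[int, int]]
    cds: str  # spliced CDS actually present (incl. stop when not partial3)
    has_start: bool
    has_stop: bool
    length: int  # transcript length


def _build_coding_transcript(rng: np.random.Generator, p: SimParams, idx: int):
    tid = f"T{idx:04d}"
    gid = f"g{idx:04d}"
    cds = _random_cds(rng, *p.cds_length)
    L = len(cds)

    partial5 = rng.random() < p.partial5_rate
    partial3 = (not partial5) and rng.random() < p.partial3_rate

    # retained introns, inserted in the middle 20-80% of the CDS
    introns_seq: list[str] = []
    cut_points: list[int] = []
    if rng.random() < p.intron_retention_rate:
        k = int(rng.integers(p.introns_per_gene[0], p.introns_per_gene[1] + 1))
        lo, hi = int(0.2 * L), int(0.8 * L)
        tries = 0
        while len(cut_points) < k and tries < 50:
            c = int(rng.integers(lo, hi))
            if all(abs(c - o) >= 30 for o in cut_points):
                cut_points.append(c)
            tries += 1
        cut_points.sort()
        introns_seq = [_random_intron(rng, *p.intron_length) for _ in cut_points]

    # 5' truncation (partial genes): drop a prefix of the CDS
    drop5 = 0
    if partial5:
        drop5 = int(rng.integers(9, max(10, int(0.15 * L))))
        drop5 += (3 - drop5 % 3) % 3  # cut on a codon boundary
        cut_points = [c for c in cut_points if c > drop5 + 30]
        introns_seq = introns_seq[: len(cut_points)]
    drop3 = 0
    if partial3:
        drop3 = int(rng.integers(9, max(10, int(0.15 * L))))
        drop3 += (3 - drop3 % 3) % 3
        cut_points = [c for c in cut_points if c < L - drop3 - 30]
        introns_seq = introns_seq[: len(cut_points)]

    cds_present = cds[drop5 : L - drop3]

    utr5 = "" if partial5 else _random_dna(rng, int(rng.integers(*p.utr_length)))
    if utr5 and len(utr5) >= 3:
        # in-frame stop immediately upstream of ATG: anchors the true ORF
        utr5 = utr5[:-3] + _STOPS[rng.integers(0, 3)]
    utr3 = "" if partial3 else _random_dna(rng, int(rng.integers(*p.utr_length)))

    # assemble mRNA(+): utr5 + cds pieces with introns at cut points
    pieces: list[str] = [utr5]
    exons: list[tuple[int, int]] = []
    pos = len(utr5)
    prev = drop5
    for c, iseq in zip(cut_points, introns_seq):
        seg = cds[prev:c]
        pieces.append(seg)
        exons.append((pos, pos + len(seg)))
        pos += len(seg)
        pieces.append(iseq)
        pos += len(iseq)
        prev = c
    seg = cds[prev : L - drop3]
    pieces.append(seg)
    exons.append((pos, pos + len(seg)))
    pos += len(seg)
    pieces.append(utr3)
    seq = "".join(pieces)

    strand = "-" if rng.random() < p.minus_strand_rate else "+"
    n = len(seq)
    if strand == "-":
        seq = revcomp(seq)
        exons = [(n - e, n - s) for s, e in exons][::-1]

    # flags from content: a truncated CDS may still happen to start with ATG
    has_start, has_stop = seqcore.infer_completeness(cds_present, 0)
    gene = _Gene(
        tid=tid,
        gid=gid,
        strand=strand,
        mrna_exons=exons,
        introns=[
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        ],
        cds=cds_present,
        has_start=has_start,
        has_stop=has_stop,
        length=n,
    )
    return Transcript(tid, seq), gene, cds


def _truth_model(g: _Gene) -> GeneModel:
    return GeneModel(
        id=g.gid,
        transcript_id=g.tid,
        strand=g.strand,
        exons=tuple(ExonBlock(s, e) for s, e in g.mrna_exons),
        phase=0,
        has_start=g.has_start,
        has_stop=g.has_stop,
        source="truth",
    )


def _evidence_for(
    rng: np.random.Generator, p: SimParams, g: _Gene, full_cds: str
) -> list[ProteinAlignmentRecord]:
    """Spliced alignment records: true blocks, jittered terminal boundaries."""
    prot_full = translate(full_cds)[:-1]  # reference protein, stop removed
    plen = len(prot_full)

    # blocks actually alignable: CDS present on the transcript, minus stop
    blocks = [list(b) for b in g.mrna_exons]
    if g.has_stop:
        if g.strand == "+":
            blocks[-1][1] -= 3
        else:
            blocks[0][0] += 3
    aligned_aa_full = sum(e - s for s, e in blocks) // 3

    out = []
    n_prot = int(rng.integers(p.n_evidence_proteins[0], p.n_evidence_proteins[1] + 1))
    jmax = p.alignment_boundary_jitter // 3
    for j in range(n_prot):
        bl = [list(b) for b in blocks]
        u = int(rng.integers(0, jmax + 1)) if jmax else 0
        v = int(rng.integers(0, jmax + 1)) if jmax else 0
        if g.strand == "+":
            bl[0][0] += 3 * u
            bl[-1][1] -= 3 * v
        else:
            bl[-1][1] -= 3 * u
            bl[0][0] += 3 * v
        _, n_mut = _mutate_protein(rng, prot_full, p.protein_mutation_rate)
        aligned_aa = aligned_aa_full - u - v
        percent = max(30.0, 100.0 * (1 - n_mut / max(plen, 1)))
        out.append(
            ProteinAlignmentRecord(
                protein_id=f"{g.gid}.p{j + 1}",
                protein_length=plen,
                transcript_id=g.tid,
                strand=g.strand,
                blocks=tuple(ExonBlock(s, e) for s, e in bl),
                phase=0,
                percent=round(percent, 1),
                raw_score=float(round(aligned_aa * 2 * percent / 100.0)),
                frameshift_flag=False,
                earlystop_flag=False,
            )
        )
    return out


def _abinitio_for(
    rng: np.random.Generator, p: SimParams, g: _Gene
) -> GeneModel | None:
    if rng.random() < p.abinitio_miss_rate:
        return None
    exons = [list(b) for b in g.mrna_exons]
    if rng.random() < p.abinitio_shift_rate:
        # truncation error: shrink one terminal exon by 1-3 codons
        d = 3 * int(rng.integers(1, 4))
        if rng.random() < 0.5:
            exons[0][0] += d
        else:
            exons[-1][1] -= d
    model = GeneModel(
        id=f"{g.tid}.ab1",
        transcript_id=g.tid,
        strand=g.strand,
        exons=tuple(ExonBlock(s, e) for s, e in exons),
        phase=0,
        source="abinitio",
    )
    return model


def _spurious_abinitio(
    rng: np.random.Generator, t: Transcript, k: int
) -> GeneModel | None:
    if t.length < 180:
        return None
    span = 3 * int(rng.integers(50, min(150, t.length // 3)))
    start = int(rng.integers(0, t.length - span + 1))
    return GeneModel(
        id=f"{t.id}.ab1",
        transcript_id=t.id,
        strand="+" if rng.random() < 0.5 else "-",
        exons=(ExonBlock(start, start + span),),
        phase=0,
        source="abinitio",
    )


# ---------------------------------------------------------------------------
# variants and the second assembly
# ---------------------------------------------------------------------------

def _truth_region(g: _Gene | None, lo: int, hi: int) -> str:
    if g is None:
        return "others"
    if any(lo < e and s < hi for s, e in g.mrna_exons):
        return "exon"
    if g.mrna_exons[0][0] < hi and lo < g.mrna_exons[-1][1]:
        return "intron"
    return "others"


def _plant_variants(
    rng: np.random.Generator,
    p: SimParams,
    transcripts: Sequence[Transcript],
    genes: Mapping[str, _Gene],
) -> list[PlantedVariant]:
    n_snp = round(p.snp_rate * p.n_transcripts)
    n_indel = round(p.indel_rate * p.n_transcripts)
    k = p.flank_k
    spacing = 2 * k + 12
    occupied: dict[str, list[tuple[int, int]]] = {t.id: [] for t in transcripts}
    planted: list[PlantedVariant] = []
    want = ["SNP"] * n_snp + ["INS", "DEL"] * (n_indel // 2) + (
        ["INS"] if n_indel % 2 else []
    )
    tries = 0
    for vtype in want:
        placed = False
        while not placed and tries < 100 * len(want):
            tries += 1
            t = transcripts[int(rng.integers(0, len(transcripts)))]
            max_ref = 4 if vtype == "DEL" else 1
            if t.length < 2 * k + max_ref + 20:
                continue
            pos = int(rng.integers(k + 4, t.length - k - max_ref - 4))
            span = (pos - spacing, pos + max_ref + spacing)
            if any(a < span[1] and span[0] < b for a, b in occupied[t.id]):
                continue
            if vtype == "SNP":
                ref = t.seq[pos]
                if "N" in ref:
                    continue
                alt = str(
                    rng.choice([b for b in "ACGT" if b != ref])
                )
            elif vtype == "INS":
                ref = t.seq[pos]
                alt = ref + _random_dna(rng, int(rng.integers(1, 4)))
            else:
                d = int(rng.integers(1, 4))
                ref = t.seq[pos : pos + 1 + d]
                alt = ref[0]
            rec = VariantRecord(
                transcript_id=t.id,
                pos=pos,
                ref=ref,
                alt=alt,
                vtype=vtype,
                depth=int(rng.integers(5, 120)),
                qual=float(round(rng.uniform(20, 60), 1)),
            )
            region = _truth_region(genes.get(t.id), pos, pos + len(ref))
            planted.append(PlantedVariant(rec, region, True))
            occupied[t.id].append((pos, pos + len(ref)))
            placed = True
    # mark a deterministic fraction as diverged-flank
    n_div = round(p.diverged_flank_zone_rate * len(planted))
    order = rng.permutation(len(planted))
    diverged = set(order[:n_div].tolist())
    planted = [
        PlantedVariant(pv.record, pv.region, i not in diverged)
        for i, pv in enumerate(planted)
    ]
    return planted


def _mutate_zone(rng: np.random.Generator, seg: str) -> str:
    """~10% substitutions, at least one, anywhere in the window."""
    out = list(seg)
    changed = False
    for i in range(len(out)):
        if rng.random() < 0.1:
            alts = [b for b in "ACGT" if b != out[i]]
            out[i] = alts[int(rng.integers(0, 3))]
            changed = True
    if not changed and out:
        i = len(out) // 2
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[int(rng.integers(0, 3))]
    return "".join(out)


def _build_assembly_b(
    rng: np.random.Generator,
    p: SimParams,
    transcripts: Sequence[Transcript],
    planted: Sequence[PlantedVariant],
) -> list[Transcript]:
    by_tid: dict[str, list[PlantedVariant]] = {}
    for pv in planted:
        by_tid.setdefault(pv.record.transcript_id, []).append(pv)
    k = p.flank_k
    out = []
    for t in transcripts:
        pvs = sorted(by_tid.get(t.id, []), key=lambda pv: pv.record.pos)
        if not pvs:
            out.append(Transcript(t.id, t.seq))
            continue
        chunks: list[str] = []
        cur = 0
        for pv in pvs:
            v = pv.record
            seg = t.seq[cur : v.pos]
            if not pv.flank_conserved:
                head, zone = seg[: max(0, len(seg) - k)], seg[max(0, len(seg) - k) :]
                seg = head + _mutate_zone(rng, zone)
            chunks.append(seg)
            chunks.append(v.alt)
            cur = v.pos + len(v.ref)
            if not pv.flank_conserved:
                zone = t.seq[cur : cur + k]
                chunks.append(_mutate_zone(rng, zone))
                cur += len(zone)
        chunks.append(t.seq[cur:])
        out.append(Transcript(t.id, "".join(chunks)))
    return out


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate(params: SimParams | None = None, **overrides) -> TruthSet:
    """Generate a full paired-assembly fixture with known truth."""
    p = params or SimParams()
    if overrides:
        p = dataclasses.replace(p, **overrides)
    rng = np.random.default_rng(p.seed)
    transcripts: list[Transcript] = []
    genes: dict[str, _Gene] = {}
    true_models: list[GeneModel] = []
    introns: dict[str, list[tuple[int, int]]] = {}
    alignments: list[ProteinAlignmentRecord] = []
    abinitio: list[GeneModel] = []
    for i in range(1, p.n_transcripts + 1):
        if rng.random() < p.gene_probability:
            t, g, full_cds = _build_coding_transcript(rng, p, i)
            transcripts.append(t)
            genes[t.id] = g
            model = _truth_model(g)
            seqcore.validate_model(model, t)
            true_models.append(model)
            introns[g.gid] = g.introns
            if rng.random() >= p.evidence_dropout:
                alignments.extend(_evidence_for(rng, p, g, full_cds))
            ab = _abinitio_for(rng, p, g)
            if ab is not None:
                abinitio.append(ab)
        else:
            t = Transcript(
                f"T{i:04d}", _random_dna(rng, int(rng.integers(400, 2000)))
            )
            transcripts.append(t)
            if rng.random() < p.abinitio_spurious_rate:
                sp = _spurious_abinitio(rng, t, p.flank_k)
                if sp is not None:
                    abinitio.append(sp)
    planted = _plant_variants(rng, p, transcripts, genes)
    transcripts_b = _build_assembly_b(rng, p, transcripts, planted)
    return TruthSet(
        params=p,
        transcripts_a=transcripts,
        transcripts_b=transcripts_b,
        true_models=true_models,
        introns=introns,
        variants=planted,
        alignments=alignments,
        abinitio=abinitio,
    )


def write_fixture(truth: TruthSet, outdir) -> dict[str, Path]:
    """Write every pipeline input (plus the truth) as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assembly_a": outdir / "assemblyA.fa",
        "assembly_b": outdir / "assemblyB.fa",
        "evidence_tsv": outdir / "evidence.tsv",
        "evidence_gff2": outdir / "evidence.gff2",
        "abinitio": outdir / "abinitio.gff",
        "queries": outdir / "queries.gff",
        "vcf": outdir / "planted.vcf",
        "truth": outdir / "truth.gff3",
        "manifest": outdir / "manifest.json",
    }
    seqcore.write_fasta(((t.id, t.seq) for t in truth.transcripts_a), paths["assembly_a"])
    seqcore.write_fasta(((t.id, t.seq) for t in truth.transcripts_b), paths["assembly_b"])
    formats_io.write_alignment_tsv(truth.alignments, paths["evidence_tsv"])
    formats_io.write_exonerate_gff(truth.alignments, paths["evidence_gff2"])
    formats_io.write_abinitio_gtf(truth.abinitio, paths["abinitio"])
    queries = [
        a
        for a in truth.alignments
        if a.percent >= 70 and a.query_cov >= 0.9
        and not (a.frameshift_flag or a.earlystop_flag)
    ]
    formats_io.write_exonerate_gff(queries, paths["queries"])
    formats_io.write_vcf(
        (pv.record for pv in truth.variants), truth.assembly_a, paths["vcf"]
    )
    formats_io.write_gff3(truth.true_models, paths["truth"])
    manifest = {
        "params": dataclasses.asdict(truth.params),
        "files": sorted(k for k in paths if k != "manifest"),
        "n_true_models": len(truth.true_models),
        "n_variants": len(truth.variants),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return paths


def from_manifest(path) -> TruthSet:
    """Deterministically regenerate a fixture from its manifest."""
    manifest = json.loads(Path(path).read_text())
    params = manifest["params"]
    for key in ("introns_per_gene", "intron_length", "cds_length",
                "utr_length", "n_evidence_proteins"):
        params[key] = tuple(params[key])
    return simulate(SimParams(**params))


# ---------------------------------------------------------------------------
# truth-based scoring
# ---------------------------------------------------------------------------

def exact_cds_recovery(
    truth: TruthSet, predicted: Sequence[GeneModel]
) -> tuple[float, int]:
    """Fraction of true models whose exact CDS appears in the prediction."""
    asm = truth.assembly_a
    by_tid: dict[str, list[GeneModel]] = {}
    for m in predicted:
        by_tid.setdefault(m.transcript_id, []).append(m)
    hit = 0
    for tm in truth.true_models:
        want = cds_of(tm, asm[tm.transcript_id])
        found = any(
            m.strand == tm.strand
            and cds_of(m, asm[m.transcript_id]) == want
            for m in by_tid.get(tm.transcript_id, [])
        )
        hit += found
    n = len(truth.true_models)
    return (hit / n if n else 1.0), n


def junction_recovery(
    truth: TruthSet, predicted: Sequence[GeneModel]
) -> tuple[float, int]:
    """Fraction of true models whose full junction set is predicted exactly
    (with span overlap, so single-exon truths must be hit in place)."""
    by_tid: dict[str, list[GeneModel]] = {}
    for m in predicted:
        by_tid.setdefault(m.transcript_id, []).append(m)
    hit = 0
    for tm in truth.true_models:
        found = any(
            m.strand == tm.strand
            and m.junctions() == tm.junctions()
            and m.span_overlaps(tm)
            for m in by_tid.get(tm.transcript_id, [])
        )
        hit += found
    n = len(truth.true_models)
    return (hit / n if n else 1.0), n


def truth_queries(
    truth: TruthSet, only_retained_intron: bool = False
) -> list[QueryRegion]:
    """True gene structures expressed as evaluator query regions."""
    out = []
    for tm in truth.true_models:
        if only_retained_intron and not tm.multiexon:
            continue
        out.append(
            QueryRegion(
                query_id=f"truth:{tm.id}",
                protein_id=tm.id,
                transcript_id=tm.transcript_id,
                strand=tm.strand,
                blocks=tm.exons,
                phase=tm.phase,
                multiexon=tm.multiexon,
                codon_set=_codon_set(tm.transcript_id, tm.strand, tm.exons, tm.phase),
            )
        )
    return out


def represented_fraction(
    truth: TruthSet,
    genes: Sequence[GeneModel],
    only_retained_intron: bool = False,
    threshold: float = 0.99,
) -> tuple[float, int]:
    """Fraction of true genes represented (codon coverage >= threshold)."""
    queries = truth_queries(truth, only_retained_intron)
    results = evaluate_gene_set(queries, genes, threshold)
    n = len(queries)
    rep = sum(r.represented for r in results)
    return (rep / n if n else 1.0), n


__all__ = [
    "SimParams",
    "PRESETS",
    "PlantedVariant",
    "TruthSet",
    "simulate",
    "write_fixture",
    "from_manifest",
    "exact_cds_recovery",
    "junction_recovery",
    "truth_queries",
    "represented_fraction",
]
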