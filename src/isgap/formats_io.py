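"""Readers and writers for every external format the pipeline touches.

Dialects handled:

* **Alignment TSV** — one spliced protein-to-transcript alignment per line,
  tab-separated::

      protein_id  protein_length  transcript_id  strand  percent  raw_score \
      blocks  phase  frameshift  earlystop

  ``blocks`` is a semicolon-separated list of 0-based half-open
  ``start-end`` intervals in transcript coordinates; the two flag columns
  use ``-`` for false and ``+`` for true. Lines starting with ``#`` are
  comments. This dialect exists so the pipeline is testable without
  Exonerate installed.
* **Exonerate GFF2** (``--showtargetgff``): per alignment a ``gene`` feature
  carrying the query id and raw score plus ``exon`` features. Extra
  free-form attributes ``percent``, ``protein_length`` and ``phase`` are
  honoured when present (Exonerate's own GFF omits the percent score).
  Frameshifts are detected from block lengths inconsistent with a single
  reading frame; early stops by translating the implied CDS when transcript
  sequences are supplied.
* **Augustus GFF/GTF** — ``CDS`` features grouped by their transcript
  attribute (GTF ``transcript_id "x"`` or GFF3-style ``Parent=``/``ID=``),
  phase column honoured.
* **GFF3 output** — gene -> mRNA -> CDS hierarchy, seqid = transcript id,
  1-based inclusive coordinates, phases computed walking 5'->3' in gene
  orientation, with ``isgap_source`` / ``isgap_support`` /
  ``isgap_completeness`` custom attributes. ``read_gff3(write_gff3(M)) == M``.
* **VCF 4.x** — CHROM is a transcript id; multi-allelic sites are split into
  one record per ALT.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import seqcore
from .seqcore import (
    ExonBlock,
    GeneModel,
    StructuralError,
    Transcript,
    cds_of,
    infer_completeness,
    translate,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinAlignmentRecord:
    """One spliced alignment of a reference protein onto a transcript."""

    protein_id: str
    protein_length: int
    transcript_id: str
    strand: str
    blocks: tuple[ExonBlock, ...]
    phase: int = 0
    percent: float = 100.0
    raw_score: float = 0.0
    frameshift_flag: bool = False
    earlystop_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.strand not in ("+", "-"):
            raise StructuralError(f"bad strand {self.strand!r}")
        if not (0.0 <= self.percent <= 100.0):
            raise StructuralError(f"percent {self.percent} outside [0, 100]")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise StructuralError(f"blocks unsorted/overlapping: {a}, {b}")

    @property
    def aligned_nt(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def query_cov(self) -> float:
        """Fraction of protein residues aligned, computed from block lengths."""
        if self.protein_length <= 0:
            return 1.0
        return min(1.0, (self.aligned_nt - self.phase) / 3 / self.protein_length)


@dataclass(frozen=True)
class VariantRecord:
    """A SNP/insertion/deletion at a transcript position (0-based)."""

    transcript_id: str
    pos: int
    ref: str
    alt: str
    vtype: str
    depth: int = -1
    qual: float = 0.0

    def __post_init__(self) -> None:
        expected = (
            "SNP"
            if len(self.ref) == len(self.alt) == 1
            else "INS"
            if len(self.alt) > len(self.ref)
            else "DEL"
        )
        if self.vtype != expected:
            raise StructuralError(
                f"vtype {self.vtype} inconsistent with REF/ALT lengths "
                f"({self.ref!r}/{self.alt!r})"
            )

    @property
    def ref_span(self) -> tuple[int, int]:
        return (self.pos, self.pos + len(self.ref))


def _detect_frameshift(rec: ProteinAlignmentRecord) -> bool:
    """Block lengths inconsistent with one reading frame across splices.

    A clean protein alignment covers whole codons after the phase offset,
    so the spliced length minus phase must be divisible by 3.
    """
    return (rec.aligned_nt - rec.phase) % 3 != 0


def _detect_earlystop(
    rec: ProteinAlignmentRecord, transcripts: Mapping[str, Transcript]
) -> bool:
    t = transcripts.get(rec.transcript_id)
    if t is None:
        return False
    model = GeneModel(
        id="tmp",
        transcript_id=rec.transcript_id,
        strand=rec.strand,
        exons=rec.blocks,
        phase=rec.phase,
    )
    prot = translate(cds_of(model, t), rec.phase)
    internal = prot[:-1] if prot.endswith("*") else prot
    return "*" in internal


# ---------------------------------------------------------------------------
# alignment TSV dialect
# ---------------------------------------------------------------------------

_FLAG = {"-": False, "+": True, "F": False, "T": True}


def _parse_blocks(text: str) -> tuple[ExonBlock, ...]:
    blocks = []
    for chunk in text.split(";"):
        s, _, e = chunk.partition("-")
        blocks.append(ExonBlock(int(s), int(e)))
    return tuple(blocks)


def _format_blocks(blocks: Sequence[ExonBlock]) -> str:
    return ";".join(f"{b.start}-{b.end}" for b in blocks)


def read_alignment_tsv(path) -> list[ProteinAlignmentRecord]:
    out: list[ProteinAlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: expected 10 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                rec = ProteinAlignmentRecord(
                    protein_id=fields[0],
                    protein_length=int(fields[1]),
                    transcript_id=fields[2],
                    strand=fields[3],
                    percent=float(fields[4]),
                    raw_score=float(fields[5]),
                    blocks=_parse_blocks(fields[6]),
                    phase=int(fields[7]),
                    frameshift_flag=_FLAG[fields[8]],
                    earlystop_flag=_FLAG[fields[9]],
                )
            except StructuralError as exc:
                logger.warning("%s:%d: record rejected: %s", path, lineno, exc)
                continue
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable line ({exc})")
            out.append(rec)
    return out


def write_alignment_tsv(records: Iterable[ProteinAlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#protein_id\tprotein_length\ttranscript_id\tstrand\tpercent\t"
            "raw_score\tblocks\tphase\tframeshift\tearlystop\n"
        )
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.protein_id,
                        str(r.protein_length),
                        r.transcript_id,
                        r.strand,
                        f"{r.percent:g}",
                        f"{r.raw_score:g}",
                        _format_blocks(r.blocks),
                        str(r.phase),
                        "+" if r.frameshift_flag else "-",
                        "+" if r.earlystop_flag else "-",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Exonerate --showtargetgff GFF2 dialect
# ---------------------------------------------------------------------------

def _gff2_attrs(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_exonerate_gff(
    path, transcripts: Mapping[str, Transcript] | None = None
) -> list[ProteinAlignmentRecord]:
    """Parse Exonerate ``--showtargetgff`` output into alignment records.

    ``transcripts`` (optional, id -> Transcript) enables early-stop detection
    by translation; frameshifts are detected from block arithmetic alone.
    """
    out: list[ProteinAlignmentRecord] = []
    current: dict | None = None

    def _flush() -> None:
        nonlocal current
        if current is None:
            return
        try:
            rec = ProteinAlignmentRecord(
                protein_id=current["protein_id"],
                protein_length=current["protein_length"],
                transcript_id=current["transcript_id"],
                strand=current["strand"],
                percent=current["percent"],
                raw_score=current["raw_score"],
                blocks=tuple(sorted(current["blocks"])),
                phase=current["phase"],
            )
        except StructuralError as exc:
            logger.warning("%s: alignment rejected: %s", path, exc)
            current = None
            return
        fs = _detect_frameshift(rec)
        es = _detect_earlystop(rec, transcripts) if transcripts else False
        if fs or es:
            rec = replace(rec, frameshift_flag=fs, earlystop_flag=es)
        out.append(rec)
        current = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}"
                )
            seqid, _src, ftype, start, end, score, strand, _frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates ({exc})")
            if ftype == "gene":
                _flush()
                a = _gff2_attrs(attrs)
                current = {
                    "protein_id": a.get("sequence", a.get("Query", "?")),
                    "protein_length": int(a.get("protein_length", 0)),
                    "transcript_id": seqid,
                    "strand": strand,
                    "percent": float(a.get("percent", 100.0)),
                    "raw_score": float(score) if score != "." else 0.0,
                    "phase": int(a.get("phase", 0)),
                    "blocks": [],
                }
            elif ftype == "exon":
                if current is None:
                    raise ValueError(f"{path}:{lineno}: exon before any gene feature")
                current["blocks"].append(ExonBlock(start_i - 1, end_i))
            # similarity / cds / splice5 / splice3 / intron features are
            # redundant with the exon list and are skipped.
    _flush()
    return out


def write_exonerate_gff(records: Iterable[ProteinAlignmentRecord], path) -> None:
    """Emit alignments in the Exonerate ``--showtargetgff`` GFF2 dialect."""
    src = "exonerate:protein2genome:local"
    with open(path, "w") as fh:
        fh.write("# --- START OF GFF DUMP ---\n")
        for i, r in enumerate(records, 1):
            start = r.blocks[0].start + 1
            end = r.blocks[-1].end
            attrs = (
                f"gene_id {i} ; sequence {r.protein_id} ; "
                f"gene_orientation {r.strand} ; percent {r.percent:g} ; "
                f"protein_length {r.protein_length} ; phase {r.phase}"
            )
            fh.write(
                f"{r.transcript_id}\t{src}\tgene\t{start}\t{end}\t"
                f"{r.raw_score:g}\t{r.strand}\t.\t{attrs}\n"
            )
            for b in r.blocks:
                fh.write(
                    f"{r.transcript_id}\t{src}\texon\t{b.start + 1}\t{b.end}\t"
                    f".\t{r.strand}\t.\tinsertions 0 ; deletions 0\n"
                )
            fh.write(
                f"{r.transcript_id}\t{src}\tsimilarity\t{start}\t{end}\t"
                f"{r.raw_score:g}\t{r.strand}\t.\t"
                f"alignment_id {i} ; Query {r.protein_id}\n"
            )
        fh.write("# --- END OF GFF DUMP ---\n")


def read_alignments(
    path, transcripts: Mapping[str, Transcript] | None = None
) -> list[ProteinAlignmentRecord]:
    """Auto-detect the alignment dialect (TSV vs Exonerate GFF2) and read."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            ncols = len(line.rstrip("\n").split("\t"))
            if ncols == 9:
                return read_exonerate_gff(path, transcripts)
            return read_alignment_tsv(path)
    return []


# ---------------------------------------------------------------------------
# Augustus-dialect ab initio models
# ---------------------------------------------------------------------------

_GTF_TID = re.compile(r'transcript_id\s+"([^"]+)"')
_GFF_PARENT = re.compile(r"(?:Parent|ID)=([^;]+)")


def read_abinitio_gff(path) -> list[GeneModel]:
    """Group Augustus CDS features by transcript attribute into gene models.

    Completeness flags are provisionally false; they are recomputed from
    sequence by :func:`isgap.integrator.filter_abnormal_abinitio`.
    """
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}"
                )
            seqid, _src, ftype, start, end, _score, strand, frame, attrs = fields
            if ftype != "CDS":
                continue
            m = _GTF_TID.search(attrs) or _GFF_PARENT.search(attrs)
            tid = m.group(1) if m else f"anon{lineno}"
            g = groups.setdefault(
                tid, {"transcript_id": seqid, "strands": set(), "cds": []}
            )
            if g["transcript_id"] != seqid:
                g["strands"].add("CONFLICT")
            g["strands"].add(strand)
            g["cds"].append((int(start) - 1, int(end), 0 if frame == "." else int(frame)))
            if tid not in order:
                order.append(tid)
    models: list[GeneModel] = []
    for tid in order:
        g = groups[tid]
        if len(g["strands"]) != 1:
            logger.warning("%s: model %s rejected: inconsistent strand", path, tid)
            continue
        strand = next(iter(g["strands"]))
        cds = sorted(g["cds"])
        # model phase is the phase of the 5'-most CDS part in gene orientation
        phase = cds[0][2] if strand == "+" else cds[-1][2]
        try:
            models.append(
                GeneModel(
                    id=tid,
                    transcript_id=g["transcript_id"],
                    strand=strand,
                    exons=tuple(ExonBlock(s, e) for s, e, _ in cds),
                    phase=phase,
                    source="abinitio",
                    support=0,
                )
            )
        except StructuralError as exc:
            logger.warning("%s: model %s rejected: %s", path, tid, exc)
    return models


def write_abinitio_gtf(models: Iterable[GeneModel], path) -> None:
    """Emit models in the Augustus GTF dialect (used by the fixture generator)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f"{m.transcript_id}\tAUGUSTUS\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{m.id}\n"
            )
            fh.write(
                f"{m.transcript_id}\tAUGUSTUS\ttranscript\t{m.start + 1}\t{m.end}"
                f"\t.\t{m.strand}\t.\t{m.id}.t1\n"
            )
            for block, phase in zip(m.exons, _cds_phases(m)):
                fh.write(
                    f"{m.transcript_id}\tAUGUSTUS\tCDS\t{block.start + 1}\t"
                    f"{block.end}\t.\t{m.strand}\t{phase}\t"
                    f'transcript_id "{m.id}.t1"; gene_id "{m.id}";\n'
                )


# ---------------------------------------------------------------------------
# GFF3 output
# ---------------------------------------------------------------------------

def _cds_phases(model: GeneModel) -> list[int]:
    """GFF phase of each exon block, in forward (file) order.

    Phase = bases to skip at the feature's 5' (gene-orientation) edge to hit
    the next complete codon, walking the CDS 5'->3' in gene orientation.
    """
    order = model.exons if model.strand == "+" else model.exons[::-1]
    phases: list[int] = []
    consumed = 0
    for e in order:
        if consumed == 0:
            phases.append(model.phase)
        else:
            phases.append((3 - ((consumed - model.phase) % 3)) % 3)
        consumed += len(e)
    return phases if model.strand == "+" else phases[::-1]


def _completeness_tag(model: GeneModel) -> str:
    if model.has_start and model.has_stop:
        return "complete"
    if model.has_stop:
        return "partial5"
    if model.has_start:
        return "partial3"
    return "internal"


_TAG_FLAGS = {
    "complete": (True, True),
    "partial5": (False, True),
    "partial3": (True, False),
    "internal": (False, False),
}


def write_gff3(models: Iterable[GeneModel], path) -> None:
    """gene -> mRNA -> CDS hierarchy; 1-based inclusive coordinates."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            if m.id in seen:
                raise ValueError(f"duplicate model id {m.id!r}")
            seen.add(m.id)
            attrs = (
                f"ID={m.id};isgap_source={m.source};isgap_support={m.support};"
                f"isgap_completeness={_completeness_tag(m)};isgap_phase={m.phase}"
            )
            if m.evidence_ids:
                attrs += f";isgap_evidence={','.join(m.evidence_ids)}"
            fh.write(
                f"{m.transcript_id}\tisgap\tgene\t{m.start + 1}\t{m.end}\t"
                f"{m.score!r}\t{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.transcript_id}\tisgap\tmRNA\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.id}.m;Parent={m.id}\n"
            )
            for i, (block, phase) in enumerate(zip(m.exons, _cds_phases(m)), 1):
                fh.write(
                    f"{m.transcript_id}\tisgap\tCDS\t{block.start + 1}\t{block.end}"
                    f"\t.\t{m.strand}\t{phase}\tID={m.id}.c{i};Parent={m.id}.m\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Read back :func:`write_gff3` output (lossless round trip)."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}"
                )
            seqid, _src, ftype, start, end, score, strand, _phase, attrs = fields
            a = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = a["ID"]
                has_start, has_stop = _TAG_FLAGS[a.get("isgap_completeness", "internal")]
                genes[gid] = {
                    "transcript_id": seqid,
                    "strand": strand,
                    "score": float(score) if score != "." else 0.0,
                    "source": a.get("isgap_source", "evidence"),
                    "support": int(a.get("isgap_support", 0)),
                    "phase": int(a.get("isgap_phase", 0)),
                    "has_start": has_start,
                    "has_stop": has_stop,
                    "evidence_ids": tuple(
                        x for x in a.get("isgap_evidence", "").split(",") if x
                    ),
                    "exons": [],
                }
                order.append(gid)
            elif ftype == "mRNA":
                mrna_to_gene[a["ID"]] = a["Parent"]
            elif ftype == "CDS":
                gid = mrna_to_gene.get(a.get("Parent", ""), a.get("Parent", ""))
                if gid not in genes:
                    raise ValueError(f"{path}:{lineno}: CDS with unknown parent")
                genes[gid]["exons"].append(ExonBlock(int(start) - 1, int(end)))
    out = []
    for gid in order:
        g = genes[gid]
        out.append(
            GeneModel(
                id=gid,
                transcript_id=g["transcript_id"],
                strand=g["strand"],
                exons=tuple(sorted(g["exons"])),
                phase=g["phase"],
                has_start=g["has_start"],
                has_stop=g["has_stop"],
                source=g["source"],
                support=g["support"],
                score=g["score"],
                evidence_ids=g["evidence_ids"],
            )
        )
    return out


def write_cds_fasta(
    models: Iterable[GeneModel], transcripts: Mapping[str, Transcript], path
) -> None:
    seqcore.write_fasta(
        ((m.id, cds_of(m, transcripts[m.transcript_id])) for m in models), path
    )


def write_protein_fasta(
    models: Iterable[GeneModel], transcripts: Mapping[str, Transcript], path
) -> None:
    def _prot(m: GeneModel) -> str:
        p = translate(cds_of(m, transcripts[m.transcript_id]), m.phase)
        return p[:-1] if p.endswith("*") else p

    seqcore.write_fasta(((m.id, _prot(m)) for m in models), path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path, transcripts: Mapping[str, Transcript] | None = None
) -> list[VariantRecord]:
    """Read a VCF; CHROM is a transcript id; multi-allelic sites are split."""
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    for v in VCF(str(path)):
        if transcripts is not None and v.CHROM not in transcripts:
            logger.warning("VCF record on unknown transcript %s dropped", v.CHROM)
            continue
        depth = v.INFO.get("DP")
        depth = int(depth) if depth is not None else -1
        for alt in v.ALT:
            ref, a = v.REF, alt
            vtype = (
                "SNP"
                if len(ref) == len(a) == 1
                else "INS"
                if len(a) > len(ref)
                else "DEL"
            )
            out.append(
                VariantRecord(
                    transcript_id=v.CHROM,
                    pos=v.POS - 1,
                    ref=ref,
                    alt=a,
                    vtype=vtype,
                    depth=depth,
                    qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                )
            )
    return out


def write_vcf(
    variants: Iterable[VariantRecord],
    transcripts: Mapping[str, Transcript],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        for tid, t in transcripts.items():
            fh.write(f"##contig=<ID={tid},length={t.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"DP={v.depth}" if v.depth >= 0 else "."
            fh.write(
                f"{v.transcript_id}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t"
                f"{v.qual:g}\tPASS\t{info}\n"
            )


__all__ = [
    "ProteinAlignmentRecord",
    "VariantRecord",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "read_exonerate_gff",
    "write_exonerate_gff",
    "read_alignments",
    "read_abinitio_gff",
    "write_abinitio_gtf",
    "write_gff3",
    "read_gff3",
    "write_cds_fasta",
    "write_protein_fasta",
    "read_vcf",
    "write_vcf",
]
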