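"""Step 1: protein alignments -> merged, filtered, non-redundant gene models.

Candidate structures come straight from spliced protein alignments (one model
per retained alignment). Structures sharing an identical exon–exon junction
set on the same transcript and strand collapse to a single consensus model;
single-exon structures, which have no junctions, merge when they overlap on
the same transcript/strand in the same reading frame. Models with internal
in-frame stops or frame-inconsistent block arithmetic are removed, and each
overlap cluster keeps only the model with the most evidence proteins (then
the highest mapping score).
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

from .formats_io import ProteinAlignmentRecord
from .seqcore import (
    ExonBlock,
    GeneModel,
    Transcript,
    cds_of,
    infer_completeness,
    replace,
    translate,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_PERCENT = 30.0
DEFAULT_MAX_INTRON = 50_000


from dataclasses import dataclass


@dataclass(frozen=True)
class JunctionKey:
    """Identity under which gene structures are merged.

    Multi-exon structures are keyed by their ordered (donor, acceptor)
    intron boundary pairs; single-exon structures carry a reading-frame tag
    instead (the junction-identity rule is undefined without junctions, so
    frame-compatible overlap is the merge criterion).
    """

    transcript_id: str
    strand: str
    junctions: tuple[tuple[int, int], ...]
    frame: int | None = None

    def __post_init__(self) -> None:
        for d, a in self.junctions:
            if d >= a:
                raise ValueError(f"junction donor {d} not before acceptor {a}")
        if list(self.junctions) != sorted(self.junctions):
            raise ValueError("junction pairs must be sorted")

    @classmethod
    def of(cls, model: GeneModel) -> "JunctionKey":
        if model.multiexon:
            return cls(model.transcript_id, model.strand, model.junctions())
        return cls(
            model.transcript_id,
            model.strand,
            (),
            frame_tag(model.strand, model.exons, model.phase),
        )


def frame_tag(strand: str, exons: Sequence[ExonBlock], phase: int) -> int:
    """Transcript-frame (mod 3) of the model's first complete codon.

    Anchored at the gene-orientation 5' terminus: forward-start for '+',
    forward-end for '-'. Two single-exon models translate the same codons
    over their overlap iff their tags agree.
    """
    if strand == "+":
        return (exons[0].start + phase) % 3
    return (exons[-1].end - phase) % 3


def structures_from_alignments(
    records: Iterable[ProteinAlignmentRecord],
    transcripts: Mapping[str, Transcript],
    min_percent: float = DEFAULT_MIN_PERCENT,
    max_intron: int = DEFAULT_MAX_INTRON,
) -> list[GeneModel]:
    """One candidate gene model per retained alignment (source=evidence)."""
    models: list[GeneModel] = []
    counters = Counter()
    per_tid: Counter = Counter()
    for rec in records:
        if rec.percent < min_percent:
            counters["below_min_percent"] += 1
            continue
        if rec.frameshift_flag or rec.earlystop_flag:
            counters["flagged_invalid"] += 1
            continue
        if rec.transcript_id not in transcripts:
            counters["unknown_transcript"] += 1
            continue
        # coalesce zero-gap blocks, then apply the intron-length ceiling
        blocks: list[ExonBlock] = []
        for b in rec.blocks:
            if blocks and b.start == blocks[-1].end:
                blocks[-1] = ExonBlock(blocks[-1].start, b.end)
            else:
                blocks.append(b)
        gaps = [b.start - a.end for a, b in zip(blocks, blocks[1:])]
        if any(g > max_intron for g in gaps):
            counters["intron_too_long"] += 1
            continue
        t = transcripts[rec.transcript_id]
        if blocks[-1].end > t.length:
            counters["out_of_bounds"] += 1
            continue
        per_tid[rec.transcript_id] += 1
        model = GeneModel(
            id=f"{rec.transcript_id}.ev{per_tid[rec.transcript_id]}",
            transcript_id=rec.transcript_id,
            strand=rec.strand,
            exons=tuple(blocks),
            phase=rec.phase,
            source="evidence",
            support=1,
            score=rec.raw_score,
            evidence_ids=(rec.protein_id,),
        )
        cds = cds_of(model, t)
        hs, he = infer_completeness(cds, model.phase)
        models.append(replace(model, has_start=hs, has_stop=he))
    if counters:
        logger.info("structures_from_alignments dropped: %s", dict(counters))
    return models


def _consensus_boundary(values: Sequence[int], outermost: str) -> int:
    """Majority vote over candidate terminal boundaries; ties -> outermost."""
    counts = Counter(values)
    best = max(counts.values())
    tied = [v for v, c in counts.items() if c == best]
    return min(tied) if outermost == "start" else max(tied)


def _merge_group(
    members: Sequence[GeneModel], transcripts: Mapping[str, Transcript], new_id: str
) -> GeneModel:
    first = members[0]
    start = _consensus_boundary([m.start for m in members], "start")
    end = _consensus_boundary([m.end for m in members], "end")
    exons = list(first.exons)
    exons[0] = ExonBlock(start, exons[0].end) if len(exons) > 1 else ExonBlock(start, end)
    if len(exons) > 1:
        exons[-1] = ExonBlock(exons[-1].start, end)
    # phase follows the member whose 5'-terminal boundary was elected
    if first.strand == "+":
        donor = next(m for m in members if m.start == start)
    else:
        donor = next(m for m in members if m.end == end)
    evidence = tuple(sorted({p for m in members for p in m.evidence_ids}))
    model = GeneModel(
        id=new_id,
        transcript_id=first.transcript_id,
        strand=first.strand,
        exons=tuple(exons),
        phase=donor.phase,
        source="merged",
        support=len(evidence) if evidence else len(members),
        score=sum(m.score for m in members),
        evidence_ids=evidence,
    )
    cds = cds_of(model, transcripts[model.transcript_id])
    hs, he = infer_completeness(cds, model.phase)
    return replace(model, has_start=hs, has_stop=he)


def merge_same_junctions(
    models: Iterable[GeneModel], transcripts: Mapping[str, Transcript]
) -> list[GeneModel]:
    """Collapse structures with identical junction sets into consensus models.

    Terminal boundaries are elected per end by majority over the contributing
    alignments (tie -> outermost boundary); internal junctions are shared by
    construction and never altered. Single-exon structures (no junctions)
    merge when they overlap in the same transcript-frame on the same strand.
    """
    multi: dict[tuple, list[GeneModel]] = defaultdict(list)
    single: dict[tuple, list[GeneModel]] = defaultdict(list)
    for m in models:
        if m.multiexon:
            multi[(m.transcript_id, m.strand, m.junctions())].append(m)
        else:
            tag = frame_tag(m.strand, m.exons, m.phase)
            single[(m.transcript_id, m.strand, tag)].append(m)

    groups: list[list[GeneModel]] = []
    for key in sorted(multi, key=lambda k: (k[0], k[1], k[2])):
        groups.append(multi[key])
    for key in sorted(single):
        # transitive span-overlap clusters within one frame class
        members = sorted(single[key], key=lambda m: (m.start, m.end, m.id))
        cluster: list[GeneModel] = []
        reach = -1
        for m in members:
            if cluster and m.start >= reach:
                groups.append(cluster)
                cluster = []
                reach = -1
            cluster.append(m)
            reach = max(reach, m.end)
        if cluster:
            groups.append(cluster)

    per_tid: Counter = Counter()
    merged: list[GeneModel] = []
    for group in sorted(groups, key=lambda g: (g[0].transcript_id, g[0].start, g[0].id)):
        tid = group[0].transcript_id
        per_tid[tid] += 1
        merged.append(_merge_group(group, transcripts, f"{tid}.mg{per_tid[tid]}"))
    return merged


def filter_invalid_cds(
    models: Iterable[GeneModel], transcripts: Mapping[str, Transcript]
) -> list[GeneModel]:
    """Drop models with internal in-frame stops or frame-inconsistent blocks."""
    kept: list[GeneModel] = []
    dropped = Counter()
    for m in models:
        cds = cds_of(m, transcripts[m.transcript_id])
        if m.has_start and m.has_stop and len(cds) % 3 != 0:
            dropped["frameshift"] += 1
            continue
        prot = translate(cds, m.phase)
        internal = prot[:-1] if prot.endswith("*") else prot
        if "*" in internal:
            dropped["early_stop"] += 1
            continue
        kept.append(m)
    if dropped:
        logger.info("filter_invalid_cds removed: %s", dict(dropped))
    return kept


def overlap_clusters(
    models: Sequence[GeneModel], strandless: bool = False
) -> list[list[GeneModel]]:
    """Transitive single-nucleotide span-overlap clusters per transcript(/strand)."""
    grouped: dict[tuple, list[GeneModel]] = defaultdict(list)
    for m in models:
        key = (m.transcript_id,) if strandless else (m.transcript_id, m.strand)
        grouped[key].append(m)
    clusters: list[list[GeneModel]] = []
    for key in sorted(grouped):
        members = sorted(grouped[key], key=lambda m: (m.start, m.end, m.id))
        cluster: list[GeneModel] = []
        reach = -1
        for m in members:
            if cluster and m.start >= reach:
                clusters.append(cluster)
                cluster = []
                reach = -1
            cluster.append(m)
            reach = max(reach, m.end)
        if cluster:
            clusters.append(cluster)
    return clusters


def _rank_key(m: GeneModel):
    return (-m.support, -m.score, -m.cds_len, m.id)


def resolve_overlaps(
    models: Sequence[GeneModel], strandless: bool = False
) -> list[GeneModel]:
    """Keep one model per overlap cluster: most evidence proteins first, then
    mapping score, then CDS length, then id (deterministic)."""
    out = [min(cluster, key=_rank_key) for cluster in overlap_clusters(models, strandless)]
    return sorted(out, key=lambda m: (m.transcript_id, m.start, m.id))


__all__ = [
    "DEFAULT_MIN_PERCENT",
    "DEFAULT_MAX_INTRON",
    "JunctionKey",
    "frame_tag",
    "structures_from_alignments",
    "merge_same_junctions",
    "filter_invalid_cds",
    "overlap_clusters",
    "resolve_overlaps",
]
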