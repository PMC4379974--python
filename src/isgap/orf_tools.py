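"""Fixed-frame extension of partial genes and the six-frame ORF baseline.

Partial gene models (missing start and/or stop) are elongated codon-by-codon
in their established reading frame into the flanking transcript sequence:
upstream until an in-frame ATG (start gained) or an in-frame stop (extension
refused past evidence), downstream until an in-frame stop (extended through
it) — or, either way, until fewer than three nucleotides remain. Splice
junctions and the reading frame are never altered, so the original protein is
always a substring of the extended one.

The six-frame baseline translates each transcript in all three frames of both
strands and keeps open reading frames, ignoring gene structure entirely — the
conventional shortcut this package's evidence-based pipeline is measured
against. It emits single-exon models only, by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .seqcore import (
    START_CODON,
    STOP_CODONS,
    ExonBlock,
    GeneModel,
    Transcript,
    cds_of,
    replace,
    revcomp,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_AA = 100


@dataclass(frozen=True)
class Orf:
    """An open reading frame in forward-strand half-open coordinates.

    ``frame`` is the codon offset on the *reported* strand (for '-', on the
    reverse-complemented sequence). ``aa_length`` excludes the stop codon;
    the stop codon is included in the [start, end) span when present.
    """

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    has_start: bool
    has_stop: bool
    aa_length: int


def _frame_orfs(codons: list[str]) -> list[tuple[int, int, bool, bool]]:
    """ORFs within one frame as (codon_lo, codon_hi, has_start, has_stop).

    Complete ORFs run from the first ATG of a stop-terminated segment through
    its stop. When a frame contains no complete ORF, the open stretch after
    the last stop (or the whole frame if stop-free) qualifies as a partial
    ORF.
    """
    orfs: list[tuple[int, int, bool, bool]] = []
    seg_start = 0
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            try:
                atg = codons.index(START_CODON, seg_start, i)
            except ValueError:
                atg = -1
            if atg >= 0:
                orfs.append((atg, i + 1, True, True))
            seg_start = i + 1
    if not orfs and seg_start < len(codons):
        tail = codons[seg_start:]
        orfs.append(
            (seg_start, len(codons), tail[0] == START_CODON, False)
        )
    return orfs


def six_frame_orfs(
    transcript: Transcript,
    min_aa: int = DEFAULT_MIN_AA,
    mode: str = "longest",
    require_start: bool = False,
    require_stop: bool = False,
) -> list[Orf]:
    """Enumerate ORFs in all six frames of a transcript.

    ``mode='all'`` returns every ORF with at least ``min_aa`` residues
    (stop excluded); ``mode='longest'`` returns the single longest such ORF
    per transcript. Transcripts shorter than 3 nt yield an empty list.
    """
    if mode not in ("longest", "all"):
        raise ValueError(f"mode must be 'longest' or 'all', got {mode!r}")
    n = transcript.length
    if n < 3:
        return []
    found: list[Orf] = []
    for strand, seq in (("+", transcript.seq), ("-", revcomp(transcript.seq))):
        for frame in range(3):
            ncod = (n - frame) // 3
            codons = [seq[frame + 3 * i : frame + 3 * i + 3] for i in range(ncod)]
            for lo, hi, hs, he in _frame_orfs(codons):
                a = frame + 3 * lo
                b = frame + 3 * hi
                if strand == "-":
                    a, b = n - b, n - a
                aa = (hi - lo) - (1 if he else 0)
                found.append(
                    Orf(transcript.id, strand, frame, a, b, hs, he, aa)
                )
    found = [
        o
        for o in found
        if o.aa_length >= min_aa
        and (o.has_start or not require_start)
        and (o.has_stop or not require_stop)
    ]
    if mode == "all" or not found:
        return sorted(found, key=lambda o: (o.start, o.end, o.strand, o.frame))
    best = min(
        found,
        key=lambda o: (
            -o.aa_length,
            not (o.has_start and o.has_stop),
            o.strand != "+",
            o.frame,
            o.start,
        ),
    )
    return [best]


def sixframe_gene_set(
    transcripts: Iterable[Transcript],
    min_aa: int = DEFAULT_MIN_AA,
    mode: str = "longest",
    require_start: bool = False,
    require_stop: bool = False,
) -> list[GeneModel]:
    """Six-frame baseline gene set: one single-exon model per retained ORF."""
    models: list[GeneModel] = []
    for t in transcripts:
        for k, o in enumerate(
            six_frame_orfs(t, min_aa, mode, require_start, require_stop), 1
        ):
            models.append(
                GeneModel(
                    id=f"{t.id}.sf{k}",
                    transcript_id=t.id,
                    strand=o.strand,
                    exons=(ExonBlock(o.start, o.end),),
                    phase=0,
                    has_start=o.has_start,
                    has_stop=o.has_stop,
                    source="sixframe",
                    support=0,
                    score=float(o.aa_length),
                )
            )
    return models


# ---------------------------------------------------------------------------
# fixed-frame extension of partial genes
# ---------------------------------------------------------------------------

def extend_partial(model: GeneModel, transcript: Transcript) -> GeneModel:
    """Extend a partial model in its fixed frame to gain a start and/or stop.

    Complete models are returned unchanged. Junctions are never altered, no
    internal stop is ever introduced, and the operation is idempotent.
    """
    if model.is_complete:
        return model
    seq = transcript.seq
    n = len(seq)
    cds = cds_of(model, transcript)
    exons = list(model.exons)
    phase = model.phase
    hs, he = model.has_start, model.has_stop
    changed = False

    if model.strand == "+":
        if not hs:
            s0 = exons[0].start + phase
            new_start = None
            c = s0 - 3
            while c >= 0:
                codon = seq[c : c + 3]
                if codon == START_CODON:
                    new_start = c
                    hs = True
                    break
                if codon in STOP_CODONS:
                    if c + 3 == s0 and cds[phase : phase + 3] == START_CODON:
                        new_start = s0
                        hs = True
                    else:
                        logger.debug(
                            "extension_blocked_by_stop model=%s side=5'", model.id
                        )
                    break
                c -= 3
            else:
                # ran past the transcript start without a verdict
                kmax = s0 // 3
                if kmax >= 1:
                    new_start = s0 - 3 * kmax
            if new_start is not None and new_start != exons[0].start:
                exons[0] = ExonBlock(new_start, exons[0].end)
                phase = 0
                changed = True
        if not he:
            tail = (len(cds) - model.phase) % 3
            c = exons[-1].end - tail
            new_end = None
            while c + 3 <= n:
                codon = seq[c : c + 3]
                if codon in STOP_CODONS:
                    new_end = c + 3
                    he = True
                    break
                c += 3
            if new_end is None:
                avail = (n - (exons[-1].end - tail)) // 3
                if avail >= 1:
                    new_end = exons[-1].end - tail + 3 * avail
            if new_end is not None and new_end > exons[-1].end:
                exons[-1] = ExonBlock(exons[-1].start, new_end)
                changed = True
    else:
        if not hs:
            top = exons[-1].end - phase  # forward coord just above 1st codon
            new_end = None
            c = top
            while c + 3 <= n:
                codon = revcomp(seq[c : c + 3])
                if codon == START_CODON:
                    new_end = c + 3
                    hs = True
                    break
                if codon in STOP_CODONS:
                    if c == top and cds[phase : phase + 3] == START_CODON:
                        new_end = top
                        hs = True
                    else:
                        logger.debug(
                            "extension_blocked_by_stop model=%s side=5'", model.id
                        )
                    break
                c += 3
            else:
                avail = (n - top) // 3
                if avail >= 1:
                    new_end = top + 3 * avail
            if new_end is not None and new_end != exons[-1].end:
                exons[-1] = ExonBlock(exons[-1].start, new_end)
                phase = 0
                changed = True
        if not he:
            tail = (len(cds) - model.phase) % 3
            bottom = exons[0].start + tail
            new_start = None
            c = bottom - 3
            while c >= 0:
                codon = revcomp(seq[c : c + 3])
                if codon in STOP_CODONS:
                    new_start = c
                    he = True
                    break
                c -= 3
            if new_start is None:
                avail = bottom // 3
                if avail >= 1:
                    new_start = bottom - 3 * avail
            if new_start is not None and new_start < exons[0].start:
                exons[0] = ExonBlock(new_start, exons[0].end)
                changed = True

    if not changed and hs == model.has_start and he == model.has_stop:
        return model
    return replace(
        model,
        exons=tuple(exons),
        phase=phase,
        has_start=hs,
        has_stop=he,
        source="extended" if changed else model.source,
    )


def extend_all(
    models: Iterable[GeneModel], transcripts: Mapping[str, Transcript]
) -> list[GeneModel]:
    return [extend_partial(m, transcripts[m.transcript_id]) for m in models]


__all__ = [
    "DEFAULT_MIN_AA",
    "Orf",
    "six_frame_orfs",
    "sixframe_gene_set",
    "extend_partial",
    "extend_all",
]
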