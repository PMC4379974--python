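"""Core sequence types and codon arithmetic for transcript-space gene models.

Everything downstream of assembly lives in *transcript space*: a gene model is
an ordered set of exon blocks on one assembled transcript, and an intron is the
gap between two consecutive blocks (a retained intron physically present in the
transcript sequence). Coordinates are 0-based, half-open, always on the
transcript's forward strand; minus-strand models keep their exons in ascending
forward order and the spliced CDS is the reverse complement of the exon
concatenation. ``phase`` is the offset of the first complete codon within that
strand-corrected spliced CDS.

Only the standard nuclear genetic code is supported (plant mRNA). Codons
containing ``N`` translate to ``'X'``, which is never a stop: assemblies
contain Ns and treating them as stops would truncate genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_STANDARD_TABLE = unambiguous_dna_by_id[1]
CODON_TABLE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
START_CODON = "ATG"

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: provenance labels a model may carry
MODEL_SOURCES = ("evidence", "extended", "abinitio", "merged", "sixframe", "truth")


class SequenceError(ValueError):
    """Input sequence violates the DNA alphabet or basic preconditions."""


class StructuralError(ValueError):
    """A gene model's structure is inconsistent with its transcript."""


class InvariantViolation(ValueError):
    """A model's completeness flags disagree with its sequence content."""


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        pos = next(i for i, ch in enumerate(seq) if ch in bad)
        raise SequenceError(
            f"non-DNA character {seq[pos]!r} at position {pos}"
        )


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}.

    An involution: ``revcomp(revcomp(s)) == s``. N self-complements.
    """
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, phase: int = 0) -> str:
    """Translate consecutive codons starting at offset ``phase``.

    Stops are rendered as ``'*'``; any codon containing ``N`` becomes ``'X'``;
    a trailing 1–2 nt partial codon is ignored.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    _check_alphabet(seq)
    out = []
    for i in range(phase, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(CODON_TABLE[codon])
    return "".join(out)


@dataclass(frozen=True)
class Transcript:
    """A named DNA sequence from a de novo assembly."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("transcript id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        _check_alphabet(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class ExonBlock:
    """A half-open interval [start, end) on a transcript's forward strand."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise StructuralError(f"bad exon block ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "ExonBlock") -> bool:
        return self.start < other.end and other.start < self.end


def _as_blocks(exons: Iterable) -> tuple[ExonBlock, ...]:
    out = []
    for e in exons:
        out.append(e if isinstance(e, ExonBlock) else ExonBlock(int(e[0]), int(e[1])))
    return tuple(out)


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon blocks on one transcript with strand, frame and provenance.

    ``support`` counts distinct evidence proteins behind the model; ``score``
    accumulates the raw alignment scores of its contributors.
    """

    id: str
    transcript_id: str
    strand: str
    exons: tuple[ExonBlock, ...]
    phase: int = 0
    has_start: bool = False
    has_stop: bool = False
    source: str = "evidence"
    support: int = 0
    score: float = 0.0
    evidence_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", _as_blocks(self.exons))
        if not self.id:
            raise StructuralError("gene model id must be non-empty")
        if self.strand not in ("+", "-"):
            raise StructuralError(f"bad strand {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise StructuralError(f"bad phase {self.phase}")
        if self.source not in MODEL_SOURCES:
            raise StructuralError(f"unknown source {self.source!r}")
        if not self.exons:
            raise StructuralError("gene model needs at least one exon")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise StructuralError(
                    f"exons not sorted/disjoint with >=1 nt introns: {a} then {b}"
                )

    # -- geometry -----------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def cds_len(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_complete(self) -> bool:
        return self.has_start and self.has_stop

    @property
    def multiexon(self) -> bool:
        return len(self.exons) > 1

    def junctions(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) forward-strand intron boundary pairs."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def span_overlaps(self, other: "GeneModel") -> bool:
        return self.start < other.end and other.start < self.end


def cds_of(model: GeneModel, transcript: Transcript) -> str:
    """Spliced coding sequence: exon concatenation, strand-corrected.

    Introns (inter-exon gaps) never appear in the output.
    """
    if model.transcript_id != transcript.id:
        raise StructuralError(
            f"model {model.id} is on {model.transcript_id}, not {transcript.id}"
        )
    if model.end > transcript.length:
        raise StructuralError(
            f"model {model.id} exon end {model.end} beyond transcript "
            f"length {transcript.length}"
        )
    cds = "".join(transcript.seq[e.start : e.end] for e in model.exons)
    return revcomp(cds) if model.strand == "-" else cds


def infer_completeness(cds: str, phase: int) -> tuple[bool, bool]:
    """(has_start, has_stop) inferred from spliced CDS content.

    has_start requires an ATG prefix in phase 0; has_stop requires the final
    in-frame codon (at phase-anchored frame) to be a stop.
    """
    has_start = phase == 0 and cds.startswith(START_CODON)
    coding = len(cds) - phase
    has_stop = (
        coding >= 3 and coding % 3 == 0 and cds[-3:] in STOP_CODONS
    )
    return has_start, has_stop


def classify_completeness(model: GeneModel, transcript: Transcript) -> str:
    """One of complete / partial5 / partial3 / internal, checked against content."""
    cds = cds_of(model, transcript)
    exp_start, exp_stop = infer_completeness(cds, model.phase)
    if (exp_start, exp_stop) != (model.has_start, model.has_stop):
        raise InvariantViolation(
            f"model {model.id}: flags (start={model.has_start}, "
            f"stop={model.has_stop}) disagree with CDS content "
            f"(start={exp_start}, stop={exp_stop})"
        )
    if model.has_start and model.has_stop:
        return "complete"
    if model.has_stop:
        return "partial5"
    if model.has_start:
        return "partial3"
    return "internal"


def validate_model(model: GeneModel, transcript: Transcript) -> None:
    """Raise unless the model satisfies every structural invariant.

    Checks bounds, flag/content agreement, complete => ATG..stop with CDS
    length divisible by 3, and absence of internal in-frame stops.
    """
    cds = cds_of(model, transcript)
    classify_completeness(model, transcript)  # raises on flag mismatch
    if model.is_complete:
        if (len(cds) % 3) != 0 or model.phase != 0:
            raise InvariantViolation(
                f"model {model.id}: complete but CDS length {len(cds)} "
                f"(phase {model.phase}) not a whole codon count"
            )
        if not cds.startswith(START_CODON) or cds[-3:] not in STOP_CODONS:
            raise InvariantViolation(f"model {model.id}: complete without ATG..stop")
    prot = translate(cds, model.phase)
    internal = prot[:-1] if prot.endswith("*") else prot
    if "*" in internal:
        raise InvariantViolation(f"model {model.id}: internal stop codon")


# -- spliced coordinate arithmetic ------------------------------------------

def spliced_positions(model: GeneModel) -> list[int]:
    """Transcript coordinates of CDS bases in gene 5'->3' order."""
    pos = [p for e in model.exons for p in range(e.start, e.end)]
    return pos[::-1] if model.strand == "-" else pos


def codon_triples(model: GeneModel) -> list[tuple[int, int, int]]:
    """Transcript-coordinate triples of each complete codon, in gene order.

    A triple fully identifies region + frame; two models share a codon iff
    the same three transcript bases are translated together in both.
    """
    pos = spliced_positions(model)
    return [
        (pos[i], pos[i + 1], pos[i + 2])
        for i in range(model.phase, len(pos) - 2, 3)
    ]


def frame_offset_at(model: GeneModel, position: int) -> int | None:
    """Codon phase (0/1/2) of a transcript position within the model's CDS.

    Returns None if the position is not exonic in this model.
    """
    off = 0
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    for e in exons:
        if e.start <= position < e.end:
            local = (position - e.start) if model.strand == "+" else (e.end - 1 - position)
            return (off + local - model.phase) % 3
        off += len(e)
    return None


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> list[Transcript]:
    """Load transcripts; IDs are the first whitespace-delimited token."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(Transcript(rec.id, str(rec.seq)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, seq) pairs wrapped at ``width`` columns."""
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


__all__ = [
    "CODON_TABLE",
    "STOP_CODONS",
    "START_CODON",
    "SequenceError",
    "StructuralError",
    "InvariantViolation",
    "Transcript",
    "ExonBlock",
    "GeneModel",
    "revcomp",
    "translate",
    "cds_of",
    "infer_completeness",
    "classify_completeness",
    "validate_model",
    "spliced_positions",
    "codon_triples",
    "frame_offset_at",
    "read_fasta",
    "write_fasta",
    "replace",
]
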