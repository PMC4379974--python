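"""Variant region classification and bi-directional flank confirmation.

Variants called on one assembly are classified by the transcript region they
hit — exon, intron, or other (UTR/non-coding) — against the final gene
models, with precedence exon > intron > others for spans that straddle a
boundary. A variant is *confirmed* when the k-mers immediately flanking its
REF span in the first assembly both occur, exactly and uniquely, in a single
transcript of the second assembly separated by the ALT allele — the classic
flank-conservation screen used to promote variants to usable markers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import VariantRecord
from .seqcore import GeneModel, Transcript

logger = logging.getLogger(__name__)

DEFAULT_FLANK_K = 50


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: VariantRecord
    region: str  # exon | intron | others
    confirmed: bool = False
    flags: tuple[str, ...] = ()


def classify_variant_regions(
    variants: Iterable[VariantRecord],
    models: Sequence[GeneModel],
    transcripts: Mapping[str, Transcript] | None = None,
) -> list[ClassifiedVariant]:
    """Assign each variant exactly one region class (exon > intron > others)."""
    by_tid: dict[str, list[GeneModel]] = {}
    for m in models:
        by_tid.setdefault(m.transcript_id, []).append(m)
    out: list[ClassifiedVariant] = []
    for v in variants:
        if transcripts is not None and v.transcript_id not in transcripts:
            logger.warning(
                "variant at %s:%d dropped: unknown transcript", v.transcript_id, v.pos
            )
            continue
        lo, hi = v.ref_span
        region = "others"
        for m in by_tid.get(v.transcript_id, []):
            if any(lo < e.end and e.start < hi for e in m.exons):
                region = "exon"
                break
            if m.start < hi and lo < m.end:
                region = "intron"  # inside the gene span but only intron gaps
        out.append(ClassifiedVariant(v, region))
    return out


def _find_flanks(
    seq: str, left: str, right: str, alt: str, require_alt: bool, max_mismatch: int
) -> int:
    """Count placements of left + alt + right within one transcript."""
    hits = 0
    k = len(left)
    if max_mismatch == 0:
        i = seq.find(left)
        while i != -1:
            j = i + k
            mid_ok = (not require_alt) or seq[j : j + len(alt)] == alt
            if mid_ok and seq[j + len(alt) : j + len(alt) + k] == right:
                hits += 1
            i = seq.find(left, i + 1)
        return hits
    # mismatch-tolerant scan (small inputs only)
    def _ham_le(a: str, b: str, m: int) -> bool:
        d = 0
        for x, y in zip(a, b):
            if x != y:
                d += 1
                if d > m:
                    return False
        return True

    for i in range(len(seq) - k + 1):
        if not _ham_le(seq[i : i + k], left, max_mismatch):
            continue
        j = i + k
        mid_ok = (not require_alt) or seq[j : j + len(alt)] == alt
        r = seq[j + len(alt) : j + len(alt) + k]
        if mid_ok and len(r) == k and _ham_le(r, right, max_mismatch):
            hits += 1
    return hits


def confirm_flanks(
    classified: Sequence[ClassifiedVariant],
    assembly_a: Mapping[str, Transcript],
    assembly_b: Mapping[str, Transcript],
    k: int = DEFAULT_FLANK_K,
    require_alt: bool = True,
    max_flank_mismatch: int = 0,
) -> list[ClassifiedVariant]:
    """Confirm variants by exact bi-directional k-mer flank matching.

    Confirmed iff both flanks occur in a single transcript of the second
    assembly, exactly once across the whole assembly, separated by the ALT
    allele. Variants within ``k`` nt of a transcript end are flagged
    ``unconfirmable``; multi-hit flank pairs are flagged ``ambiguous``.
    """
    out: list[ClassifiedVariant] = []
    for cv in classified:
        v = cv.variant
        t = assembly_a.get(v.transcript_id)
        if t is None:
            out.append(
                ClassifiedVariant(v, cv.region, False, cv.flags + ("unknown_transcript",))
            )
            continue
        lo, hi = v.ref_span
        if lo < k or hi + k > t.length:
            out.append(
                ClassifiedVariant(v, cv.region, False, cv.flags + ("unconfirmable",))
            )
            continue
        left = t.seq[lo - k : lo]
        right = t.seq[hi : hi + k]
        hits = 0
        for tb in assembly_b.values():
            hits += _find_flanks(
                tb.seq, left, right, v.alt, require_alt, max_flank_mismatch
            )
            if hits > 1:
                break
        if hits == 1:
            out.append(ClassifiedVariant(v, cv.region, True, cv.flags))
        elif hits > 1:
            out.append(
                ClassifiedVariant(v, cv.region, False, cv.flags + ("ambiguous",))
            )
        else:
            out.append(ClassifiedVariant(v, cv.region, False, cv.flags))
    return out


REGIONS = ("exon", "intron", "others")


def variant_summary(classified: Sequence[ClassifiedVariant]) -> pd.DataFrame:
    """Counts of SNPs/INDELs by region, whole and confirmed, plus totals."""
    rows = ["SNPs", "INDELs", "Total"]
    cols = pd.MultiIndex.from_product(
        [["whole", "confirmed"], [*REGIONS, "sum"]]
    )
    table = pd.DataFrame(0, index=rows, columns=cols)
    for cv in classified:
        kind = "SNPs" if cv.variant.vtype == "SNP" else "INDELs"
        for scope in ("whole",) + (("confirmed",) if cv.confirmed else ()):
            for row in (kind, "Total"):
                table.loc[row, (scope, cv.region)] += 1
                table.loc[row, (scope, "sum")] += 1
    return table


__all__ = [
    "DEFAULT_FLANK_K",
    "ClassifiedVariant",
    "classify_variant_regions",
    "confirm_flanks",
    "variant_summary",
    "REGIONS",
]
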