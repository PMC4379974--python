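"""Validation of predicted gene sets against reference-protein alignments.

Reference proteins aligned to the transcripts under strict thresholds
(percent >= 70, query coverage >= 90%, no frameshift/early-stop) define
*query regions*; redundancy is allowed — one protein may yield many regions
across transcripts, each evaluated independently. A gene *represents* a query
when it translates the query's codons in the same region, on the same strand
and in the same frame: coverage is counted per codon (all three bases of a
query codon must be translated together by the gene), and a query is
represented when coverage reaches the threshold (99% by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import ProteinAlignmentRecord
from .seqcore import ExonBlock, GeneModel, codon_triples

logger = logging.getLogger(__name__)

DEFAULT_MIN_PERCENT = 70.0
DEFAULT_MIN_COV = 0.9
DEFAULT_THRESHOLD = 0.99


@dataclass(frozen=True)
class QueryRegion:
    """One correctly aligned reference-protein region on a transcript."""

    query_id: str
    protein_id: str
    transcript_id: str
    strand: str
    blocks: tuple[ExonBlock, ...]
    phase: int
    multiexon: bool
    codon_set: frozenset[tuple[int, int, int]]


@dataclass(frozen=True)
class RepresentationResult:
    query_id: str
    best_gene_id: str
    coverage: float
    represented: bool


def _codon_set(
    transcript_id: str, strand: str, blocks, phase: int
) -> frozenset[tuple[int, int, int]]:
    probe = GeneModel(
        id="q", transcript_id=transcript_id, strand=strand,
        exons=tuple(blocks), phase=phase,
    )
    return frozenset(codon_triples(probe))


def select_query_regions(
    alignments: Iterable[ProteinAlignmentRecord],
    min_percent: float = DEFAULT_MIN_PERCENT,
    min_cov: float = DEFAULT_MIN_COV,
) -> list[QueryRegion]:
    """Retain clean, high-stringency aligned regions as independent queries."""
    out: list[QueryRegion] = []
    for rec in alignments:
        if rec.percent < min_percent or rec.query_cov < min_cov:
            continue
        if rec.frameshift_flag or rec.earlystop_flag:
            continue
        qid = (
            f"{rec.protein_id}@{rec.transcript_id}:"
            f"{rec.blocks[0].start}-{rec.blocks[-1].end}{rec.strand}"
        )
        out.append(
            QueryRegion(
                query_id=qid,
                protein_id=rec.protein_id,
                transcript_id=rec.transcript_id,
                strand=rec.strand,
                blocks=rec.blocks,
                phase=rec.phase,
                multiexon=len(rec.blocks) > 1,
                codon_set=_codon_set(
                    rec.transcript_id, rec.strand, rec.blocks, rec.phase
                ),
            )
        )
    return out


def coverage_of(
    query: QueryRegion,
    genes: Sequence[GeneModel],
    threshold: float = DEFAULT_THRESHOLD,
    _cache: dict | None = None,
) -> RepresentationResult:
    """Best per-gene codon coverage of a query region.

    A query codon counts as covered by a gene iff the gene translates the
    same three transcript bases as one codon on the same strand. Ties on
    coverage break by gene id.
    """
    best_id, best_cov = "", 0.0
    nq = len(query.codon_set)
    for g in sorted(genes, key=lambda g: g.id):
        if g.transcript_id != query.transcript_id or g.strand != query.strand:
            continue
        if _cache is not None:
            gset = _cache.get(g.id)
            if gset is None:
                gset = _cache[g.id] = frozenset(codon_triples(g))
        else:
            gset = frozenset(codon_triples(g))
        cov = len(query.codon_set & gset) / nq if nq else 0.0
        if cov > best_cov:
            best_id, best_cov = g.id, cov
    return RepresentationResult(
        query_id=query.query_id,
        best_gene_id=best_id,
        coverage=best_cov,
        represented=best_cov >= threshold,
    )


def evaluate_gene_set(
    queries: Sequence[QueryRegion],
    genes: Sequence[GeneModel],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[RepresentationResult]:
    by_tid: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_tid.setdefault(g.transcript_id, []).append(g)
    cache: dict = {}
    return [
        coverage_of(q, by_tid.get(q.transcript_id, []), threshold, _cache=cache)
        for q in queries
    ]


def _block(queries, results):
    rep = [r for r in results if r.represented]
    return {
        "queries": len(queries),
        "represented": len(rep),
        "represented_pct": 100.0 * len(rep) / len(queries) if queries else 0.0,
        "representing_genes": len({r.best_gene_id for r in rep}),
    }


def summarize_validation(
    queries: Sequence[QueryRegion],
    results: Sequence[RepresentationResult],
    results2: Sequence[RepresentationResult] | None = None,
    labels: tuple[str, str] = ("set1", "set2"),
) -> dict:
    """Overall and multi-exon-only representation tables.

    With two result sets, adds the difference breakdown over all cases where
    the two gene sets did not both represent the same query region.
    """
    multi_idx = [i for i, q in enumerate(queries) if q.multiexon]
    report: dict = {
        labels[0]: {
            "overall": _block(queries, results),
            "multiexon": _block(
                [queries[i] for i in multi_idx], [results[i] for i in multi_idx]
            ),
        }
    }
    if results2 is not None:
        report[labels[1]] = {
            "overall": _block(queries, results2),
            "multiexon": _block(
                [queries[i] for i in multi_idx], [results2[i] for i in multi_idx]
            ),
        }
        both = only1 = only2 = neither = 0
        for r1, r2 in zip(results, results2):
            if r1.represented and r2.represented:
                both += 1
            elif r1.represented:
                only1 += 1
            elif r2.represented:
                only2 += 1
            else:
                neither += 1
        report["difference"] = {
            f"only_{labels[0]}": only1,
            f"only_{labels[1]}": only2,
            "both": both,
            "neither": neither,
        }
    return report


def report_frame(report: dict) -> pd.DataFrame:
    rows = []
    for label, tables in report.items():
        if label == "difference":
            continue
        for scope, block in tables.items():
            rows.append({"gene_set": label, "scope": scope, **block})
    return pd.DataFrame(rows)


__all__ = [
    "DEFAULT_MIN_PERCENT",
    "DEFAULT_MIN_COV",
    "DEFAULT_THRESHOLD",
    "QueryRegion",
    "RepresentationResult",
    "select_query_regions",
    "coverage_of",
    "evaluate_gene_set",
    "summarize_validation",
    "report_frame",
]
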