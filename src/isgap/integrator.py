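"""Training-set export, ab initio filtering, integration, representative
selection and gene-set statistics.

Evidence models are the backbone: an ab initio model that agrees with an
overlapping evidence model (identical junctions in the shared span, same
reading frame) only ever *extends* its terminal boundaries; a conflicting
ab initio model is discarded; an ab initio model on transcript territory
without protein evidence is adopted unchanged. One ab initio model never
bridges two evidence models into one.

A locus is a transitive same-transcript/strand span-overlap cluster; its
representative is the longest complete model, else the longest partial.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence_builder import overlap_clusters, resolve_overlaps
from .seqcore import (
    ExonBlock,
    GeneModel,
    Transcript,
    cds_of,
    infer_completeness,
    replace,
    spliced_positions,
    translate,
)

logger = logging.getLogger(__name__)

DEFAULT_TRAINING_N = 2000
DEFAULT_MIN_CDS = 150


@dataclass(frozen=True)
class Locus:
    """A cluster of mutually overlapping gene models on one transcript/strand."""

    transcript_id: str
    strand: str
    span: tuple[int, int]
    members: tuple[str, ...]


@dataclass(frozen=True)
class GeneSetStats:
    n_genes: int
    n_multiexon: int
    n_introns: int
    mean_exon_len: float
    mean_intron_len: float
    total_len: int
    mean_len: float
    no_introns: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Number of genes": [self.n_genes],
                "Number of genes containing multiple exons": [self.n_multiexon],
                "Number of introns": [self.n_introns],
                "Average length of exons (bp)": [round(self.mean_exon_len, 1)],
                "Average length of introns (bp)": [round(self.mean_intron_len, 1)],
                "Total length (bp)": [self.total_len],
                "Average length (bp)": [round(self.mean_len, 1)],
            }
        ).T.rename(columns={0: "value"})


def select_training_genes(
    models: Sequence[GeneModel],
    n: int = DEFAULT_TRAINING_N,
    seed: int = 0,
) -> list[GeneModel]:
    """Sample ``n`` complete genes for an external trainer's input.

    Weighted sampling without replacement (weight = CDS length, doubled for
    multi-exon models, so spliced genes and long genes are preferred),
    deterministic for a given seed. Falls back to every complete model when
    fewer than ``n`` exist.
    """
    complete = sorted(
        (m for m in models if m.is_complete), key=lambda m: m.id
    )
    if not complete:
        raise ValueError("no complete gene models to build a training set from")
    if len(complete) <= n:
        if len(complete) < n:
            logger.warning(
                "only %d complete models available for a training set of %d",
                len(complete),
                n,
            )
        return list(complete)
    rng = np.random.default_rng(seed)
    weights = np.array(
        [m.cds_len * (2.0 if m.multiexon else 1.0) for m in complete]
    )
    # Efraimidis–Spirakis keys: top-n of u^(1/w) is a weighted sample
    keys = rng.random(len(complete)) ** (1.0 / weights)
    picked = np.argsort(-keys)[:n]
    return [complete[i] for i in sorted(picked)]


def filter_abnormal_abinitio(
    models: Iterable[GeneModel],
    transcripts: Mapping[str, Transcript],
    min_cds: int = DEFAULT_MIN_CDS,
) -> list[GeneModel]:
    """Drop abnormal ab initio models; recompute completeness from sequence.

    Abnormal means: exons out of transcript bounds, CDS shorter than
    ``min_cds`` nt, an internal in-frame stop, or a CDS length inconsistent
    with the declared phase (no complete codon at all).
    """
    kept: list[GeneModel] = []
    dropped = Counter()
    for m in models:
        t = transcripts.get(m.transcript_id)
        if t is None or m.end > t.length:
            dropped["out_of_bounds"] += 1
            continue
        cds = cds_of(m, t)
        if m.cds_len < min_cds:
            dropped["short_cds"] += 1
            continue
        if len(cds) - m.phase < 3:
            dropped["phase_inconsistent"] += 1
            continue
        prot = translate(cds, m.phase)
        internal = prot[:-1] if prot.endswith("*") else prot
        if "*" in internal:
            dropped["internal_stop"] += 1
            continue
        hs, he = infer_completeness(cds, m.phase)
        kept.append(replace(m, has_start=hs, has_stop=he, source="abinitio"))
    if dropped:
        logger.info("filter_abnormal_abinitio removed: %s", dict(dropped))
    return kept


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _junctions_in_span(model: GeneModel, lo: int, hi: int):
    return tuple(
        (d, a) for d, a in model.junctions() if d >= lo and a <= hi
    )


def _frames_agree(a: GeneModel, b: GeneModel) -> bool:
    """Do the two models translate some shared base in the same codon phase?"""
    pos_a = {p: i for i, p in enumerate(spliced_positions(a))}
    for j, p in enumerate(spliced_positions(b)):
        i = pos_a.get(p)
        if i is not None:
            return (i - a.phase) % 3 == (j - b.phase) % 3
    return False


def _union_exons(a: Sequence[ExonBlock], b: Sequence[ExonBlock]) -> tuple[ExonBlock, ...]:
    ivals = sorted([(e.start, e.end) for e in a] + [(e.start, e.end) for e in b])
    out: list[list[int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple(ExonBlock(s, e) for s, e in out)


def _extend_with(
    ev: GeneModel, ab: GeneModel, transcript: Transcript
) -> GeneModel:
    exons = _union_exons(ev.exons, ab.exons)
    # re-anchor the phase on the evidence model's first complete codon
    anchor = spliced_positions(ev)[ev.phase]
    merged = replace(ev, exons=exons, phase=0, source="merged")
    offset = spliced_positions(merged).index(anchor)
    merged = replace(merged, phase=offset % 3)
    cds = cds_of(merged, transcript)
    hs, he = infer_completeness(cds, merged.phase)
    return replace(merged, has_start=hs, has_stop=he)


def integrate(
    evidence_models: Sequence[GeneModel],
    abinitio_models: Sequence[GeneModel],
    transcripts: Mapping[str, Transcript],
) -> list[GeneModel]:
    """Combine evidence and ab initio models without same-strand overlap.

    (a) compatible overlap -> evidence model extended to the union span;
    (b) conflicting overlap -> ab initio model discarded;
    (c) no overlap -> ab initio model adopted unchanged.
    """
    current: dict[str, GeneModel] = {m.id: m for m in evidence_models}
    by_key: dict[tuple, list[str]] = defaultdict(list)
    for m in evidence_models:
        by_key[(m.transcript_id, m.strand)].append(m.id)
    adopted: list[GeneModel] = []
    counts = Counter()
    for ab in sorted(abinitio_models, key=lambda m: m.id):
        t = transcripts[ab.transcript_id]
        overlapping = [
            current[i]
            for i in by_key.get((ab.transcript_id, ab.strand), [])
            if current[i].span_overlaps(ab)
        ]
        if not overlapping:
            adopted.append(ab)
            counts["adopted"] += 1
            continue
        compatible = []
        for ev in overlapping:
            lo = max(ev.start, ab.start)
            hi = min(ev.end, ab.end)
            if _junctions_in_span(ev, lo, hi) != _junctions_in_span(ab, lo, hi):
                compatible = None
                break
            if not _frames_agree(ev, ab):
                compatible = None
                break
            compatible.append(ev)
        if compatible is None:
            counts["discarded_conflict"] += 1
            continue
        if len(compatible) > 1:
            counts["discarded_bridge"] += 1  # bridging is not performed
            continue
        ev = compatible[0]
        current[ev.id] = _extend_with(ev, ab, t)
        counts["extended"] += 1
    logger.info("integrate: %s", dict(counts))
    out = list(current.values()) + adopted
    # enforce the same-strand non-overlap invariant (evidence outranks
    # ab initio through its support count)
    return resolve_overlaps(out)


def final_filter(
    models: Iterable[GeneModel],
    predicate: Callable[[GeneModel], bool] | None = None,
) -> list[GeneModel]:
    """Apply the pluggable final screen (default: accept all)."""
    models = list(models)
    if predicate is None:
        return models
    kept = [m for m in models if predicate(m)]
    logger.info("final_filter kept %d of %d models", len(kept), len(models))
    if not kept:
        logger.warning("final_filter removed every model")
    return kept


def hitlist_predicate(path, require_hit: bool = True) -> Callable[[GeneModel], bool]:
    """Keep models whose id appears in a hit-list file (one id per line)."""
    with open(path) as fh:
        ids = {line.strip() for line in fh if line.strip()}
    if not ids:
        logger.warning("hit list %s is empty", path)
    return lambda m: (m.id in ids) if (ids or require_hit) else True


def build_loci(models: Sequence[GeneModel]) -> list[tuple[Locus, list[GeneModel]]]:
    out = []
    for cluster in overlap_clusters(models):
        span = (min(m.start for m in cluster), max(m.end for m in cluster))
        locus = Locus(
            cluster[0].transcript_id,
            cluster[0].strand,
            span,
            tuple(m.id for m in cluster),
        )
        out.append((locus, cluster))
    return out


def select_representatives(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Exactly one model per locus: longest complete, else longest partial.

    Ties break by higher support, then id (deterministic).
    """
    reps: list[GeneModel] = []
    for _locus, members in build_loci(models):
        complete = [m for m in members if m.is_complete]
        pool = complete or members
        reps.append(
            min(pool, key=lambda m: (-m.cds_len, -m.support, m.id))
        )
    return sorted(reps, key=lambda m: (m.transcript_id, m.start, m.id))


def gene_set_stats(models: Sequence[GeneModel]) -> GeneSetStats:
    """Counts and means in the shape of a standard annotation summary table."""
    if not models:
        return GeneSetStats(0, 0, 0, 0.0, 0.0, 0, 0.0, no_introns=True)
    exon_lens = [len(e) for m in models for e in m.exons]
    intron_lens = [
        b.start - a.end for m in models for a, b in zip(m.exons, m.exons[1:])
    ]
    total = sum(m.cds_len for m in models)
    return GeneSetStats(
        n_genes=len(models),
        n_multiexon=sum(1 for m in models if m.multiexon),
        n_introns=len(intron_lens),
        mean_exon_len=float(np.mean(exon_lens)),
        mean_intron_len=float(np.mean(intron_lens)) if intron_lens else 0.0,
        total_len=total,
        mean_len=total / len(models),
        no_introns=not intron_lens,
    )


# ---------------------------------------------------------------------------
# the assembled pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnnotateResult:
    step1: list[GeneModel]
    step2: list[GeneModel]
    training: list[GeneModel]
    abinitio: list[GeneModel]
    integrated: list[GeneModel]
    final: list[GeneModel]
    representatives: list[GeneModel]
    stats: GeneSetStats


def annotate(
    transcripts: Mapping[str, Transcript],
    alignments: Sequence,
    abinitio_models: Sequence[GeneModel] = (),
    min_percent: float = 30.0,
    max_intron: int = 50_000,
    training_n: int = DEFAULT_TRAINING_N,
    training_seed: int = 0,
    min_cds: int = DEFAULT_MIN_CDS,
    predicate: Callable[[GeneModel], bool] | None = None,
    overlap_strandless: bool = False,
) -> AnnotateResult:
    """Run the full evidence-based annotation pipeline.

    Step 1 builds, merges and de-duplicates evidence structures; Step 2
    extends partial genes in fixed frame; Step 3 filters ab initio models
    and integrates them without overlap; Step 4 applies the final filter and
    picks per-locus representatives.
    """
    from .evidence_builder import (
        filter_invalid_cds,
        merge_same_junctions,
        structures_from_alignments,
    )
    from .orf_tools import extend_all

    candidates = structures_from_alignments(
        alignments, transcripts, min_percent=min_percent, max_intron=max_intron
    )
    merged = merge_same_junctions(candidates, transcripts)
    valid = filter_invalid_cds(merged, transcripts)
    step1 = resolve_overlaps(valid, strandless=overlap_strandless)
    step2 = extend_all(step1, transcripts)
    try:
        training = select_training_genes(step2, n=training_n, seed=training_seed)
    except ValueError:
        logger.warning("no complete models; training set is empty")
        training = []
    ab_ok = filter_abnormal_abinitio(abinitio_models, transcripts, min_cds=min_cds)
    integrated = integrate(step2, ab_ok, transcripts)
    # fixed-frame extension applies to partial genes wherever they arise:
    # newly adopted ab initio models get the same treatment evidence models
    # received in Step 2 (a truncated predicted gene regains its start/stop)
    integrated = resolve_overlaps(
        extend_all(integrated, transcripts), strandless=overlap_strandless
    )
    final = final_filter(integrated, predicate)
    reps = select_representatives(final)
    return AnnotateResult(
        step1=step1,
        step2=step2,
        training=training,
        abinitio=ab_ok,
        integrated=integrated,
        final=final,
        representatives=reps,
        stats=gene_set_stats(final),
    )


__all__ = [
    "Locus",
    "GeneSetStats",
    "AnnotateResult",
    "select_training_genes",
    "filter_abnormal_abinitio",
    "integrate",
    "final_filter",
    "hitlist_predicate",
    "build_loci",
    "select_representatives",
    "gene_set_stats",
    "annotate",
]
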