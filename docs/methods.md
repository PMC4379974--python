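# Methods

## Coordinate model

Everything is computed in transcript space: 0-based, half-open intervals on
the transcript's forward strand, for both strands of a gene. Minus-strand
models keep their exons in ascending forward order; the spliced CDS is the
reverse complement of the exon concatenation, and `phase` (0/1/2) is the
offset of the first complete codon within that strand-corrected CDS. GFF
I/O converts to 1-based inclusive coordinates at the boundary, and per-part
CDS phases are computed walking 5′→3′ in gene orientation. This single
canonical representation makes splice arithmetic unambiguous: a codon is
identified by the *triple of transcript positions* it translates, which is
also the unit of the evaluator's coverage metric.

Only the standard nuclear genetic code is supported (the target data is
plant mRNA). Codons containing `N` translate to `X`; `X` is never a stop
and never blocks extension — assemblies contain Ns, and treating them as
stops would truncate genes.

## Step 1: evidence structures

* Alignment retention: percent score ≥ `min_percent` (default 30), every
  implied intron ≤ `max_intron` (default 50,000 nt). Records already flagged
  as frameshifted or early-stopped are dropped at intake.
* Frameshift detection for the GFF2 dialect is arithmetic: a clean protein
  alignment covers whole codons after its phase offset, so spliced block
  length − phase must be ≡ 0 (mod 3). Early stops are detected by
  translating the implied CDS (when transcript sequences are available).
* Merging: structures with an identical junction set on one transcript and
  strand collapse to one model. Only terminal boundaries can disagree
  (internal boundaries are the junctions themselves), so "consensus" is a
  per-end majority vote over the contributing alignments, ties resolved to
  the outermost (longer) boundary. The merged phase follows the member
  whose 5′-terminal boundary won the vote.
* Single-exon structures have no junctions; they merge when they overlap on
  the same transcript and strand *in the same reading frame* (the frame tag
  is the transcript-frame of the first complete codon, anchored at the
  gene-orientation 5′ terminus). Frame-compatible overlap is the natural
  analogue of junction identity for the junction-free case.
* Overlap resolution: transitive ≥ 1 nt span-overlap clusters per transcript
  and strand (a `--overlap-strandless` switch exists because strand-blind
  resolution is also defensible); each cluster keeps one model, ranked by
  support (distinct evidence proteins), then mapping score, then CDS
  length, then id. The id tiebreak exists purely for reproducibility.

## Step 2: fixed-frame extension

Extension walks codon-by-codon in the model's established frame, in the
plain transcript sequence beyond the terminal exons (there is no splicing
outside the aligned region to respect).

* 5′ side: stop at the first in-frame ATG. If an in-frame stop appears
  first, the boundary does not move past it — we refuse to extend past
  evidence; the single exception is a stop sitting immediately upstream of
  an existing in-frame ATG, which just confirms the start. Hitting the
  transcript edge without a verdict extends to the outermost full codon and
  leaves the model 5′-partial.
* 3′ side: extend through the first in-frame stop; at the transcript edge,
  extend to the last full codon and leave the model 3′-partial.

The operation never alters junctions, never introduces an internal stop
(every codon it walks over has been inspected), is idempotent, and the
original translation is always a substring of the extended one. It applies
twice in the pipeline: to Step 1 output, and again after integration so
that adopted ab initio models whose predictor truncated a terminal boundary
regain their start/stop the same way evidence models do. The second pass is
this package's design choice: extension is defined on *partial gene
models*, not on a particular provenance, and a whole-codon truncation is
deterministically repaired by it.

## Six-frame baseline

Within each of the six frames, complete ORFs run from the first ATG of each
stop-terminated segment through its stop; a frame with no complete ORF
contributes its trailing open stretch as a partial ORF (so a stop-free,
ATG-free frame is still reported — poly-A tails, incomplete transcripts).
Defaults are `mode=longest` (one ORF per transcript) and `min_aa=100`, both
configurable, with `--require-start/--require-stop` to restrict to anchored
ORFs; a conventional length cutoff is used because no canonical one exists.
The stop codon is included in the reported span (GFF3 CDS convention);
`aa_length` excludes it. The baseline emits single-exon models only, by
construction — that is the point of the comparison.

## Integration policy

Evidence always beats ab initio: the evidence model is the backbone and is
only ever *extended*, never shortened or re-spliced. Compatibility means
identical junction sets restricted to the shared span and agreement of
codon phase at a shared exonic base. The merged exon set is the interval
union of both models — equivalent to terminal-boundary extension when the
ab initio model adds no outside junctions, and preserving its extra
introns when it does. One ab initio model overlapping two evidence models
compatibly is discarded rather than allowed to bridge them: fusing two
independently evidenced genes on the strength of a single prediction is the
riskier error. "Abnormal" ab initio models (the screen applied before
integration) are this package's definition, since no standard one exists:
internal in-frame stop, CDS < 150 nt, out-of-bounds exons, or no complete
codon under the declared phase; all thresholds configurable.

The training-set export samples 2,000 complete genes without replacement,
weighted by CDS length and doubled for multi-exon models (a trainer needs
splice signal), deterministically for a given seed; it writes GFF3 + FASTA
for an external trainer and deliberately does not run one.

## Evaluator

Query regions are reference-protein alignments at percent ≥ 70 and query
coverage ≥ 0.9 with no frameshift/early-stop, kept redundantly (one protein
may map to many transcripts; each region is judged independently).
Coverage is *codon-level*: a query codon is covered only when all three of
its transcript bases are translated together, on the same strand, by the
gene — nucleotide-level overlap would credit out-of-frame translation,
which is exactly the artefact being measured. A region is represented at
coverage ≥ 0.99 (configurable). The side-by-side report adds the breakdown
over regions not represented by both sets.

## Variant screen

Region classification precedence is exon > intron > others for REF spans
straddling a boundary (InDels), yielding the mutually exclusive three-way
partition the summary table needs. Flank confirmation extracts the k-mers
(default k = 50) immediately 5′ and 3′ of the REF span in assembly A and
requires both to occur in assembly B separated by exactly the ALT allele —
exact matching, the strictest reproducible reading of "detected"
(`--max-flank-mismatch` relaxes it; `--no-require-alt` drops the allele
check). A flank pair found at more than one place in assembly B is flagged
`ambiguous` and not confirmed (a marker that maps twice is unusable);
variants within k nt of a transcript end are `unconfirmable`.

## The fixture generator (simfix)

`simfix` emulates the structures an annotator actually faces, not a read
simulator: per coding transcript one gene with UTRs; a fraction of genes
carry 1–2 retained GT..AG introns inserted uniformly (codon boundaries and
mid-codon alike, to exercise phase handling across splices); some
transcripts are truncated mid-CDS at either end (partial genes); the rest
are non-coding decoys. Evidence alignments are the true exon blocks with
terminal boundaries jittered by whole codons (splice junctions are emitted
exactly — a spliced aligner anchors them on GT..AG, while alignment *ends*
are where it wavers) and percent scores derived from mutated copies of the
true protein. Ab initio models are the truth perturbed by whole-codon
terminal truncation, omission, or spurious single-exon calls on decoys;
truncation-only errors emulate an undertrained predictor, and extension
errors are excluded because the evidence-first integration policy has no
way to detect a confidently wrong ab initio boundary. Assembly B is
assembly A with planted SNPs/InDels applied; a chosen fraction sit inside
diverged flank zones (~10% substitutions, at least one forced per flank
window) giving the confirmation screen guaranteed negatives, and variants
are spaced > 2k apart so zones never interact.

Two deliberate idealisations, and what they imply about the tests: planted
introns are frame-disrupting (length forced ≢ 0 mod 3) and land in the
middle 20–80% of the CDS. A frame-preserving, stop-free retained intron is
read through silently by six-frame translation and is indistinguishable
from coding sequence without a reference; real retained introns
overwhelmingly do disrupt frame, and the middle placement guarantees no
single contiguous ORF can cover ≥ 99% of a broken gene's codons. A stop
codon is also planted in-frame immediately upstream of each true ATG, which
pins the six-frame ORF of an intron-free gene to the true start.
Consequently, passing tests demonstrate the pipeline's structural logic —
junction consensus, frame bookkeeping, extension, integration, flank
matching — under controlled noise; they do not demonstrate robustness to
mis-spliced alignments, chimeric transcripts, or frame-preserving retained
introns, none of which the generator produces.

Default parameters (500 transcripts, 70% coding, 30% intron retention,
intron 60–500 bp, CDS 360–1500 bp, UTR 30–300 bp, 2–4 evidence proteins per
gene with 2% protein mutation and ±6 nt end jitter, 15% of genes without
evidence, ab initio truncation/omission/spurious rates 5/10/5%) loosely
mirror a plant transcriptome with mean intron ≈ 300 bp, without claiming to
reproduce any particular dataset. Presets: `noise-free` (200 transcripts,
no jitter/mutations/ab initio errors), `default`, `hard` (double jitter,
5% mutation, 50% retention). Identical parameters + seed give byte-identical
fixture files, and a fixture regenerates exactly from its manifest.

## Numerical and degenerate-input choices

* Ties are always broken deterministically, ending at the model id.
* Empty gene sets yield zero-filled statistics; a set with no introns
  reports mean intron length 0 with an explicit `no_introns` flag.
* Unparseable lines are hard errors naming the line number; structurally
  invalid records (overlapping blocks, inconsistent strand) are rejected
  per-record with a logged warning rather than aborting a whole file.
* GFF3 round trips are lossless for every model field, including float
  scores (written via `repr`).
* Problem sizes in the tests and the acceptance script (200–500 transcripts
  per fixture, 1,000 random 500-mers for the ORF-enumerator cross-check)
  are the package's chosen desk-scale study conditions; all properties they
  check are construction-based and hold across seeds.

## Known limitations

* Genome coordinates, alternative genetic codes and RNA alphabets are out
  of scope; so are running aligners/predictors (Exonerate, Augustus) and
  any functional annotation.
* The overlap-resolution and locus definitions are maximally permissive
  (≥ 1 nt transitive overlap); densely overlapping gene families on one
  transcript will be collapsed harder than a genome-based annotator would.
* Exonerate's GFF2 does not carry its percent score; the reader defaults it
  to 100 unless the extended attributes are present, so percent filtering
  is only meaningful for inputs that carry the attribute (or the TSV
  dialect).
* Six-frame ORF definitions vary across tools; the one here (first-ATG
  complete ORFs plus trailing open stretches) is stated exactly and
  enforced against an independent enumerator, but counts from other tools
  will differ.
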