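# Methods

## Reference model

tDRs are mapped against transcript-space libraries, never the genome.  Two
libraries are built from an annotated tRNA gene set:

* **Mature library.** Each gene body has its annotated introns excised
  (1-based closed intervals, removed right-to-left) and a non-templated
  3′ `CCA` appended.  Genes whose mature sequences are identical — and which
  share the same amino-acid / anticodon / family-identifier metadata — form
  one family `W-X-Y-Z`, where `Z` is the member count.  Identical sequences
  under *different* metadata are deliberately not merged (a warning is
  logged): merging would destroy the printed naming scheme.  Genes sharing
  metadata but diverging in sequence are rejected as malformed input, since
  the family identifier denotes a sequence family by construction.
* **Pre library.** The unspliced genomic transcript: 40 nt of 5′ flank
  (standing in for the leader), the intron-retaining body, 40 nt of 3′ flank
  (trailer).  Genes of one mature family with identical pre sequence group
  into `pre-W-X-Y-Z.n` (`Z` = largest member copy index, `n` = group size).

The package defines its own rebuildable reference format — a gene-body
multi-FASTA plus a sidecar TSV (metadata, intron intervals, flanks) — so
libraries can be reconstructed from any gtRNAdb-style export or from the
built-in simulator, rather than shipping a fixed FASTA.

Generalized loop coordinates (used by the naming grammar) are the per-field
statistical modes of per-gene loop annotations when provided; multimodal
ties resolve to the smallest candidate, which widens the annotation window
rather than narrowing it.  Without annotations the canonical defaults apply:
D-loop 13–22, anticodon loop 31–39 (5′-anchored), T-loop −23…−15
(3′-anchored, because the variable loop makes 5′-anchored T-loop positions
unstable).

## Read filtering

Defaults: Phred floor 28 at *every* position (a score exactly 28 passes —
the filter removes reads whose quality drops *below* the floor), length
window 14–40 nt inclusive, abundance floor 100 copies inclusive.  Quality is
applied before collapsing so that a unique sequence's count reflects only
trustworthy copies; reads containing `N` are discarded at the quality step
(an ambiguous call can never support a confident exact match) and are
reported inside the quality bucket of the run summary, keeping the
conservation identity

    input = quality + length + count + mapped + unmapped

exact.  The abundance floor may instead be given as a fraction of total
input reads (`min_count_frac`) for libraries of very different depth.  The
upper length bound is configurable; 40 nt is the default because the
size-class grammar itself caps a tRNA-half at 40 nt.

## Alignment hierarchy

Stages, in dispatch order: exact/mature, exact/pre, 1 mismatch, 1 deletion,
2 mismatches, 2 deletions, 3-base contiguous deletion — the error-tolerant
stages against mature families only, on the assumption that only mature
tRNAs are extensively modified.  The stage order is overridable
(`--stage-order`), e.g. to prioritise deletions over mismatches.

Contract details that matter for reproducibility:

* End-to-end alignment of the read, sense strand only; no insertions (a
  reverse-transcriptase skip removes reference bases from the read; nothing
  adds bases).
* Each stage demands its exact error count (MM2 = exactly two mismatches).
  Because a read only reaches a stage after all earlier stages failed
  *across all families*, "exactly k" and "at most k" dispatch identically;
  the exact form keeps every placement's error lists characteristic of its
  stage.
* Two deletions may fall on any two window positions; the three-base stage
  requires one contiguous gap.  An adjacent pair belongs to the two-deletion
  stage simply because it is tried first.
* Within a family, ties between equally good windows resolve to the leftmost
  start, then the lexicographically smallest error-position set.  Across
  families there is no tie-break: the read counts fully in every family
  placed at its stage.
* Results are sorted by descending count then sequence, so output is
  independent of input order.

The implementation is a per-stage scan (vectorised Hamming distance for
mismatch stages; subsequence-pruned window enumeration for deletion stages).
The test suite validates it against an independent brute-force enumerator of
all windows × all error patterns on randomized toy references (520 unique
reads, 100 % agreement in stage, placement and error positions).

## Coverage, naming, quantification

Coverage at a position is the count-weighted fraction of the family's placed
reads whose reference window spans it; deleted reference positions count as
covered (the read derives from across them).  Error fractions at a position
are computed over *spanning* reads and split into three classes: mismatch,
single-base deletion (from either deletion stage ≤ 2), and three-base-gap
deletion.

Primary-tDR naming follows the grammar described in the README.  Numerical
conventions: all coverage comparisons are strict (`> 0.5`, `> 2/3`); exactly
half or exactly two-thirds does not qualify.  Negative coordinates resolve
as −k ↦ L+1−k, so −1 is the final `CCA` adenosine of a mature family.  The
suffix letters concatenate in the fixed order 5′, D, T, A, 3′ — the unique
simple order consistent with the composite names the grammar can produce
(`DA`, `DTA`).  Two edge cases are permitted and logged rather than
suppressed: near-full-length coverage emits `5′3′`, and a body-only pre-tDR
emits a bare `B` (reachable only for intron-containing genes, whose pre body
is not a substring of any mature sequence).  A dominant region (> 2/3) whose
> 50 % length falls outside both size windows is reported `undefined` with
its statistics retained.

Quantification uses full multi-map counting (numerators may sum to more
than the denominator; each relative abundance is still ≤ 100 because the
family numerator never exceeds the shared denominator).  Mature and pre
families share one denominator — all mapped reads.  Report tables print
relative abundance to one decimal; machine-readable values keep full
precision.  Post-hoc aggregation to isodecoder (`W-X`) or amino-acid level
sums member counts and uses the members' maximum coverage maximum; this is a
documented package choice, as no formula is canonical at aggregated level.

## Coverage maps

One row per family, top 50 by relative abundance by default; dot area is
linear in coverage.  Mature maps colour by nucleotide and overlay the error
classes exceeding 5 % of spanning reads at a position (most frequent class
only, ties to the earlier class in mismatch < del1 < del3 order); pre maps
colour by leader/body/trailer and carry no overlays since pre alignment is
exact-only.  Styles live in `MapSpec`, not in drawing code.  Rendering is
deterministic (fixed SVG hash salt, date metadata stripped): identical
inputs give byte-identical SVG.

## Synthetic data

The simulator emulates the study conditions rather than realistic error
processes: random 73-nt gene bodies (76-nt mature with `CCA` — the canonical
human cytosolic tRNA scale) with 40-nt flanks and optional introns; declared
tDRs as exact reference spans with optionally one injected error pattern
(substitution, one/two/three-base skip) at a declared position; uniform Q41
qualities; declared copy counts at or above the 100-copy floor; optional
singleton noise reads that the abundance filter should remove.  Error
positions must keep two intact bases from each span edge, so an injected
pattern cannot alias into a cheaper stage at the read's margins.  Truth
tables (expected stage per read; expected count, peak coverage, relative
abundance and primary name per family) follow arithmetically from the
declarations.

What the simulator does *not* emulate — and therefore what passing recovery
tests do not demonstrate about real data: sequencing-error noise,
position-dependent quality decay, 3′-tapering coverage, partially
overlapping isoform mixtures, genuinely ambiguous multi-family reads with
unequal fidelity, or realistic tRNA sequence composition (bodies are i.i.d.
uniform).  Recovery tests demonstrate the pipeline's bookkeeping and
grammar, not robustness to biological noise.

## Problem sizes and determinism

The shipped tests run on toy scales chosen to keep every code path and the
brute-force oracle exhaustively checkable: ≤ 5 families, 73–117-nt bodies,
hundreds of unique reads.  All randomness flows through explicit
`numpy.random.default_rng` seeds; the hypothesis suite runs derandomized.

## Known limitations

* No reverse-complement search by design (small RNA-seq is sense-stranded);
  no soft clipping, no insertions, no gaps beyond three bases.
* Error-tolerant stages never run against pre-tRNAs; a modified pre-tRNA
  read is reported unmapped.
* Reverse-transcriptase aborts under-represent heavily modified species;
  this is an experimental limitation upstream of any mapper and is not
  modelled.
* The relative-abundance formula is a ceiling on the primary tDR's share;
  it can overestimate when secondary species overlap the peak position.
* Differential analyses across samples (correlation, clustering, PCA) are
  out of scope; the report TSVs are designed to feed standard tools.
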