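# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the simulators do and do not
emulate, and the numerical choices a maintainer would want written down.

## The element model

A full-length retrozyme is modelled as `LTR5 – CR – LTR3` flanked by a 4-nt
target-site duplication (TSD):

* **LTRs** are ~300–400 bp direct repeats; each carries a Type III
  hammerhead ribozyme and, in the 5' copy, the promoter.  The two LTRs of
  one element are identical at integration (a consequence of the reverse-
  transcription mechanism), so the substitution count between them is a
  molecular clock for insertion age.
* **CR (central region)** is unique per element family; its 5' end holds
  the primer-binding site (PBS, reverse complement of the tRNA-Met
  3'-terminal sequence) and its 3' end a polypurine tract (PPT), the two
  priming signals of reverse transcription.  CR similarity defines group
  membership; between groups CRs share no significant similarity.
* **Completeness classes**: `full` (two LTRs + CR), `cr_partial` (a CR with
  at most one intact LTR), `ltr_fragment` (an isolated LTR or piece of
  one).  Chains of three or more equally spaced LTR hits are merged into
  one element flagged `tandem` (an incomplete tandem repeat of the unit,
  the genomic fingerprint of rolling-circle replication followed by
  reverse transcription of a concatemer).

## Homology scan

Exact k-mer seeding (default k = 12) on both strands, clustering of seeds
by diagonal (band 16), one Smith–Waterman refinement per cluster window
with match +1 / mismatch −2 / gap −3 (via Biopython's `PairwiseAligner`),
and collapse of overlapping same-strand hits to the best-scoring one.  Each
diagonal cluster gets its own refinement window: neighbouring element
copies must not be collapsed into one alignment.  `evalue_like` is a
Karlin–Altschul-style surrogate (λ = 1.28, K = 0.46, the ungapped +1/−2
values) computed from score and search-space size; it ranks and filters
hits the way an E-value does but is not calibrated to any BLAST release.
Default thresholds: `min_identity` 0.70, `min_length` 50 nt,
`max_evalue_like` 1e−10.  Externally computed outfmt-6 hits can replace
the internal scanner.

## Boundary refinement

Local alignment trims mismatched ends, so hits against diverged LTR copies
can start or stop a few bases inside the true element.  Annotation
therefore re-places boundaries by full-length minimum-Hamming placement:
the left LTR against the search query (when available), every other LTR of
the element against the refined left LTR.  This is exact whenever
divergence is substitution-dominated — the expected regime for young
elements — and merely approximate for indel-riddled copies.  TSD detection
then requires an exact, N-free 4/4 match of the flanks; PBS requires ≥10 nt
of exact complementarity to the tRNA 3' end within the first 30 nt of the
CR (the tRNA sequence is a configuration input, never hard-coded); PPT is
the longest run in the last 40 nt of the CR with ≥10 nt, ≥90% purines,
purine endpoints, ties resolved toward the 3' end.

## Hammerhead ribozyme detection

Detection is descriptor-based; no folding is attempted.  The motif, written
5'→3' with the topology of a cis-cleaving Type III hammerhead (entered and
exited through helix III):

    [III 5'] CUGANGA [II 5'] loop [II 3'] GAAA [I 5'] loop [I 3'] NUH | [III 3']

Core box 1 (`CUGANGA`, position 5 free) and box 2 (`GAAA`) are located with
at most one substitution each at the conserved catalytic positions; box 2
must start 10–60 nt downstream of box 1.  Helix II needs ≥3 consecutive
Watson–Crick pairs between the segments adjacent to the boxes; helix I
closes at an NUH triplet (H ∈ {A, C, U}) and helix III needs ≥3 pairs
flanking the core.  The scissile bond lies immediately 3' of the NUH
triplet; the first nucleotide of the downstream product is reported as the
monomer 5' end (a G in both the synthetic cassette and the observed
biology).  Substitutions at catalytic positions are reported and clear
`core_intact` without suppressing the match, so degenerate ribozymes are
annotated rather than hidden.  Overlapping candidate placements are
resolved to fewest-substitutions, then leftmost.

## Read classification and binning

Reads are aligned end-to-end (read-global, reference-infix) with unit edit
costs via edlib, on both strands, against every reference doubled when
circular — junction-spanning reads from circular monomer RNA then align
without special cases.  Gaps count as mismatches.  The best reference is
the minimum-distance one, ties to the lexicographically lowest id; reads
below 85% identity are dropped and counted.  Binning rounds the mismatch
percentage half-up to an integer: 0 → perfect, 1 → "1%", 2 → "2%", 3–13 →
"3–13%", >13 → ">13%"; for 100-nt reads one substitution is exactly one
percent.

## Strict assembly

The assembler is deliberately conservative because genomic retrozyme copies
are close in sequence: an overlap must be exact (one mismatch forbids the
merge) and a merge may add at most 25 nt of new sequence relative to the
larger contig (`min(len_a, len_b) − overlap ≤ 25`), which prevents foreign
reads from anchoring to long single-read overhangs at contig ends.
Containments merge with extension 0.  Defaults: `min_overlap` 20 nt,
`max_extension` 25 nt.

Merge order matters in principle: a read that links two growing chains can
be consumed by the wrong neighbour.  Up to 10 reads the assembler therefore
solves the merge-order problem exactly (memoized exhaustive search
minimizing first the number of contigs, then total assembled length, with
a canonical tie-break); beyond that it applies the globally best merge
greedily (longest overlap, then smallest contig-id pair, a contig being
identified by its smallest member read id).  Both modes are deterministic
and independent of input read order, and every output is re-audited: each
member read must match its contig verbatim at its recorded offset.
Fragmentation at realistic coverage is expected behaviour of the cap, not
a defect — it is what keeps molecules separate.

## Small RNAs and methylation

A small RNA counts as retrozyme-specific only on an exact full-length match
(either strand, circular doubling); inputs are assumed adapter-trimmed.
Region labels use majority footprint overlap with LTR vs CR spans in
*monomer* coordinates (one LTR + CR) when profiling against monomer
references; exact ties resolve to LTR.  The miRNA scan slides each miRNA's
reverse complement along the doubled element and reports sites with at
most 4 mismatches ("fewer than five").

Bisulfite conversion turns unmethylated C into T with the configured
conversion probability (default 1.0 in simulation; incomplete conversion is
a nuisance parameter, not corrected for in calling).  Calling is per
reference cytosine per clone: C → methylated, T → unmethylated, anything
else uncallable; contexts CpG / CHG / CHH are assigned from the reference
(every C gets exactly one; cytosines too close to the 3' end for a full
context default to CHH).  Only plus-strand cytosines of the amplicon are
called, since clones derive from a PCR product.  Clones whose identity to
the reference *outside* C positions falls below 90% are excluded — bisulfite
chemistry only touches cytosines, so divergence elsewhere marks a foreign
clone.  The target-vs-control comparison is a two-sided Mann–Whitney U on
per-clone methylation fractions (the clone is the experimental unit); the
underlying box-plot-style data carry no named test, and a distribution-free
test on clone fractions is the conservative default.  scipy's exact method
is used at small clone counts.

## Simulators: what they emulate, what they do not

`simulate_genome` plants elements in random-background scaffolds
(GC 0.38).  Defaults describe the studied genome's structure: 9 full
elements in two CR groups of 7 and 2, LTR–LTR divergences
[2, 0, 1, 7, 12, 20, 32, 0, 9] spanning the observed 0–32 range, two of
the nine planted as incomplete tandem repeats, plus 5 CR-partial and 20
LTR-fragment copies, LTR length 350 nt, CR lengths 600/450 nt.  Planted
elements keep ≥2 kb of background between them, reflecting the dispersal
of real copies (and making geometric pairing well-posed).  Divergence —
between groups (8%), within groups (1–2%), and between the two LTRs of an
element — never touches the ribozyme cassette, the PBS or the PPT: these
are the functionally constrained parts of real elements (between-group
similarity concentrates in the ribozyme-containing LTR portion), and
protecting them keeps planted feature coordinates and mismatch counts
exact.  The planted hammerhead cassette is a synthetic construct satisfying
the descriptor, not any natural ribozyme sequence.

`simulate_replication` applies r rounds of per-base substitution at rate ε
(uniform over the three alternatives) to each molecule independently, r
drawn from a configurable distribution; expected per-base divergence is
1 − (1 − ε)^r.  Replication errors are substitutions only — the read
analysis reports "mismatches", and indel modelling would complicate the
1%/2% binning without evidential basis.  `simulate_reads` draws 100-nt
reads with uniform starts on the circle (junction-spanning) and uniform
strand; no sequencing-error model is applied by default.
`simulate_small_rnas` draws error-free fragments from LTR or CR spans with
a configurable LTR bias (default 0.816) and length distribution (24-nt
dominated).  `simulate_bisulfite_clones` draws independent per-site states
from per-context rates.

Passing the recovery tests therefore shows the analysis logic is correct
under substitution-dominated divergence, clean reads and exact ground
truth; it does not establish robustness to indels, sequencing error,
adapter contamination, chimeric PCR artefacts or genome mis-assembly, none
of which the generators emulate.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: 6 × 30 kb
scaffolds; 150–250 molecules and 600–1000 reads per replication condition;
a 3 × 4 grid of (ε, r) ∈ {0.0005, 0.001, 0.002} × {1, 5, 10, 20}; 10,000
small RNAs; 20 bisulfite clones per arm; 200 random read sets of ≤8 reads
for the assembler-vs-exhaustive-search comparison.  Where reads cluster by
molecule (they share its mutations), standard errors are cluster-robust
(summed per-molecule residuals), not per-read.  All simulators are pure
functions of their configuration including the seed; stage seeds in the
pipeline are derived from the run seed by fixed offsets.

Known limitations: minus-strand element simulation is config-gated rather
than default; boundary refinement assumes substitution-dominated LTR
divergence; the e-value surrogate is not calibrated to NCBI BLAST; group
labels depend on single-linkage clustering, which is checked against (and
refuses) chains that would join CRs below 50% identity.
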