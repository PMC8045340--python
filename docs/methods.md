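# Methods

This note documents the models, algorithms and parameter choices behind
`negeseek`, what the synthetic-data generator does and does not emulate,
and the numerical conventions a user should know before trusting or
extending the results.

## Sequence model and I/O

All internal computation uses the uppercase DNA alphabet `{A,C,G,T,N}`;
RNA input is converted on read (`U` → `T`). Translation follows the
standard genetic code; a stop codon renders `*` and any codon containing
`N` (or otherwise untranslatable) renders `X`. Small-RNA libraries are
length-filtered to 18–30 nt with **inclusive** bounds (databases rarely
state inclusivity; both ends are kept here) and collapsed by exact
sequence; FASTQ qualities are parsed and discarded — quality and adapter
trimming are upstream concerns, not part of this pipeline.

## ORF calling and genome organization

ORFs are called on the plus strand only: the viruses targeted here have
positive-sense genomes, and minus-strand ORFs would be artifacts. In
each of the three frames an ORF runs from the first `ATG` after the
previous in-frame stop (or the sequence start) to the next in-frame stop
**inclusive**; ORFs lacking a downstream stop are discarded.
Coordinates are 1-based inclusive and include the stop codon, so a span
of `3(k+1)` nt encodes a `k`-aa product. Alternative start codons
(GTG/TTG) are not considered.

Major-ORF selection keeps every ORF of at least `min_len_codons` codons
(default **150**, chosen to pass the typical ~450-nt accessory ORFs of
this virus group while rejecting random open stretches) and drops ORFs
nested inside a longer one. UTR lengths and consecutive-pair relations
(overlap or intergenic length, same/different frame) follow directly
from the selected spans and satisfy the bookkeeping identity

```
utr5 + Σ span − Σ overlap + Σ intergenic + utr3 = genome length,
```

which the test suite asserts programmatically. A trailing poly(A) run of
≥ 10 nt can optionally be trimmed first, since genome lengths for these
viruses are conventionally reported excluding the tail.

## Palm-motif order classification

The RdRP palm motifs are matched as symbolic patterns — A `D x{4,5} D`,
B `G x{2,3} T x{3} N`, C `GDD` — where a wildcard position matches the
20 standard residues only; `X` (unknown residue) never satisfies any
position. Scanning reports *all* matches, including overlapping
registers of the variable-width patterns.

Classification scans a region of the protein (default: the C-terminal
half, where the polymerase domain of the long replicase ORF sits; this
avoids helicase-region false positives), enumerates candidate triples
taking one hit per motif, mutually non-overlapping, and requires the gap
between consecutive chosen motifs to lie within **5–300 aa**. The bounds
are this package's own guardrail — without them a 2,287-aa replicase
offers spurious pairings between motifs at opposite ends of the protein
— and are configurable. Among surviving triples the one with minimal
span wins, ties broken toward the leftmost (deterministic). The order
label is the chosen motifs' names sorted by position; no surviving
triple yields `undetermined`.

## Pairwise identity and neighbor joining

Global alignment uses affine-gap Needleman–Wunsch (Biopython's
`PairwiseAligner`): protein BLOSUM62 with gap open 10 / extend 0.5,
nucleotide match +5 / mismatch −4 with the same gaps — common defaults,
all configurable. The first gap position costs the open penalty, each
additional position the extend penalty. Percent identity is
`100 · identical / denominator`, reported to one decimal; the default
denominator counts columns with no gap in either sequence, with
"shorter sequence" and "full alignment length" available behind a flag
because published matrices rarely state their convention — reproduced
identities should therefore be compared with a tolerance of a couple of
percentage points.

Neighbor joining (Saitou–Nei, via scikit-bio) runs on
`d = (100 − identity)/100`. Negative branch lengths are clamped to zero
and flagged. NJ is exact on additive distance matrices, which the suite
verifies on randomly generated trees by recovering all leaf-to-leaf
distances. NJ here is a deliberately lightweight clustering check, not a
substitute for maximum-likelihood phylogenetics: no model selection, no
bootstrap, no alignment trimming.

The packaged 18-taxon RdRP identity table (upper triangle aa, lower
triangle nt) covers INLV1 and representative nege/kita-like viruses in
the Centivirus, Nelorpivirus, Aphiglyvirus, Kitaviridae and
Sandewavirus groups; `nj_tree` on its aa distances places INLV1 with
its two closest relatives (~77% aa identity).

## Transmembrane scanning

The ORF3 (SP24) product is scanned with a sliding Kyte–Doolittle
hydropathy window (window **19** aa, threshold **1.6** — the classic
setting for TM helix detection; `X` scores 0). Maximal runs of window
centers at or above threshold are expanded to the full window extent;
expansions that overlap or abut are merged, so a single helix split by a
one-residue dip is not double-counted. This is a transparent scanner,
not an HMM topology model: it reports no inside/outside orientation and
its boundaries are approximate. On 19–20 aa hydrophobic islands against
a hydrophilic background the predicted boundaries sit within ±5 aa of
the island edges; segment *counts* are reliable, exact boundaries are
not promised. Note that the segment count is not strictly monotone in
the threshold (raising it can split one merged segment into two); the
total predicted TM area is monotone and is what the suite tests.

## vsiRNA mapping and profiling

Mapping is exact string matching of each distinct read against the
genome and its reverse complement — the faithful equivalent of
zero-mismatch short-read alignment at the ~9 kb genome scale,
implemented with a substring index per read length (O(1) lookup per
read). Every hit is re-verifiable: extracting the genomic span and
applying the strand rule reproduces the read exactly.

Profile conventions:

* a multi-locus read contributes its full count **once** to totals and
  to the size/5′-nt tallies — by default on the strand carrying the
  majority of its placements (ties go to `+` and are flagged; an
  alternative `split` policy allocates fractionally by per-strand
  placement share) — and spreads `count / n_loci` coverage weight over
  each placement, so total coverage mass equals Σ count × length over
  mapped reads;
* reads matching both strands (reverse-complement palindromes) count on
  `+` and are flagged;
* the mapped-fraction denominator is the length-filtered (18–30 nt)
  library, the only denominator that is well-defined from the inputs
  this tool sees;
* 5′-terminal nucleotides are reported in the RNA alphabet (`T` → `U`),
  matching the field's plotting convention.

## Synthetic data: what it emulates, and what it does not

`gen_genome` plants ORFs (ATG, interior encoded codon-by-codon, TAA), an
in-frame stop directly upstream of each start (so the annotator opens
the ORF exactly at the planted ATG), a motif block in the replicase
ORF and hydrophobic TM islands in the membrane-protein ORF, then
repairs the sequence by constraint-checked point mutations: premature
stops are removed from every planted frame, and any spurious
plus-strand ORF long enough to be called is disrupted (first by
knocking out its ATG, else by writing an in-frame stop near its
middle). Repairs never touch protected feature codons, never introduce
D/N into the motif-scan flanks, and keep the TM background hydrophilic,
so the planted truth survives repair. Generation is deterministic per
seed and ends with a self-check that annotation, motif order and TM
count round-trip.

Design constants worth knowing:

* motif blocks use 7/9-aa gaps and draw wildcard and gap residues from
  an alphabet without D/N/G/T, so each planted motif matches its
  pattern in exactly one register; flanks inside the scan region carry
  no D or N, making them motif-free by construction;
* TM islands are poly-L against a K/R background; with window 19 and
  threshold 1.6 the above-threshold crossing happens at 14 island
  residues per window, which pins predicted boundaries to exactly ±5 aa
  of the island edges — the origin of the ±5 aa tolerance used in the
  tests;
* the TM-bearing ORF must not overlap another ORF (overlap residues are
  dictated by the other reading frame and would blur island edges);
  overlaps between other ORF pairs are fully supported;
* the built-in 8945-nt configuration reproduces a published aphid
  nege-like virus layout: ORF1 45–6908 (frame 3), a 263-nt ORF1/ORF2
  overlap in different frames, 44/98-nt UTRs, a C-A-B motif block at aa
  1950 of the 2287-aa replicase, and TM islands at aa 68–87, 107–126,
  138–157, 177–196 of a 204-aa ORF3. The ORF2 end (8190) and ORF3
  start (8233) are not published for that virus and are this package's
  choice of a typical layout (514-aa ORF2, 42-nt intergenic region).

`gen_reads` draws viral reads as exact substrings (or reverse
complements) with lengths from a configurable distribution (default
mode: 22 nt with probability 0.69, matching reported vsiRNA size
profiles), strand `Bernoulli(0.5)`, uniform or hotspot-weighted start
positions, and per-read rejection sampling so the 5′ A/U frequency hits
its target (default 0.8). Background reads are random sequences
verified to match neither strand, so mapped/unmapped truth is exact.

What the generator does **not** emulate: sequencing error, quality
scores, adapter remnants, Dicer-specific cut-site structure, host
transcriptome composition, or real codon usage (flank residues are
i.i.d., and motif-region flanks omit D/N entirely). Passing round-trip
tests therefore demonstrates that the analysis recovers planted
structure under the stated noise model — not that it is robust to
artifacts of real libraries, which should still be quality-controlled
upstream.

## Problem sizes and determinism

The shipped tests run the mapping oracle on 100 random genomes up to
2 kb, parameter recovery on 20 simulated libraries of 100,000 reads
each (20,000 viral) with agreement required within 3 binomial standard
deviations, round-trip recovery on 20 random genome configurations, and
NJ exactness on 100 random trees of 4–10 leaves — sizes chosen so the
statistical checks have the power of the study-scale library while the
whole suite stays in the minutes range. All randomness flows from
explicit integer seeds (hypothesis runs derandomized); identical
configuration and seed give byte-identical genomes, libraries and
manifests.

## Known limitations

* Motif classification is per-sequence; it does not map motifs across a
  multiple alignment, and heavily diverged palms with non-standard
  spacing will come out `undetermined` rather than mislabeled.
* Identity values depend on the scoring scheme and denominator
  convention; cross-tool comparisons need the ±2-point caution above.
* The TM scanner cannot distinguish a signal anchor from a TM helix and
  reports no orientation.
* Exact-match mapping deliberately ignores mismatches; a single SNP
  between the sequenced population and the reference drops all reads
  covering it. For the intra-host, same-assembly use case this is the
  intended "zero mismatches" semantics.
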