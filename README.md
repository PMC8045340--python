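# negeseek

A characterization pipeline for nege-like insect viruses — the ~9 kb,
positive-sense single-stranded RNA viruses (negeviruses, kitaviruses and
their relatives) increasingly discovered in aphids and other insects by
metatranscriptomic sequencing. Given a viral genome and a small-RNA
library, `negeseek` reproduces the standard desk analysis that turns an
assembled contig into a characterized virus:

1. **Genome organization** — call the major plus-strand ORFs (these
   viruses typically encode three, partially overlapping), derive the 5′
   and 3′ UTR lengths and the overlap/intergenic relation of every
   consecutive ORF pair; report as TSV and GFF3.
2. **RdRP palm-motif order** — locate the catalytic motifs of the
   RNA-dependent RNA polymerase, A `D-x(4,5)-D`, B `G-x(2,3)-T-x(3)-N`
   and C `GDD`, and classify the architecture as canonical **A-B-C** or
   circularly permuted **C-A-B**. The permuted palm is a lineage marker:
   it characterizes the Centivirus and Sandewavirus groups, while
   Nelorpivirus, Aphiglyvirus and the plant kita-/virga-like viruses
   keep the canonical order.
3. **Pairwise identity and clustering** — percent identity between RdRP
   domains from affine-gap Needleman–Wunsch global alignment (aa and
   nt), assembled into symmetric matrices, plus Saitou–Nei neighbor
   joining on `d = (100 − identity)/100` as a lightweight clustering
   check. An 18-taxon RdRP identity table for INLV1 (Indomegoura
   nege-like virus 1) and related nege/kita-like viruses ships with the
   package.
4. **Membrane topology of ORF3** — the SP24 virion membrane protein is
   scanned with a Kyte–Doolittle hydropathy window (window 19, threshold
   1.6); maximal above-threshold runs, expanded to full window extent
   and merged, are reported as transmembrane segments.
5. **vsiRNA profiling** — small RNAs (18–30 nt) are mapped to the genome
   by exact, zero-mismatch matching on both strands, and the classic
   antiviral-RNAi diagnostics are tallied: size distribution (total and
   unique, per strand), strand polarity, 5′-terminal nucleotide
   composition in the RNA alphabet, per-position coverage and the mapped
   fraction of the library.
6. **Synthetic data** — a generator builds genomes with planted ORFs,
   motif blocks and hydrophobic TM islands, and read libraries with a
   configurable length mode, strand balance, 5′ A/U bias and hotspot,
   all with exact ground truth, so every stage is testable offline.

## Worked example

Generate the built-in synthetic genome (8945 nt, mirroring a published
aphid nege-like virus layout), annotate it, then simulate and profile a
small-RNA library:

```
$ negeseek synth genome --seed 7 --out-dir demo
$ negeseek annotate --genome demo/genome.fasta --expect-orfs 3 --out-dir demo
genome_length   8945
utr5_len        44
utr3_len        98
ORF1-ORF2       overlap 263     different_frame
ORF2-ORF3       intergenic      42      same_frame
```

The genome is 8945 nt with a 44-nt 5′ UTR and a 98-nt 3′ UTR; ORF1 and
ORF2 overlap by 263 nt in different reading frames — the hallmark
negevirus arrangement. `demo/` now holds the GFF3/TSV annotation and the
translated ORF products.

```
$ negeseek synth reads --genome demo/genome.fasta --seed 7 \
      --n-viral 2000 --n-background 8000 --out-dir demo
$ negeseek sirna --reads demo/reads.fastq --genome demo/genome.fasta \
      --fmt fastq --out-dir demo
n_total_mapped  2000
n_unique_mapped 1934
frac_total      0.2000
frac_unique     0.1947
```

All 2000 simulated viral reads map back with zero mismatches (20% of
the 10,000-read library, matching the simulation's composition); the
size-distribution, 5′-nucleotide and coverage panels are written as
TSVs. `negeseek motifs` on the ORF1 product reports `order C-A-B`
(the permuted palm), and `negeseek tmscan` on the ORF3 product reports
`n_segments 4`. `negeseek characterize` runs all stages in one call.

## Layout

```
src/negeseek/
  seqio.py      FASTA/FASTQ I/O, reverse complement, translation, read collapsing
  annotate.py   plus-strand ORF calling, UTRs, overlaps, GFF3/TSV reports
  motifs.py     palm-motif scanning and A-B-C / C-A-B order classification
  identity.py   global alignment, identity matrices, neighbor joining
  membrane.py   Kyte-Doolittle hydropathy profile and TM segment prediction
  sirna.py      zero-mismatch read mapping and vsiRNA profiling
  simulate.py   synthetic genome and read-library generators with ground truth
  cli.py        the `negeseek` command-line interface
  data/         packaged 18-taxon RdRP identity table (TSV)
```

See `docs/methods.md` for the methods, parameter choices and known
limitations.
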