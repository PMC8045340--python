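"""Plus-strand ORF calling and genome-organization annotation.

Nege-like viruses carry a positive-sense ssRNA genome of ~9 kb with three
long, partially overlapping ORFs; the coding region is flanked by short
untranslated regions. This module finds major ORFs on the plus strand,
derives UTR lengths and the overlap/intergenic relations between
consecutive ORFs, and emits TSV/GFF3 reports.

Coordinates are 1-based inclusive throughout, and an ORF span includes
its stop codon (so a span of ``3(k+1)`` nt encodes a ``k``-aa protein).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seqio import GenomeRecord, ProteinRecord, translate

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AnnotationError(ValueError):
    """Raised when no ORF meets the length threshold."""


@dataclass
class OrfAnnotation:
    """One called ORF: 1-based inclusive span, frame, translated product."""

    index: int           # ordinal, 1-based, 5'->3'
    start: int           # position of the A of ATG
    end: int             # position of the last base of the stop codon
    frame: int           # 1|2|3 on the plus strand
    protein: ProteinRecord  # stop stripped

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        return self.span_nt // 3


@dataclass
class Relation:
    """Relation between consecutive major ORFs i and j (1-based ordinals)."""

    i: int
    j: int
    kind: str            # "overlap" | "intergenic"
    length: int          # nt
    same_frame: bool


@dataclass
class GenomeAnnotation:
    genome_id: str
    genome_length: int
    orfs: list[OrfAnnotation]
    utr5_len: int
    utr3_len: int
    relations: list[Relation]
    warnings: list[str] = field(default_factory=list)


def find_orfs(genome: GenomeRecord, min_len_codons: int = 150) -> list[OrfAnnotation]:
    """Call ORFs in the three plus-strand frames.

    In each frame an ORF runs from the first ATG after the previous
    in-frame stop (or the sequence start) to the next in-frame stop,
    inclusive. ORFs lacking a downstream stop are discarded. Only ORFs of
    at least ``min_len_codons`` codons (stop included) are returned,
    sorted by start.
    """
    if len(genome) < 6:
        raise ValueError("genome too short to contain an ORF")
    if min_len_codons < 2:
        raise ValueError("min_len_codons must be >= 2")
    seq = genome.seq
    out: list[OrfAnnotation] = []
    for offset in range(3):
        start: int | None = None  # 0-based position of current ORF's ATG
        for pos in range(offset, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                end = pos + 3  # exclusive
                if (end - start) // 3 >= min_len_codons:
                    prot = translate(seq[start:end]).rstrip("*")
                    out.append(OrfAnnotation(
                        index=0, start=start + 1, end=end,
                        frame=offset + 1,
                        protein=ProteinRecord(f"{genome.id}_orf", prot)))
                start = None
    out.sort(key=lambda o: (o.start, o.end))
    return out


def _select_major(orfs: list[OrfAnnotation]) -> list[OrfAnnotation]:
    """Drop ORFs nested inside a longer one; keep the rest sorted by start."""
    keep: list[OrfAnnotation] = []
    for o in orfs:
        nested = any(p.start <= o.start and o.end <= p.end and p.span_nt > o.span_nt
                     for p in orfs)
        if not nested:
            keep.append(o)
    return keep


def trim_polya(genome: GenomeRecord, min_run: int = 10) -> GenomeRecord:
    """Strip a trailing poly(A) run of at least ``min_run`` bases, if any."""
    n = len(genome.seq) - len(genome.seq.rstrip("A"))
    if n >= min_run:
        return GenomeRecord(genome.id, genome.seq[:-n], genome.description)
    return genome


def annotate_genome(genome: GenomeRecord, min_len_codons: int = 150,
                    expected_orfs: int | None = None,
                    polya_min_run: int | None = None) -> GenomeAnnotation:
    """Annotate the major-ORF organization of a plus-sense genome.

    Returns UTR lengths and the overlap/intergenic relation of every
    consecutive major-ORF pair. ``expected_orfs`` attaches a warning (not
    an error) when the count differs. ``polya_min_run`` optionally trims a
    trailing poly(A) run before annotation.
    """
    if polya_min_run is not None:
        genome = trim_polya(genome, polya_min_run)
    orfs = _select_major(find_orfs(genome, min_len_codons))
    if not orfs:
        raise AnnotationError(
            f"no ORF of >= {min_len_codons} codons found in {genome.id!r}; "
            "consider lowering the threshold")
    warnings: list[str] = []
    if expected_orfs is not None and len(orfs) != expected_orfs:
        msg = (f"expected {expected_orfs} major ORFs, found {len(orfs)} "
               f"at threshold {min_len_codons}")
        warnings.append(msg)
        logger.warning(msg)
    for k, o in enumerate(orfs, start=1):
        o.index = k
        o.protein.id = f"{genome.id}_ORF{k}"
    relations = []
    for a, b in zip(orfs, orfs[1:]):
        ov = a.end - b.start + 1
        if ov > 0:
            relations.append(Relation(a.index, b.index, "overlap", ov,
                                      a.frame == b.frame))
        else:
            relations.append(Relation(a.index, b.index, "intergenic", -ov,
                                      a.frame == b.frame))
    return GenomeAnnotation(
        genome_id=genome.id,
        genome_length=len(genome),
        orfs=orfs,
        utr5_len=orfs[0].start - 1,
        utr3_len=len(genome) - orfs[-1].end,
        relations=relations,
        warnings=warnings,
    )


def validate_annotation(ann: GenomeAnnotation, genome: GenomeRecord) -> None:
    """Programmatic check of every structural invariant of an annotation."""
    assert ann.genome_length == len(genome)
    for o in ann.orfs:
        assert o.span_nt % 3 == 0
        assert len(o.protein.seq) == o.n_codons - 1
        assert 1 <= o.start and o.end <= ann.genome_length
        assert genome.seq[o.start - 1:o.start + 2] == "ATG"
        assert genome.seq[o.end - 3:o.end] in STOP_CODONS
    assert ann.utr5_len == ann.orfs[0].start - 1
    assert ann.utr3_len == ann.genome_length - ann.orfs[-1].end
    total = ann.utr5_len + ann.utr3_len + sum(o.span_nt for o in ann.orfs)
    for r in ann.relations:
        total += r.length if r.kind == "intergenic" else -r.length
    assert total == ann.genome_length, "genome length bookkeeping failed"


def annotation_to_tsv(ann: GenomeAnnotation) -> str:
    """One row per ORF: index, start, end, frame, length_nt, protein_len."""
    lines = ["orf\tstart\tend\tframe\tlength_nt\tprotein_len"]
    for o in ann.orfs:
        lines.append(f"ORF{o.index}\t{o.start}\t{o.end}\t{o.frame}"
                     f"\t{o.span_nt}\t{len(o.protein.seq)}")
    return "\n".join(lines) + "\n"


def annotation_to_gff3(ann: GenomeAnnotation) -> str:
    """GFF3 with CDS and UTR features, all on strand ``+``, phase 0."""
    gid = ann.genome_id
    lines = ["##gff-version 3",
             f"##sequence-region {gid} 1 {ann.genome_length}"]
    def row(ftype, start, end, attrs):
        return f"{gid}\tnegeseek\t{ftype}\t{start}\t{end}\t.\t+\t0\t{attrs}"
    if ann.utr5_len > 0:
        lines.append(row("five_prime_UTR", 1, ann.utr5_len, f"ID={gid}_5UTR"))
    for o in ann.orfs:
        lines.append(row("CDS", o.start, o.end,
                         f"ID={gid}_ORF{o.index};Name=ORF{o.index}"))
    if ann.utr3_len > 0:
        lines.append(row("three_prime_UTR", ann.genome_length - ann.utr3_len + 1,
                         ann.genome_length, f"ID={gid}_3UTR"))
    return "\n".join(lines) + "\n"


def parse_gff3_cds(text: str) -> list[tuple[int, int]]:
    """Recover (start, end) of CDS features from GFF3 emitted here."""
    spans = []
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) >= 5 and cols[2] == "CDS":
            spans.append((int(cols[3]), int(cols[4])))
    return spans
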