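"""Sequence I/O and core sequence operations.

Everything downstream (annotation, motif scanning, identity, siRNA
profiling) works on plain uppercase DNA strings over ``{A,C,G,T,N}``.
RNA input is normalized to the DNA alphabet on read (``U`` -> ``T``);
this keeps a single internal alphabet even though the viruses handled
here have RNA genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
AA_STANDARD = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = frozenset(AA_STANDARD + "X*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised on unparseable or empty FASTA/FASTQ input."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


class FrameError(ValueError):
    """Raised when a nucleotide sequence is not a whole number of codons."""


@dataclass
class GenomeRecord:
    """A named nucleotide sequence (viral genome, host read, ...)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"GenomeRecord {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"GenomeRecord {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """A named amino-acid sequence; at most one trailing stop ``*``."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise AlphabetError(
                f"ProteinRecord {self.id!r}: illegal characters {sorted(bad)}"
            )
        if "*" in self.seq.rstrip("*") or self.seq.count("*") > 1:
            raise ValueError(
                f"ProteinRecord {self.id!r}: internal or repeated stop codon"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def without_stop(self) -> "ProteinRecord":
        return ProteinRecord(self.id, self.seq.rstrip("*"))


@dataclass
class ReadSet:
    """A small-RNA library collapsed by identical sequence.

    ``records`` keeps one representative (id, seq) per distinct sequence;
    ``counts`` maps each distinct sequence to its multiplicity. ``n_reads``
    is the number of reads that survived the length filter and
    ``n_removed`` the number discarded by it.
    """

    records: list[tuple[str, str]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    n_removed: int = 0

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def validate(self) -> None:
        rec_seqs = {s for _, s in self.records}
        if rec_seqs != set(self.counts):
            raise ValueError("ReadSet records and counts disagree")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("ReadSet counts must be positive")


def _dedupe_ids(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for i in ids:
        if i in seen:
            seen[i] += 1
            new = f"{i}.{seen[i]}"
            logger.warning("duplicate FASTA id %r renamed to %r", i, new)
            out.append(new)
        else:
            seen[i] = 0
            out.append(i)
    return out


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and ``U`` is converted to ``T``. Duplicate ids
    get a numeric suffix (with a warning). An empty file is a format error.
    """
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise FastaFormatError(f"{path}: no FASTA records found")
    ids = _dedupe_ids([r.id for r in raw])
    out = []
    for rid, rec in zip(ids, raw):
        seq = str(rec.seq).upper().replace("U", "T")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(GenomeRecord(id=rid, seq=seq, description=desc))
    return out


def write_fasta(records: Iterable[GenomeRecord | ProteinRecord],
                path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed-width line wrapping."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            desc = getattr(rec, "description", "")
            if desc:
                header += " " + desc
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement over ``{A,C,G,T,N}`` (``N`` maps to ``N``)."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"revcomp: illegal characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_maps(table: int) -> tuple[dict[str, str], frozenset[str]]:
    tab = CodonTable.unambiguous_dna_by_id[table]
    return dict(tab.forward_table), frozenset(tab.stop_codons)


_FORWARD, _STOPS = _codon_maps(1)


def translate(seq: str, table: int = 1) -> str:
    """Translate a nucleotide sequence (standard code by default).

    Stop codons become ``*``; any codon containing ``N`` (or otherwise
    untranslatable) becomes ``X``. The input length must be a multiple
    of three.
    """
    if len(seq) % 3:
        raise FrameError(f"sequence length {len(seq)} not divisible by 3")
    if table == 1:
        fwd, stops = _FORWARD, _STOPS
    else:
        fwd, stops = _codon_maps(table)
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in stops:
            out.append("*")
        else:
            out.append(fwd.get(codon, "X"))
    return "".join(out)


def collapse_reads(records: Sequence[tuple[str, str]],
                   min_len: int = 18, max_len: int = 30,
                   n_removed_prior: int = 0) -> ReadSet:
    """Length-filter (inclusive bounds) and collapse identical sequences."""
    counts: dict[str, int] = {}
    reps: dict[str, str] = {}
    removed = n_removed_prior
    for rid, seq in records:
        if not (min_len <= len(seq) <= max_len):
            removed += 1
            continue
        if seq not in counts:
            counts[seq] = 0
            reps[seq] = rid
        counts[seq] += 1
    if removed:
        logger.info("length filter removed %d reads outside [%d, %d]",
                    removed, min_len, max_len)
    return ReadSet(records=[(reps[s], s) for s in counts],
                   counts=counts, n_removed=removed)


def read_reads(path: str | Path, fmt: str = "fasta",
               min_len: int = 18, max_len: int = 30) -> ReadSet:
    """Read a small-RNA library (FASTA or FASTQ; qualities discarded).

    Reads outside ``[min_len, max_len]`` (inclusive) are dropped and
    counted in :attr:`ReadSet.n_removed`; the rest are collapsed by
    identical sequence.
    """
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported read format {fmt!r}")
    path = Path(path)
    records: list[tuple[str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    except ValueError as exc:
        raise FastaFormatError(
            f"{path}: malformed {fmt} near record {len(records) + 1} "
            f"(approx. line {len(records) * (4 if fmt == 'fastq' else 2) + 1}): {exc}"
        ) from exc
    if not records:
        raise FastaFormatError(f"{path}: no reads found")
    return collapse_reads(records, min_len=min_len, max_len=max_len)


def write_reads_tsv(reads: ReadSet, path: str | Path) -> None:
    """Write a collapsed read table: columns seq, length, count."""
    with open(path, "w") as fh:
        fh.write("seq\tlength\tcount\n")
        for _, seq in reads.records:
            fh.write(f"{seq}\t{len(seq)}\t{reads.counts[seq]}\n")
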