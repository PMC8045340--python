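"""Synthetic genomes and small-RNA libraries with known ground truth.

The generator builds positive-sense genomes with the structure the
analysis modules assume — long partially overlapping plus-strand ORFs,
palm motifs planted in a chosen order inside a designated "replicase"
ORF, hydrophobic transmembrane islands inside a designated "membrane
protein" ORF — and small-RNA libraries with a configurable length mode,
strand balance, 5'-terminal A/U bias, positional hotspot and a background
of non-matching host reads. Every planted feature is recorded as truth,
so each pipeline stage can be tested by round-trip recovery without any
downloaded data.

Construction is write-then-repair: features are written into a random
background, then targeted point mutations (a) remove premature stops from
every planted reading frame and (b) disrupt any spurious plus-strand ORF
long enough to be called by the annotator. Repairs never touch protected
feature codons and respect per-region residue constraints (no D/N in the
motif-scan flanks, hydrophilic-only in the TM background), so planted
truth survives repair. Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import STOP_CODONS, annotate_genome, find_orfs
from .membrane import KYTE_DOOLITTLE, predict_tm
from .motifs import classify_order
from .seqio import (GenomeRecord, ReadSet, _FORWARD, collapse_reads, revcomp,
                    translate)

BASES = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
# flank alphabet inside the motif-scan region: no D (motifs A/C) and no N (motif B)
AA_FLANK = "ACEFGHIKLMPQRSTVWY"
# wildcard residues inside planted motifs: additionally no G/T, so a planted
# motif matches its own pattern in exactly one register
AA_MOTIF_X = "ACEFHIKLMPQRSVWY"
TM_ISLAND_RES = "L"
TM_BACKGROUND = "KR"

_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in _FORWARD.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for v in _CODONS_FOR.values():
    v.sort()


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class GenomeConfig:
    length: int = 8945
    gc: float = 0.45
    # 1-based inclusive (start, end); frame is implied by start
    orfs: list[tuple[int, int]] = field(default_factory=list)
    motif_order: str | None = None        # "A-B-C" | "C-A-B" | None
    motif_orf: int = 0                    # index into orfs
    motif_aa_start: int = 0               # 1-based aa position of the block
    tm_orf: int | None = None
    tm_islands: list[tuple[int, int]] = field(default_factory=list)  # 1-based aa
    polya_len: int = 0
    orf_min_codons: int = 150             # threshold used to hunt spurious ORFs
    seed: int = 0


@dataclass
class GenomeTruth:
    orfs: list[tuple[int, int, int]]               # (start, end, frame)
    utr5_len: int
    utr3_len: int
    overlaps: list[tuple[int, int, int]]           # (i, j, overlap_nt) consecutive
    motif_order: str | None
    motif_hits: dict[str, tuple[int, int]]         # aa (start, end) in motif ORF
    motif_orf: int
    tm_islands: list[tuple[int, int]]
    tm_orf: int | None


def motif_block(order: str, rng: np.random.Generator) -> tuple[str, dict[str, tuple[int, int]]]:
    """Build a compact motif block (gaps 7 and 9 aa) for a given order.

    Returns the residue string and 1-based (start, end) of each motif
    within the block. Layout and wildcard alphabet guarantee each motif
    matches its pattern at exactly one position inside the block.
    """
    def x(n: int) -> str:
        return "".join(rng.choice(list(AA_MOTIF_X), size=n))

    # gap residues share the wildcard alphabet (no D/N/G/T), so a
    # variable-width pattern cannot re-anchor one residue into a gap
    flank = x

    pieces = {
        "A": "D" + x(4) + "D",
        "B": "G" + x(2) + "T" + x(3) + "N",
        "C": "GDD",
    }
    names = order.split("-")
    if sorted(names) != ["A", "B", "C"]:
        raise ConfigError(f"bad motif order {order!r}")
    block = ""
    spans = {}
    for k, name in enumerate(names):
        if k:
            block += flank(7 if k == 1 else 9)
        spans[name] = (len(block) + 1, len(block) + len(pieces[name]))
        block += pieces[name]
    return block, spans


def _frame_of(start: int) -> int:
    return (start - 1) % 3 + 1


class _Builder:
    """Mutable genome under construction, with constraint-checked edits."""

    def __init__(self, cfg: GenomeConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        p_at = (1.0 - cfg.gc) / 2.0
        p_gc = cfg.gc / 2.0
        self.seq = list(rng.choice(list(BASES), size=cfg.length,
                                   p=[p_at, p_gc, p_gc, p_at]))
        self.protected: set[int] = set()          # 0-based positions
        self.claimed: set[int] = set()
        # per-ORF residue constraint masks, filled during planting:
        # aa index (0-based) -> allowed-check tag
        self.flank_mask: dict[int, np.ndarray] = {}   # orf idx -> bool per aa
        self.tm_bg_mask: dict[int, np.ndarray] = {}

    # -- constraint machinery -------------------------------------------------

    def _codon_at(self, orf: tuple[int, int], pos0: int) -> tuple[int, str]:
        start0 = orf[0] - 1
        ci = (pos0 - start0) // 3
        p = start0 + 3 * ci
        return ci, "".join(self.seq[p:p + 3])

    def _residue_ok(self, orf_idx: int, ci: int, res: str) -> bool:
        mask = self.flank_mask.get(orf_idx)
        if mask is not None and 0 < ci <= len(mask) and mask[ci - 1]:
            if res in "DN":
                return False
        mask = self.tm_bg_mask.get(orf_idx)
        if mask is not None and 0 < ci <= len(mask) and mask[ci - 1]:
            if KYTE_DOOLITTLE.get(res, 0.0) > 0.0:
                return False
        return True

    def can_set(self, pos0: int, base: str) -> bool:
        """Would setting seq[pos0] = base keep every planted ORF valid?"""
        if pos0 in self.protected or self.seq[pos0] == base:
            return False
        old = self.seq[pos0]
        self.seq[pos0] = base
        try:
            for k, (s, e) in enumerate(self.cfg.orfs):
                if not (s - 1 <= pos0 <= e - 1):
                    continue
                ci, codon = self._codon_at((s, e), pos0)
                n_codons = (e - s + 1) // 3
                if 0 < ci < n_codons - 1 and codon in STOP_CODONS:
                    return False
                res = "*" if codon in STOP_CODONS else _FORWARD.get(codon, "X")
                if 0 < ci < n_codons - 1 and not self._residue_ok(k, ci, res):
                    return False
            return True
        finally:
            self.seq[pos0] = old

    def try_set(self, pos0: int, base: str) -> bool:
        if self.can_set(pos0, base):
            self.seq[pos0] = base
            return True
        return False

    def write_codon_to_stop(self, p0: int) -> bool:
        """Convert the codon starting at p0 into a stop, if constraints allow."""
        for stop in ("TAA", "TAG", "TGA"):
            old = self.seq[p0:p0 + 3]
            changes = [(p0 + k, b) for k, b in enumerate(stop)
                       if self.seq[p0 + k] != b]
            if any(pos in self.protected for pos, _ in changes):
                continue
            for pos, b in changes:
                self.seq[pos] = b
            if self._stop_write_ok(p0):
                return True
            self.seq[p0:p0 + 3] = old
        return False

    def _stop_write_ok(self, p0: int) -> bool:
        """Validate all planted ORFs around positions p0..p0+2 post-write."""
        for k, (s, e) in enumerate(self.cfg.orfs):
            for pos0 in range(p0, p0 + 3):
                if not (s - 1 <= pos0 <= e - 1):
                    continue
                ci, codon = self._codon_at((s, e), pos0)
                n_codons = (e - s + 1) // 3
                if ci == 0 or ci == n_codons - 1:
                    if (ci == 0 and codon != "ATG") or \
                       (ci == n_codons - 1 and codon not in STOP_CODONS):
                        return False
                    continue
                if codon in STOP_CODONS:
                    return False
                res = _FORWARD.get(codon, "X")
                if not self._residue_ok(k, ci, res):
                    return False
        return True

    # -- feature planting -----------------------------------------------------

    def encode(self, aa: str) -> str:
        return "".join(self.rng.choice(_CODONS_FOR[ch]) for ch in aa)

    def plant_orf(self, idx: int, protein_interior: str) -> None:
        """Write ATG + interior codons + TAA; skip codons owned by earlier ORFs."""
        start, end = self.cfg.orfs[idx]
        s0, e0 = start - 1, end - 1
        n_codons = (end - start + 1) // 3
        if len(protein_interior) != n_codons - 2:
            raise ConfigError("interior length mismatch")
        for p, b in zip(range(s0, s0 + 3), "ATG"):
            if p in self.protected:
                raise ConfigError(f"ORF{idx + 1} start collides with a feature")
            self.seq[p] = b
        for p, b in zip(range(e0 - 2, e0 + 1), "TAA"):
            if p in self.protected:
                raise ConfigError(f"ORF{idx + 1} stop collides with a feature")
            self.seq[p] = b
        self.protected.update(range(s0, s0 + 3))
        self.protected.update(range(e0 - 2, e0 + 1))
        self.claimed.update(range(s0, s0 + 3))
        self.claimed.update(range(e0 - 2, e0 + 1))
        for ci, res in enumerate(protein_interior, start=1):
            p = s0 + 3 * ci
            span = range(p, p + 3)
            if any(q in self.claimed for q in span):
                continue  # earlier ORF owns part of this codon; repair later
            codon = self.rng.choice(_CODONS_FOR[res])
            for q, b in zip(span, codon):
                self.seq[q] = b
            self.claimed.update(span)

    def protect_aa(self, orf_idx: int, aa_start: int, aa_end: int) -> None:
        start = self.cfg.orfs[orf_idx][0]
        p0 = start - 1 + 3 * (aa_start - 1)
        p1 = start - 1 + 3 * aa_end
        self.protected.update(range(p0, p1))

    def plant_preceding_stop(self, idx: int) -> None:
        """Plant an in-frame stop directly upstream of an ORF start.

        Guarantees the annotator opens the ORF exactly at the planted ATG.
        Skipped silently when constraints forbid it (the spurious-ORF pass
        then disrupts any upstream extension instead).
        """
        start = self.cfg.orfs[idx][0]
        if start < 4:
            return
        if self.write_codon_to_stop(start - 4):
            self.protected.update(range(start - 4, start - 1))

    # -- repair ---------------------------------------------------------------

    def repair_internal_stops(self, max_sweeps: int = 5) -> None:
        for _ in range(max_sweeps):
            dirty = False
            for s, e in self.cfg.orfs:
                s0 = s - 1
                for p in range(s0 + 3, e - 3, 3):
                    if "".join(self.seq[p:p + 3]) not in STOP_CODONS:
                        continue
                    if not self._fix_stop(p):
                        raise ConfigError(
                            f"cannot remove internal stop at {p + 1}")
                    dirty = True
            if not dirty:
                return
        raise ConfigError("stop repair did not converge")

    def _fix_stop(self, p: int) -> bool:
        for pos in self.rng.permutation([p, p + 1, p + 2]):
            for b in self.rng.permutation(list(BASES)):
                if b != self.seq[pos] and self.try_set(int(pos), str(b)):
                    if "".join(self.seq[p:p + 3]) not in STOP_CODONS:
                        return True
        return False

    def suppress_spurious_orfs(self, max_rounds: int = 60) -> None:
        planted = {(s, e) for s, e in self.cfg.orfs}
        prev_extras: set[tuple[int, int]] | None = None
        for _ in range(max_rounds):
            record = GenomeRecord("tmp", "".join(self.seq))
            found = find_orfs(record, self.cfg.orf_min_codons)
            extras = [o for o in found if (o.start, o.end) not in planted]
            missing = planted - {(o.start, o.end) for o in found}
            if missing:
                raise ConfigError(f"planted ORFs lost during repair: {missing}")
            if not extras:
                return
            key = {(o.start, o.end) for o in extras}
            progress = any(self._disrupt(o.start, o.end, planted) for o in extras)
            if not progress and key == prev_extras:
                raise ConfigError(
                    f"cannot disrupt spurious ORFs {sorted(key)} without "
                    "breaking planted features")
            prev_extras = key
        raise ConfigError("spurious-ORF suppression did not converge")

    def _disrupt(self, start: int, end: int, planted: set) -> bool:
        """Try to break one spurious ORF with a safe point edit."""
        # an upstream extension of a planted ORF (same stop, earlier first
        # ATG) may only be edited before the planted start
        hi0 = end - 1 - 3            # 0-based; keep clear of the stop codon
        for ps, pe in planted:
            if pe == end and ps > start:
                hi0 = ps - 1 - 1     # 0-based last editable position
                break
        # cheapest: knock out the opening ATG
        for pos0 in (start - 1, start, start + 1):
            target = "ATG"[pos0 - (start - 1)]
            for b in BASES:
                if b != target and self.try_set(pos0, b):
                    return True
        # otherwise write an in-frame stop inside the editable window
        codon_starts = [p for p in range(start - 1 + 3, hi0 - 1, 3)]
        mid = (start - 1 + end) // 2
        codon_starts.sort(key=lambda p: abs(p - mid))
        for p in codon_starts:
            if self.write_codon_to_stop(p):
                return True
        return False


def gen_genome(cfg: GenomeConfig, validate: bool = True
               ) -> tuple[GenomeRecord, GenomeTruth]:
    """Generate a genome with planted ORFs/motifs/TM islands plus its truth."""
    if not cfg.orfs:
        raise ConfigError("no ORFs configured")
    orfs = sorted(cfg.orfs)
    if orfs != cfg.orfs:
        raise ConfigError("ORFs must be sorted by start")
    for s, e in orfs:
        if not (1 <= s < e <= cfg.length):
            raise ConfigError(f"ORF ({s}, {e}) outside genome")
        if (e - s + 1) % 3:
            raise ConfigError(f"ORF ({s}, {e}) span not divisible by 3")
        if (e - s + 1) // 3 < 3:
            raise ConfigError(f"ORF ({s}, {e}) too short")

    rng = np.random.default_rng(cfg.seed)
    b = _Builder(cfg, rng)

    # design each ORF's interior protein (aa 2 .. n-1); planted features are
    # written into these strings before encoding
    interiors: list[str] = []
    motif_spans: dict[str, tuple[int, int]] = {}
    for k, (s, e) in enumerate(orfs):
        plen = (e - s + 1) // 3 - 1   # protein length incl. initial M
        if k == cfg.motif_orf and cfg.motif_order:
            region_start = plen // 2 + 1   # default scan region: C-terminal half
            block, spans = motif_block(cfg.motif_order, rng)
            m0 = cfg.motif_aa_start
            if m0 <= region_start or m0 + len(block) - 1 > plen - 1:
                raise ConfigError(
                    f"motif block [{m0}, {m0 + len(block) - 1}] must sit inside "
                    f"the C-terminal half ({region_start}..{plen})")
            mask = np.zeros(plen - 1, dtype=bool)   # aa 2..plen
            mask[region_start - 2:] = True
            aa = []
            for i in range(2, plen + 1):
                pool = AA_FLANK if mask[i - 2] else AA20
                aa.append(str(rng.choice(list(pool))))
            aa = list("".join(aa))
            for name, (bs, be) in spans.items():
                motif_spans[name] = (m0 + bs - 1, m0 + be - 1)
            aa[m0 - 2:m0 - 2 + len(block)] = list(block)
            # planted motif codons must not be touched by repair
            interiors.append("".join(aa))
            self_mask = mask.copy()
            self_mask[m0 - 2:m0 - 2 + len(block)] = False
            b.flank_mask[k] = self_mask
        elif k == cfg.tm_orf:
            island_set = set()
            for a0, a1 in cfg.tm_islands:
                if a0 < 2 or a1 > plen or a0 > a1:
                    raise ConfigError(f"TM island ({a0}, {a1}) outside protein")
                island_set.update(range(a0, a1 + 1))
            aa = []
            for i in range(2, plen + 1):
                if i in island_set:
                    aa.append(TM_ISLAND_RES)
                else:
                    aa.append(str(rng.choice(list(TM_BACKGROUND))))
            interiors.append("".join(aa))
            mask = np.ones(plen - 1, dtype=bool)
            for i in island_set:
                mask[i - 2] = False
            b.tm_bg_mask[k] = mask
        else:
            interiors.append("".join(rng.choice(list(AA20), size=plen - 1)))

    # relax flank restriction where another planted feature overlaps the ORF:
    # those residues are dictated by the other frame, not by this protein
    for k, mask in b.flank_mask.items():
        s, e = orfs[k]
        for j, (s2, e2) in enumerate(orfs):
            if j == k:
                continue
            lo = max(s, s2 - 6)     # include the other ORF's preceding stop
            hi = min(e, e2)
            for pos in range(lo, hi + 1):
                ci = (pos - s) // 3
                if 0 < ci <= len(mask):
                    mask[ci - 1] = False

    for k in range(len(orfs)):
        b.plant_orf(k, interiors[k])
    if cfg.motif_order:
        for a0, a1 in motif_spans.values():
            b.protect_aa(cfg.motif_orf, a0, a1)
    if cfg.tm_orf is not None:
        for a0, a1 in cfg.tm_islands:
            b.protect_aa(cfg.tm_orf, a0, a1)
    for k in range(len(orfs)):
        b.plant_preceding_stop(k)
    b.repair_internal_stops()
    b.suppress_spurious_orfs()

    # keep the genome terminus distinct from an appended poly(A) tail so the
    # tail can be trimmed back to exactly the configured genome length
    if cfg.polya_len > 0 and orfs[-1][1] < cfg.length and b.seq[-1] == "A":
        b.seq[-1] = str(rng.choice(list("CGT")))
    seq = "".join(b.seq) + "A" * cfg.polya_len
    record = GenomeRecord("synthetic_genome", seq)
    overlaps = [(i + 1, i + 2, max(0, orfs[i][1] - orfs[i + 1][0] + 1))
                for i in range(len(orfs) - 1)]
    truth = GenomeTruth(
        orfs=[(s, e, _frame_of(s)) for s, e in orfs],
        utr5_len=orfs[0][0] - 1,
        utr3_len=cfg.length - orfs[-1][1],
        overlaps=overlaps,
        motif_order=cfg.motif_order,
        motif_hits=motif_spans,
        motif_orf=cfg.motif_orf,
        tm_islands=list(cfg.tm_islands),
        tm_orf=cfg.tm_orf,
    )
    if validate:
        _validate_genome(record, truth, cfg)
    return record, truth


def _validate_genome(record: GenomeRecord, truth: GenomeTruth,
                     cfg: GenomeConfig) -> None:
    ann = annotate_genome(record, cfg.orf_min_codons,
                          polya_min_run=10 if cfg.polya_len >= 10 else None)
    got = [(o.start, o.end, o.frame) for o in ann.orfs]
    if got != truth.orfs:
        raise ConfigError(f"annotation round-trip failed: {got} != {truth.orfs}")
    if cfg.motif_order:
        prot = ann.orfs[cfg.motif_orf].protein.seq
        res = classify_order(prot)
        if res.order != cfg.motif_order:
            raise ConfigError(
                f"motif round-trip failed: {res.order} != {cfg.motif_order}")
        for name, (a0, a1) in truth.motif_hits.items():
            h = res.hits[name]
            if (h.start, h.end) != (a0, a1):
                raise ConfigError(f"motif {name} drifted: {(h.start, h.end)}")
    if cfg.tm_orf is not None and cfg.tm_islands:
        prot = ann.orfs[cfg.tm_orf].protein.seq
        segs = predict_tm(prot)
        if len(segs) != len(cfg.tm_islands):
            raise ConfigError(
                f"TM round-trip failed: {len(segs)} != {len(cfg.tm_islands)}")


def inlv1_like_config(seed: int = 0, polya_len: int = 0) -> GenomeConfig:
    """Genome configuration mirroring the published INLV1 organization.

    Length 8945 nt, ORF1 at 45-6908 (frame 3, 2287-aa product), a 263-nt
    ORF1/ORF2 overlap in different frames, a 98-nt 3' UTR, a permuted
    C-A-B palm-motif block in the C-terminal (RdRP) region of ORF1 and
    four transmembrane islands at aa 68-87 / 107-126 / 138-157 / 177-196
    of the ORF3 product. ORF2's end and ORF3's start are not published
    for INLV1 and are set to give a typical negevirus layout (514-aa
    ORF2, 204-aa ORF3, 42-nt intergenic region).
    """
    return GenomeConfig(
        length=8945,
        gc=0.45,
        orfs=[(45, 6908), (6646, 8190), (8233, 8847)],
        motif_order="C-A-B",
        motif_orf=0,
        motif_aa_start=1950,
        tm_orf=2,
        tm_islands=[(68, 87), (107, 126), (138, 157), (177, 196)],
        polya_len=polya_len,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# small-RNA library simulation
# ---------------------------------------------------------------------------

def default_length_dist() -> dict[int, float]:
    """18-30 nt length distribution with the observed 22-nt mode (0.69)."""
    return {18: 0.01, 19: 0.02, 20: 0.04, 21: 0.10, 22: 0.69, 23: 0.06,
            24: 0.03, 25: 0.02, 26: 0.01, 27: 0.01, 28: 0.005, 29: 0.003,
            30: 0.002}


@dataclass
class ReadConfig:
    n_viral: int = 20_000
    n_background: int = 80_000
    length_dist: dict[int, float] = field(default_factory=default_length_dist)
    strand_prob: float = 0.5              # P(read from the plus strand)
    five_prime_au_prob: float = 0.8       # target P(5' nt in {A, U})
    hotspot: tuple[int, int, float] | None = None   # (start, end, multiplier)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"length_dist sums to {total}, not 1")
        for p in (self.strand_prob, self.five_prime_au_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")


@dataclass
class SimulatedReads:
    records: list[tuple[str, str]]        # (id, seq), generation order shuffled
    truth: pd.DataFrame                   # read_id, origin, strand, start, length

    def readset(self, min_len: int = 18, max_len: int = 30) -> ReadSet:
        return collapse_reads(self.records, min_len, max_len)


def gen_reads(genome: GenomeRecord, cfg: ReadConfig,
              max_attempts: int = 1000) -> SimulatedReads:
    """Simulate a small-RNA library from a genome.

    Viral reads are exact substrings of the genome (or its reverse
    complement), with lengths drawn from ``length_dist``, strand
    Bernoulli(``strand_prob``) and start positions uniform or
    hotspot-weighted; per read, positions are rejection-sampled until the
    5'-terminal nucleotide matches a Bernoulli(``five_prime_au_prob``)
    A/U-class draw. Background reads are random sequences verified to
    match neither genome strand. The truth table records every read's
    origin, strand, placement and length.
    """
    gseq = genome.seq
    grc = revcomp(gseq)
    L = len(gseq)
    lens = sorted(cfg.length_dist)
    if L <= max(lens):
        raise ConfigError("genome shorter than the longest read")
    probs = np.array([cfg.length_dist[k] for k in lens])
    rng = np.random.default_rng(cfg.seed)

    weights = np.ones(L)
    if cfg.hotspot is not None:
        h0, h1, mult = cfg.hotspot
        if not (1 <= h0 <= h1 <= L) or mult <= 0:
            raise ConfigError(f"bad hotspot {cfg.hotspot}")
        weights[h0 - 1:h1] = mult
    cum = np.cumsum(weights)
    cum /= cum[-1]

    records: list[tuple[str, str]] = []
    rows = []
    lengths = rng.choice(lens, p=probs, size=cfg.n_viral)
    plus = rng.random(cfg.n_viral) < cfg.strand_prob
    want_au = rng.random(cfg.n_viral) < cfg.five_prime_au_prob
    for i in range(cfg.n_viral):
        k = int(lengths[i])
        strand = "+" if plus[i] else "-"
        for attempt in range(max_attempts):
            start0 = int(np.searchsorted(cum, rng.random()))
            if start0 > L - k:
                continue
            nt5 = gseq[start0] if strand == "+" else grc[L - (start0 + k)]
            if (nt5 in "AT") == bool(want_au[i]):
                break
        else:
            raise ConfigError(
                "rejection sampling failed; genome may lack the requested "
                "5'-terminal composition")
        sub = gseq[start0:start0 + k]
        seq = sub if strand == "+" else revcomp(sub)
        rid = f"v{i + 1:06d}"
        records.append((rid, seq))
        rows.append((rid, "viral", strand, start0 + 1, k))

    bg_lens = rng.integers(min(lens), max(lens) + 1, size=cfg.n_background)
    lut = np.array(list(BASES))
    bg_chars = lut[rng.integers(0, 4, size=(cfg.n_background, max(lens)))]
    for i in range(cfg.n_background):
        k = int(bg_lens[i])
        seq = "".join(bg_chars[i, :k])
        for attempt in range(max_attempts):
            if seq not in gseq and seq not in grc:
                break
            seq = "".join(lut[rng.integers(0, 4, size=k)])
        else:
            raise ConfigError("cannot generate a non-matching background read")
        rid = f"b{i + 1:06d}"
        records.append((rid, seq))
        rows.append((rid, "background", ".", 0, k))

    order = rng.permutation(len(records))
    records = [records[int(j)] for j in order]
    truth = pd.DataFrame([rows[int(j)] for j in order],
                         columns=["read_id", "origin", "strand", "start",
                                  "length"])
    return SimulatedReads(records, truth)


def write_reads_fastq(sim: SimulatedReads, path) -> None:
    """Write simulated reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in sim.records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_reads_fasta(sim: SimulatedReads, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in sim.records:
            fh.write(f">{rid}\n{seq}\n")
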