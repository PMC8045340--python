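"""RdRP palm-motif scanning and motif-order (canonical vs permuted) calls.

The palm subdomain of viral RNA-dependent RNA polymerases carries three
catalytic motifs: A ``D-x(4,5)-D``, B ``G-x(2,3)-T-x(3)-N`` and C ``GDD``.
In most (+)ssRNA viruses they occur in the canonical order A-B-C along the
chain, but several nege/kita-like lineages carry a circularly permuted
palm with order C-A-B. Classifying the order is a quick lineage marker:
canonical in Nelorpivirus/Aphiglyvirus and the plant kita-/virga-like
viruses, permuted in Centivirus/Sandewavirus.

A wildcard position matches the 20 standard residues only; ``X`` (unknown)
never satisfies a pattern position, fixed or wild.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .seqio import AA_STANDARD

_STANDARD = frozenset(AA_STANDARD)

# Each motif is a set of concrete templates: a fixed residue, or None for
# a single-residue wildcard. Variable-width gaps are expanded to all widths.
MOTIF_TEMPLATES: dict[str, list[tuple[str | None, ...]]] = {
    "A": [("D",) + (None,) * g + ("D",) for g in (4, 5)],
    "B": [("G",) + (None,) * g + ("T",) + (None,) * 3 + ("N",) for g in (2, 3)],
    "C": [("G", "D", "D")],
}

MOTIF_NAMES = ("A", "B", "C")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int   # 1-based aa position
    end: int     # 1-based inclusive
    matched: str


@dataclass
class MotifOrderResult:
    """Chosen motif triple (if any) and the inferred palm architecture."""

    order: str                       # "A-B-C" | "C-A-B" | other | "undetermined"
    hits: dict[str, MotifHit] | None
    all_candidates: dict[str, int] = field(default_factory=dict)
    region: tuple[int, int] | None = None

    @property
    def is_permuted(self) -> bool:
        return self.order == "C-A-B"


def _matches(window: str, template: tuple[str | None, ...]) -> bool:
    for ch, t in zip(window, template):
        if t is None:
            if ch not in _STANDARD:
                return False
        elif ch != t:
            return False
    return True


def scan_motif(protein: str, motif: str) -> list[MotifHit]:
    """All matches of one motif, including overlapping alternatives.

    Returns hits sorted by (start, end), 1-based inclusive coordinates.
    """
    if not protein:
        raise ValueError("empty protein")
    templates = MOTIF_TEMPLATES[motif]
    hits = []
    for tmpl in templates:
        w = len(tmpl)
        for i in range(len(protein) - w + 1):
            if _matches(protein[i:i + w], tmpl):
                hits.append(MotifHit(motif, i + 1, i + w, protein[i:i + w]))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def classify_order(protein: str, region: tuple[int, int] | None = None,
                   gap_min: int = 5, gap_max: int = 300) -> MotifOrderResult:
    """Infer the palm-motif order of a (putative) RdRP.

    Scanning is restricted to ``region`` (1-based inclusive, default the
    C-terminal half of the protein, where the RdRP domain of the long
    replicase ORF sits). Candidate triples take one hit per motif, mutually
    non-overlapping, with the gap between consecutive chosen motifs within
    ``[gap_min, gap_max]`` residues; the surviving triple of minimal span
    is chosen (ties broken toward the leftmost triple). With no surviving
    triple the order is "undetermined".
    """
    if region is None:
        region = (len(protein) // 2 + 1, len(protein))
    lo, hi = region
    if not (1 <= lo <= hi <= len(protein)):
        raise ValueError(f"region {region} outside protein of length {len(protein)}")
    sub = protein[lo - 1:hi]
    per_motif = {}
    for m in MOTIF_NAMES:
        per_motif[m] = [MotifHit(m, h.start + lo - 1, h.end + lo - 1, h.matched)
                        for h in scan_motif(sub, m)]
    counts = {m: len(per_motif[m]) for m in MOTIF_NAMES}
    if any(counts[m] == 0 for m in MOTIF_NAMES):
        return MotifOrderResult("undetermined", None, counts, region)

    best: tuple[int, tuple[int, ...]] | None = None  # (span, starts-key)
    best_triple: tuple[MotifHit, MotifHit, MotifHit] | None = None
    for a, b, c in product(per_motif["A"], per_motif["B"], per_motif["C"]):
        trio = sorted((a, b, c), key=lambda h: h.start)
        # mutual non-overlap and spacing bounds between consecutive motifs
        ok = True
        for u, v in zip(trio, trio[1:]):
            gap = v.start - u.end - 1
            if gap < gap_min or gap > gap_max:
                ok = False
                break
        if not ok:
            continue
        span = trio[-1].end - trio[0].start + 1
        key = (span, (a.start, b.start, c.start))
        if best is None or key < best:
            best = key
            best_triple = (a, b, c)
    if best_triple is None:
        return MotifOrderResult("undetermined", None, counts, region)
    a, b, c = best_triple
    ordered = sorted((a, b, c), key=lambda h: h.start)
    order = "-".join(h.motif for h in ordered)
    return MotifOrderResult(order, {"A": a, "B": b, "C": c}, counts, region)


def hits_to_tsv(result: MotifOrderResult, protein: str) -> str:
    """TSV report: motif, start, end, matched, chosen flag."""
    chosen = {(h.motif, h.start, h.end) for h in (result.hits or {}).values()}
    lo, hi = result.region or (1, len(protein))
    lines = ["motif\tstart\tend\tmatched\tchosen"]
    sub = protein[lo - 1:hi]
    for m in MOTIF_NAMES:
        for h in scan_motif(sub, m):
            s, e = h.start + lo - 1, h.end + lo - 1
            flag = int((m, s, e) in chosen)
            lines.append(f"{m}\t{s}\t{e}\t{h.matched}\t{flag}")
    return "\n".join(lines) + "\n"
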