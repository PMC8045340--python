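"""Pairwise percent identity (global alignment) and NJ clustering.

Percent identities between RdRP domains, at both amino-acid and
nucleotide level, are the standard first-pass homology measure for
placing a new nege/kita-like virus among its relatives. This module
computes them with affine-gap Needleman-Wunsch global alignment, stores
them in symmetric labeled matrices, and clusters taxa with
Saitou-Nei neighbor joining on ``d = (100 - identity) / 100``.

The identity denominator is configurable because published matrices
rarely state theirs: ``"nogap"`` (columns where neither sequence is
gapped; default), ``"shorter"`` (length of the shorter sequence) or
``"alignment"`` (all columns).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .seqio import AA_STANDARD, DNA_ALPHABET

_PACKAGED_TABLE = Path(__file__).parent / "data" / "rdrp_identity_18taxa.tsv"


@dataclass
class ScoringScheme:
    kind: str                      # "protein" | "nucleotide"
    substitution: object           # matrix name (str) or (match, mismatch)
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "nucleotide"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


def protein_scheme() -> ScoringScheme:
    return ScoringScheme("protein", "BLOSUM62", 10.0, 0.5)


def nucleotide_scheme() -> ScoringScheme:
    return ScoringScheme("nucleotide", (5.0, -4.0), 10.0, 0.5)


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_aligned_cols: int   # columns with no gap in either row

    def validate(self, a: str, b: str) -> None:
        assert self.aligned_a.replace("-", "") == a
        assert self.aligned_b.replace("-", "") == b
        assert self.n_identical <= self.n_aligned_cols


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    if isinstance(scheme.substitution, str):
        al.substitution_matrix = substitution_matrices.load(scheme.substitution)
    else:
        match, mismatch = scheme.substitution
        al.match_score = match
        al.mismatch_score = mismatch
    # first gap residue costs gap_open, each further residue gap_extend
    al.open_gap_score = -scheme.gap_open
    al.extend_gap_score = -scheme.gap_extend
    return al


def _check_alphabet(seq: str, scheme: ScoringScheme) -> None:
    if scheme.kind == "nucleotide":
        bad = set(seq) - DNA_ALPHABET
    else:
        bad = set(seq) - set(AA_STANDARD + "X")
    if bad:
        raise ValueError(f"sequence/scheme alphabet mismatch: {sorted(bad)}")


def global_align(a: str, b: str, scheme: ScoringScheme) -> PairwiseAlignment:
    """Optimal affine-gap global alignment with deterministic traceback."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    _check_alphabet(a, scheme)
    _check_alphabet(b, scheme)
    best = _aligner(scheme).align(a, b)[0]
    ra, rb = best[0], best[1]
    n_id = n_cols = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            n_cols += 1
            if x == y:
                n_id += 1
    aln = PairwiseAlignment(ra, rb, float(best.score), n_id, n_cols)
    aln.validate(a, b)
    return aln


def percent_identity(aln: PairwiseAlignment, denominator: str = "nogap") -> float:
    """Percent identity of an alignment, rounded to one decimal."""
    if denominator == "nogap":
        denom = aln.n_aligned_cols
    elif denominator == "shorter":
        denom = min(len(aln.aligned_a.replace("-", "")),
                    len(aln.aligned_b.replace("-", "")))
    elif denominator == "alignment":
        denom = len(aln.aligned_a)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ZeroDivisionError("undefined identity: no aligned columns")
    return round(100.0 * aln.n_identical / denom, 1)


@dataclass
class IdentityMatrix:
    """Symmetric aa and/or nt percent-identity matrices over labeled taxa."""

    labels: list[str]
    aa: pd.DataFrame | None = None
    nt: pd.DataFrame | None = None

    def validate(self) -> None:
        for name, m in (("aa", self.aa), ("nt", self.nt)):
            if m is None:
                continue
            assert list(m.index) == self.labels == list(m.columns)
            v = m.to_numpy(float)
            assert np.allclose(v, v.T, atol=1e-9), f"{name} matrix not symmetric"
            assert (v >= 0).all() and (v <= 100).all()

    def distances(self, which: str = "aa") -> pd.DataFrame:
        m = getattr(self, which)
        if m is None:
            raise ValueError(f"no {which} matrix present")
        d = (100.0 - m.to_numpy(float)) / 100.0
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=self.labels, columns=self.labels)


def build_identity_matrix(aa_seqs: dict[str, str] | None = None,
                          nt_seqs: dict[str, str] | None = None,
                          aa_scheme: ScoringScheme | None = None,
                          nt_scheme: ScoringScheme | None = None,
                          denominator: str = "nogap") -> IdentityMatrix:
    """Align all unordered pairs and assemble symmetric identity matrices."""
    if not aa_seqs and not nt_seqs:
        raise ValueError("no sequences given")
    labels = list(aa_seqs or nt_seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    if aa_seqs and nt_seqs and set(aa_seqs) != set(nt_seqs):
        missing = set(aa_seqs) ^ set(nt_seqs)
        raise ValueError(f"labels missing from one input: {sorted(missing)}")

    def matrix(seqs: dict[str, str], scheme: ScoringScheme) -> pd.DataFrame:
        absent = [l for l in labels if l not in seqs]
        if absent:
            raise ValueError(f"missing sequences for labels: {absent}")
        m = pd.DataFrame(100.0, index=labels, columns=labels)
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                pid = percent_identity(
                    global_align(seqs[la], seqs[lb], scheme), denominator)
                m.loc[la, lb] = m.loc[lb, la] = pid
        return m

    out = IdentityMatrix(labels)
    if aa_seqs:
        out.aa = matrix(aa_seqs, aa_scheme or protein_scheme())
    if nt_seqs:
        out.nt = matrix(nt_seqs, nt_scheme or nucleotide_scheme())
    out.validate()
    return out


def parse_identity_table(path: str | Path | None = None) -> IdentityMatrix:
    """Parse a half-triangle identity table (upper = aa, lower = nt).

    With no path, loads the packaged 18-taxon RdRP identity table for
    INLV1 and its nege/kita-like relatives. Diagonal cells may be ``*``
    or empty and are set to 100 in both matrices.
    """
    path = Path(path) if path is not None else _PACKAGED_TABLE
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    labels = [str(x) for x in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ValueError("row and column labels differ")
    n = len(labels)
    aa = np.full((n, n), 100.0)
    nt = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(n):
            cell = df.iat[i, j]
            val = None if (pd.isna(cell) or str(cell).strip() in ("", "*")) \
                else float(cell)
            if i == j:
                if val is not None and val != 100.0:
                    raise ValueError(f"non-100 diagonal at {labels[i]}")
                continue
            if val is None:
                raise ValueError(f"missing value at ({labels[i]}, {labels[j]})")
            if j > i:
                aa[i, j] = aa[j, i] = val
            else:
                nt[i, j] = nt[j, i] = val
    out = IdentityMatrix(labels,
                         aa=pd.DataFrame(aa, index=labels, columns=labels),
                         nt=pd.DataFrame(nt, index=labels, columns=labels))
    out.validate()
    return out


@dataclass
class NjTree:
    tree: TreeNode
    clamped: bool   # True when negative NJ branch lengths were set to 0

    def to_newick(self) -> str:
        for node in self.tree.traverse():
            if node.length is not None:
                node.length = round(float(node.length), 6)
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()


def nj_tree(m: IdentityMatrix, which: str = "aa") -> NjTree:
    """Neighbor joining on ``(100 - identity)/100`` distances.

    Standard Saitou-Nei Q-criterion (via scikit-bio); ties resolved
    deterministically by label order; negative branch lengths are clamped
    to zero and flagged.
    """
    d = m.distances(which)
    if len(m.labels) < 3:
        raise ValueError("need >= 3 taxa for NJ")
    dm = DistanceMatrix(d.to_numpy(float), m.labels)
    raw = _skbio_nj(dm, neg_as_zero=False)
    clamped = any(n.length is not None and n.length < 0 for n in raw.traverse())
    tree = _skbio_nj(dm, neg_as_zero=True)
    return NjTree(tree, clamped)


def smallest_clade_with(njt: NjTree, label: str) -> set[str]:
    """Leaf names of the smallest clade (tip's parent subtree) holding label."""
    tip = njt.tree.find(label)
    return {t.name for t in tip.parent.tips()}
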