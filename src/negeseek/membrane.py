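"""Hydropathy-based transmembrane segment prediction.

The ORF3 product of nege/kita-like viruses carries the SP24 virion
membrane-protein domain, typically with four transmembrane helices. This
module predicts TM segments with the classic sliding-window approach: a
Kyte-Doolittle hydropathy profile (window 19) thresholded at 1.6, with
each above-threshold run of window centers expanded to the full window
extent and overlapping/abutting extents merged. This is a declared,
transparent scanner, not an HMM, so predicted boundaries are approximate
(a few residues) rather than exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

KD_MIN = min(KYTE_DOOLITTLE.values())   # -4.5 (Arg)
KD_MAX = max(KYTE_DOOLITTLE.values())   # 4.5 (Ile)


@dataclass
class HydropathyProfile:
    values: np.ndarray    # windowed mean per center
    window: int
    positions: np.ndarray  # 1-based center positions


@dataclass
class TmSegment:
    start: int    # 1-based aa
    end: int      # inclusive
    peak: float   # max windowed hydropathy among the segment's centers


def hydropathy_profile(protein: str, window: int = 19) -> HydropathyProfile:
    """Sliding mean of Kyte-Doolittle hydropathy (``X`` scored 0)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if "*" in protein:
        raise ValueError("protein contains a stop character")
    if len(protein) < window:
        raise ValueError(f"window {window} exceeds protein length {len(protein)}")
    raw = np.array([KYTE_DOOLITTLE.get(ch, 0.0) for ch in protein])
    kernel = np.ones(window) / window
    values = np.convolve(raw, kernel, mode="valid")
    half = window // 2
    positions = np.arange(half + 1, len(protein) - half + 1)
    return HydropathyProfile(values, window, positions)


def predict_tm(protein: str, window: int = 19,
               threshold: float = 1.6) -> list[TmSegment]:
    """Predict transmembrane segments from the hydropathy profile.

    Maximal runs of window centers with mean hydropathy >= ``threshold``
    are expanded to the full window extent; runs whose expanded extents
    overlap or abut are merged. Returns non-overlapping segments sorted
    by start (possibly empty).
    """
    prof = hydropathy_profile(protein, window)
    half = window // 2
    above = prof.values >= threshold
    segments: list[TmSegment] = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        start = int(prof.positions[i]) - half
        end = int(prof.positions[j]) + half
        peak = float(prof.values[i:j + 1].max())
        if segments and start <= segments[-1].end + 1:
            prev = segments[-1]
            segments[-1] = TmSegment(prev.start, end, max(prev.peak, peak))
        else:
            segments.append(TmSegment(start, end, peak))
        i = j + 1
    return segments


def segments_to_tsv(segments: list[TmSegment]) -> str:
    lines = ["start\tend\tlength\tpeak"]
    for s in segments:
        lines.append(f"{s.start}\t{s.end}\t{s.end - s.start + 1}\t{s.peak:.3f}")
    return "\n".join(lines) + "\n"
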