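"""TAD interaction scores and the directionality index.

Given two TADs A and B spanning matrix windows a'..a'' and b'..b'' of an
n x n contact matrix C, the intraTAD score of A sums the upper triangle
of its diagonal block (sum over i in [a', a''], j in [i, a'']) and the
interTAD score of (A, B) sums the full rectangular block between them.
Neighbor-TAD log-ratios compare interTAD scores between two conditions
for each TAD against up to 10 flanking TADs per side, leaving out TADs
smaller than 200 kb.

The directionality index (DI) contrasts, per bin, the contact sums A
(upstream) and B (downstream) within a fixed window (2 Mb by default):
with E = (A+B)/2,

    DI = sign(B - A) * [ (A-E)^2/E + (B-E)^2/E ]

DI changes sign at TAD boundaries; aligning DI profiles on 5' TAD borders
summarizes boundary strength genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ContactMatrix, GenomicInterval

__all__ = [
    "DIProfile",
    "tad_bin_span",
    "intra_tad_score",
    "inter_tad_score",
    "neighbor_tad_ratios",
    "directionality_index",
    "align_di_at_borders",
]


@dataclass
class DIProfile:
    chrom: str
    bin_size: int
    di: np.ndarray  # NaN where masked (edges, empty windows)
    upstream: np.ndarray  # A component, kept for audit
    downstream: np.ndarray  # B component
    window: int

    def __len__(self) -> int:
        return len(self.di)


def tad_bin_span(matrix: ContactMatrix, tad: GenomicInterval) -> tuple[int, int]:
    """Inclusive bin span (a', a'') of bins whose centers fall in the TAD."""
    bs = matrix.bin_size
    centers = (np.arange(matrix.n_bins) + 0.5) * bs
    inside = np.flatnonzero((centers >= tad.start) & (centers < tad.end))
    if inside.size == 0:
        raise ValueError(f"TAD {tad} covers no bin center")
    return int(inside[0]), int(inside[-1])


def intra_tad_score(matrix: ContactMatrix, tad: GenomicInterval) -> float:
    """Upper-triangle block sum: sum_{i=a'}^{a''} sum_{j=i}^{a''} C_ij."""
    a0, a1 = tad_bin_span(matrix, tad)
    block = matrix.values[a0 : a1 + 1, a0 : a1 + 1]
    return float(np.triu(block).sum())


def inter_tad_score(
    matrix: ContactMatrix, tad_a: GenomicInterval, tad_b: GenomicInterval
) -> float:
    """Rectangular block sum: sum_{i=a'}^{a''} sum_{j=b'}^{b''} C_ij."""
    a0, a1 = tad_bin_span(matrix, tad_a)
    b0, b1 = tad_bin_span(matrix, tad_b)
    if not (a1 < b0 or b1 < a0):
        raise ValueError("interTAD score requires disjoint TADs")
    return float(matrix.values[a0 : a1 + 1, b0 : b1 + 1].sum())


def neighbor_tad_ratios(
    matrix_a: ContactMatrix,
    matrix_b: ContactMatrix,
    tads: list[GenomicInterval],
    flank_count: int = 10,
    min_size: int = 200_000,
) -> pd.DataFrame:
    """log2 interTAD ratio between conditions for flanking TAD pairs.

    TADs smaller than ``min_size`` are excluded entirely. For each kept
    TAD and each of up to ``flank_count`` following kept TADs (each pair
    visited once) the log2 ratio of interTAD scores in condition A over
    condition B is computed; pairs with a zero score in either condition
    are skipped and logged in the ``skipped`` column count.
    """
    kept = [t for t in sorted(tads, key=lambda t: t.start) if t.length >= min_size]
    rows = []
    for i, ta in enumerate(kept):
        for j in range(i + 1, min(i + 1 + flank_count, len(kept))):
            tb = kept[j]
            sa = inter_tad_score(matrix_a, ta, tb)
            sb = inter_tad_score(matrix_b, ta, tb)
            if sa <= 0 or sb <= 0:
                rows.append((i, j, np.nan, True))
                continue
            rows.append((i, j, np.log2(sa / sb), False))
    return pd.DataFrame(rows, columns=["tad_i", "tad_j", "log2_ratio", "skipped"])


def directionality_index(matrix: ContactMatrix, window: int = 2_000_000) -> DIProfile:
    """Per-bin directionality index with a fixed up/downstream window."""
    w = int(round(window / matrix.bin_size))
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    n = matrix.n_bins
    if w >= n:
        raise ValueError("window larger than the chromosome")
    up = np.full(n, np.nan)
    down = np.full(n, np.nan)
    di = np.full(n, np.nan)
    for i in range(n):
        if i - w < 0 or i + w >= n:
            continue  # full window does not fit: masked
        a = matrix.values[i, i - w : i].sum()
        b = matrix.values[i, i + 1 : i + w + 1].sum()
        up[i], down[i] = a, b
        tot = a + b
        if tot == 0:
            continue  # masked
        e = tot / 2.0
        stat = (a - e) ** 2 / e + (b - e) ** 2 / e
        di[i] = np.sign(b - a) * stat
    return DIProfile(
        chrom=matrix.chrom,
        bin_size=matrix.bin_size,
        di=di,
        upstream=up,
        downstream=down,
        window=window,
    )


def align_di_at_borders(
    profiles: dict[str, DIProfile],
    tads: list[GenomicInterval],
    flank: int = 100_000,
    reference: str | None = None,
) -> pd.DataFrame:
    """Mean DI profile around 5' TAD borders, per condition.

    DI values are stacked in +/- ``flank`` around every TAD's 5' border
    and averaged (NaN-aware); borders whose window leaves the chromosome
    are skipped. When ``reference`` names one condition, differential
    columns ``d_<cond>`` = condition - reference are added.

    Returns a DataFrame indexed by offset (bp relative to the border).
    """
    if not profiles:
        raise ValueError("need at least one DI profile")
    any_prof = next(iter(profiles.values()))
    bs = any_prof.bin_size
    fb = int(round(flank / bs))
    offsets = (np.arange(-fb, fb + 1)) * bs
    out = {"offset": offsets}
    for name, prof in profiles.items():
        if prof.bin_size != bs or len(prof) != len(any_prof):
            raise ValueError("DI profiles must share binning")
        stacks = []
        for tad in tads:
            b = int(tad.start // bs)
            if b - fb < 0 or b + fb >= len(prof):
                continue
            stacks.append(prof.di[b - fb : b + fb + 1])
        if not stacks:
            raise ValueError("no usable TAD borders")
        out[name] = np.nanmean(np.vstack(stacks), axis=0)
    df = pd.DataFrame(out).set_index("offset")
    if reference is not None:
        if reference not in profiles:
            raise ValueError(f"unknown reference condition {reference!r}")
        for name in profiles:
            if name != reference:
                df[f"d_{name}"] = df[name] - df[reference]
    return df
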