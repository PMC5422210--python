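"""Loop-list post-processing.

Loops join a 5' anchor to a 3' anchor on one chromosome. This module
merges flanking (near-duplicate) loop calls, annotates anchors with CTCF
site orientation (chromatin loops form almost exclusively between
convergent CTCF motifs, i.e. motifs pointing toward each other),
constructs candidate "extended" loops pairing the 5' anchor of one loop
with the 3' anchor of a farther loop, and summarizes loop lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval

__all__ = [
    "Loop",
    "OrientedSite",
    "merge_flanking_loops",
    "annotate_orientation",
    "extended_loops",
    "loop_length_stats",
]

ORIENTATIONS = ("convergent", "tandem", "divergent", "unassigned")


@dataclass
class Loop:
    anchor5: GenomicInterval
    anchor3: GenomicInterval
    resolution: int = 10_000
    source: str = "primary"
    orientation: str | None = None

    def __post_init__(self) -> None:
        if self.anchor5.chrom != self.anchor3.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if not self.anchor5.start < self.anchor3.start:
            raise ValueError("anchor5 must precede anchor3")

    @property
    def length(self) -> float:
        """Anchor-midpoint separation in bp."""
        return self.anchor3.midpoint - self.anchor5.midpoint

    def anchor_key(self) -> tuple:
        return (
            self.anchor5.start,
            self.anchor5.end,
            self.anchor3.start,
            self.anchor3.end,
        )


@dataclass(frozen=True)
class OrientedSite:
    """A CTCF site with mandatory motif orientation."""

    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in "+-":
            raise ValueError("oriented site requires strand + or -")

    @property
    def forward(self) -> bool:
        return self.interval.strand == "+"


def merge_flanking_loops(loops: list[Loop], tolerance_bins: int = 1) -> list[Loop]:
    """Merge loop calls whose corresponding anchors nearly coincide.

    Two loops merge when both their 5' and their 3' anchor midpoints lie
    within ``tolerance_bins`` x resolution of each other; merging is
    closed transitively and the merged loop's anchors span the union of
    the merged anchors.
    """
    if not loops:
        return []
    n = len(loops)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    m5 = np.array([lp.anchor5.midpoint for lp in loops])
    m3 = np.array([lp.anchor3.midpoint for lp in loops])
    for i in range(n):
        tol = tolerance_bins * loops[i].resolution
        close = (np.abs(m5 - m5[i]) <= tol) & (np.abs(m3 - m3[i]) <= tol)
        for j in np.flatnonzero(close):
            if j > i:
                union(i, int(j))
    groups: dict[int, list[Loop]] = {}
    for i, lp in enumerate(loops):
        groups.setdefault(find(i), []).append(lp)
    merged = []
    for members in groups.values():
        a5 = GenomicInterval(
            members[0].anchor5.chrom,
            min(lp.anchor5.start for lp in members),
            max(lp.anchor5.end for lp in members),
        )
        a3 = GenomicInterval(
            members[0].anchor3.chrom,
            min(lp.anchor3.start for lp in members),
            max(lp.anchor3.end for lp in members),
        )
        merged.append(Loop(a5, a3, resolution=members[0].resolution,
                           source=members[0].source))
    merged.sort(key=lambda lp: (lp.anchor5.start, lp.anchor3.start))
    return merged


def _anchor_strands(anchor: GenomicInterval, sites: list[OrientedSite]) -> set[str]:
    return {
        s.interval.strand for s in sites if s.interval.overlaps(anchor)
    }


def annotate_orientation(loops: list[Loop], sites: list[OrientedSite]) -> list[Loop]:
    """Classify loops by the CTCF orientation at their anchors (in place).

    An anchor has a unique orientation iff exactly one distinct strand
    overlaps it; only loops with a unique orientation at both anchors are
    classified. Convergent = 5' forward and 3' reverse (motifs pointing
    toward each other); tandem = equal strands; divergent = 5' reverse
    and 3' forward.
    """
    for lp in loops:
        s5 = _anchor_strands(lp.anchor5, sites)
        s3 = _anchor_strands(lp.anchor3, sites)
        if len(s5) != 1 or len(s3) != 1:
            lp.orientation = "unassigned"
            continue
        f5 = s5.pop() == "+"
        f3 = s3.pop() == "+"
        if f5 and not f3:
            lp.orientation = "convergent"
        elif f5 == f3:
            lp.orientation = "tandem"
        else:
            lp.orientation = "divergent"
    return loops


def extended_loops(primary: list[Loop], exclusion: float = 30_000.0) -> list[Loop]:
    """Candidate longer loops combining anchors of different primary loops.

    For every ordered pair (A, B) where B's 3' anchor lies beyond A's 3'
    anchor and B's 5' anchor is not within ``exclusion`` bp of A's 5'
    anchor (midpoint distance; < exclusion excludes, so the pair must not
    share a 5' anchor), the loop (A.anchor5, B.anchor3) is emitted.
    Duplicates and loops already present in ``primary`` are removed.
    """
    if len(primary) < 2:
        return []
    if len({lp.anchor5.chrom for lp in primary}) != 1:
        raise ValueError("extended loops are built per chromosome")
    m5 = np.array([lp.anchor5.midpoint for lp in primary])
    m3 = np.array([lp.anchor3.midpoint for lp in primary])
    # pair condition as vectorized boolean matrix: rows = A, cols = B
    beyond = m3[None, :] > m3[:, None]
    distinct5 = np.abs(m5[None, :] - m5[:, None]) >= exclusion
    a_idx, b_idx = np.nonzero(beyond & distinct5)
    primary_keys = {lp.anchor_key() for lp in primary}
    seen = set()
    out = []
    for a, b in zip(a_idx, b_idx):
        la, lb = primary[a], primary[b]
        key = (
            la.anchor5.start,
            la.anchor5.end,
            lb.anchor3.start,
            lb.anchor3.end,
        )
        if key in seen or key in primary_keys:
            continue
        seen.add(key)
        out.append(
            Loop(la.anchor5, lb.anchor3, resolution=la.resolution, source="extended")
        )
    out.sort(key=lambda lp: (lp.anchor5.start, lp.anchor3.start))
    return out


def loop_length_stats(
    loops: list[Loop], grid: np.ndarray | None = None
) -> tuple[float, pd.DataFrame]:
    """Median loop length and a Gaussian-kernel density of the lengths.

    Length is the anchor-midpoint separation. Returns (median_bp, density
    DataFrame with columns ``length`` and ``density``).
    """
    if not loops:
        raise ValueError("need at least one loop")
    lengths = np.array([lp.length for lp in loops], dtype=float)
    median = float(np.median(lengths))
    if grid is None:
        lo, hi = lengths.min(), lengths.max()
        pad = 0.25 * max(hi - lo, 1.0)
        grid = np.linspace(max(lo - pad, 0.0), hi + pad, 256)
    if len(lengths) > 1 and np.ptp(lengths) > 0:
        dens = stats.gaussian_kde(lengths)(grid)
    else:
        dens = np.zeros_like(grid, dtype=float)
        dens[np.argmin(np.abs(grid - lengths[0]))] = 1.0
    return median, pd.DataFrame({"length": grid, "density": dens})
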