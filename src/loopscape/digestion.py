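"""In-silico restriction digestion.

A genome sequence is cut at every occurrence of a restriction motif
(cut placed at the motif start, matching the 5' overhang chemistry of
enzymes like DpnII at GATC). The resulting fragment map drives two
workflows: 4C fragment-end analysis (first cutter DpnII, second cutter
Csp6I/GTAC; fragments without an internal second-cutter site are "blind"
and uninformative) and DamID, where GATC fragments are concatenated into
~50 kb extended fragments to reduce noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenomicInterval

__all__ = [
    "FragmentMap",
    "ExtendedGATCFragment",
    "digest",
    "classify_blind",
    "extend_gatc_fragments",
]

_IUPAC_UNAMBIGUOUS = set("ACGT")


def _motif_positions(sequence: str, motif: str) -> list[int]:
    """Start positions of all (possibly overlapping) motif occurrences.

    Ambiguity codes in the sequence never match.
    """
    positions = []
    start = 0
    while True:
        idx = sequence.find(motif, start)
        if idx == -1:
            break
        positions.append(idx)
        start = idx + 1
    return positions


@dataclass
class FragmentMap:
    """Restriction fragments tiling one chromosome sequence."""

    chrom: str
    sequence_length: int
    cuts: np.ndarray  # ordered first-enzyme cut positions
    fragments: list[GenomicInterval]
    blind: np.ndarray | None = None  # per-fragment flag, set by classify_blind
    excluded: np.ndarray | None = None  # unmappable-excluded flag

    def fragment_ends(self) -> np.ndarray:
        """Fragment-end positions (the cut sites), for 4C coverage."""
        return np.asarray(self.cuts)


@dataclass(frozen=True)
class ExtendedGATCFragment:
    """A run of concatenated GATC fragments (>= window unless terminal)."""

    interval: GenomicInterval
    n_fragments: int


def digest(sequence: str, motif: str, chrom: str = "chrS") -> FragmentMap:
    """Cut ``sequence`` at the start of every ``motif`` occurrence.

    Zero-length fragments from motifs at position 0 or from overlapping
    occurrences are dropped; the remaining fragments tile the sequence.
    """
    if len(motif) < 1:
        raise ValueError("motif must be non-empty")
    sequence = sequence.upper()
    motif = motif.upper()
    if set(motif) - _IUPAC_UNAMBIGUOUS:
        raise ValueError("ambiguous motif letters are not supported")
    n = len(sequence)
    if n == 0:
        return FragmentMap(chrom, 0, np.array([], dtype=int), [])
    cuts = _motif_positions(sequence, motif)
    bounds = [0] + cuts + [n]
    fragments = [
        GenomicInterval(chrom, a, b)
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]
    return FragmentMap(chrom, n, np.asarray(cuts, dtype=int), fragments)


def classify_blind(fmap: FragmentMap, second_motif: str, sequence: str) -> FragmentMap:
    """Flag fragments lacking the second enzyme's motif inside them.

    A fragment is blind iff no occurrence of ``second_motif`` is fully
    contained within it; blind fragments carry no informative 4C signal
    and are filtered before peak calling.
    """
    sequence = sequence.upper()
    if len(sequence) != fmap.sequence_length:
        raise ValueError("sequence does not match the fragment map")
    second = second_motif.upper()
    occ = np.asarray(_motif_positions(sequence, second), dtype=int)
    m = len(second)
    blind = np.ones(len(fmap.fragments), dtype=bool)
    for k, frag in enumerate(fmap.fragments):
        inside = occ[(occ >= frag.start) & (occ + m <= frag.end)]
        blind[k] = inside.size == 0
    fmap.blind = blind
    return fmap


def _overlap_len(a: GenomicInterval, lo: int, hi: int) -> int:
    return max(0, min(a.end, hi) - max(a.start, lo))


def extend_gatc_fragments(
    fmap: FragmentMap,
    window: int = 50_000,
    unmappable: list[GenomicInterval] | None = None,
    max_unmappable: int = 5_000,
) -> list[ExtendedGATCFragment]:
    """Concatenate GATC fragments left-to-right into >= ``window`` runs.

    Fragments overlapping any unmappable block longer than
    ``max_unmappable`` are dropped first. Concatenation is greedy: a new
    extended fragment starts once the cumulative constituent-fragment
    length reaches ``window``; the terminal run may be shorter. Every
    extended fragment starts and ends at a fragment boundary (a motif
    position or chromosome end).
    """
    unmappable = unmappable or []
    big_blocks = [u for u in unmappable if u.length > max_unmappable]
    excluded = np.zeros(len(fmap.fragments), dtype=bool)
    for k, frag in enumerate(fmap.fragments):
        for u in big_blocks:
            if _overlap_len(frag, u.start, u.end) > 0:
                excluded[k] = True
                break
    fmap.excluded = excluded

    out: list[ExtendedGATCFragment] = []
    run: list[GenomicInterval] = []
    run_len = 0
    for frag, drop in zip(fmap.fragments, excluded):
        if drop:
            continue
        run.append(frag)
        run_len += frag.length
        if run_len >= window:
            out.append(
                ExtendedGATCFragment(
                    GenomicInterval(fmap.chrom, run[0].start, run[-1].end),
                    n_fragments=len(run),
                )
            )
            run, run_len = [], 0
    if run:
        out.append(
            ExtendedGATCFragment(
                GenomicInterval(fmap.chrom, run[0].start, run[-1].end),
                n_fragments=len(run),
            )
        )
    return out
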