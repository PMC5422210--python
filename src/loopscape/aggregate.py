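"""Aggregate peak analysis (APA) and aggregate TAD analysis (ATA).

APA averages fixed-size contact-matrix windows centred on a set of 2D
coordinates (loop anchor pairs): with 10 kb bins and a 100 kb flank the
window spans 210 kb x 210 kb, i.e. a 21 x 21 submatrix. ATA instead
averages whole TADs: each TAD window is extended by 50% of the TAD size
on both borders and, because TADs vary in size, rescaled to a common
100 x 100 grid before averaging. Differential aggregates compare two
conditions normalized to the same matrix total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ContactMatrix, GenomicInterval

__all__ = [
    "AggregateResult",
    "apa",
    "ata",
    "differential_aggregate",
    "apa_loop_score",
]


@dataclass
class AggregateResult:
    matrix: np.ndarray  # mean submatrix
    n_used: int
    skipped: list = field(default_factory=list)  # coordinates left out, with reason

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def _coord_to_bins(matrix: ContactMatrix, coord) -> tuple[int, int]:
    """A 2D coordinate: (bp, bp) pair, a Loop, or a (bin, bin) int pair."""
    if hasattr(coord, "anchor5"):
        return (
            matrix.bin_index(coord.anchor5.midpoint),
            matrix.bin_index(coord.anchor3.midpoint),
        )
    a, b = coord
    return matrix.bin_index(a), matrix.bin_index(b)


def apa(
    matrix: ContactMatrix, coordinates, flank: int = 100_000
) -> AggregateResult:
    """Average contact submatrix around a set of 2D coordinates.

    The window extends ``flank`` bp on both sides of the coordinate, so
    the submatrix side is 2*flank/bin_size + 1 bins. Coordinates whose
    windows cross the matrix edge are skipped and logged, never padded.
    """
    f = int(round(flank / matrix.bin_size))
    w = 2 * f + 1
    acc = np.zeros((w, w))
    used = 0
    skipped = []
    for coord in coordinates:
        try:
            i, j = _coord_to_bins(matrix, coord)
        except IndexError:
            skipped.append((coord, "outside matrix"))
            continue
        if i - f < 0 or j - f < 0 or i + f >= matrix.n_bins or j + f >= matrix.n_bins:
            skipped.append((coord, "window crosses edge"))
            continue
        acc += matrix.values[i - f : i + f + 1, j - f : j + f + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable coordinates for APA")
    return AggregateResult(acc / used, used, skipped)


def _resize_bilinear(sub: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resize on bin-center coordinates; identity when sizes match."""
    m = sub.shape[0]
    if m == out_size:
        return sub.copy()
    scale = m / out_size
    centers = (np.arange(out_size) + 0.5) * scale - 0.5
    ii, jj = np.meshgrid(centers, centers, indexing="ij")
    return ndimage.map_coordinates(
        sub, [ii.ravel(), jj.ravel()], order=1, mode="nearest"
    ).reshape(out_size, out_size)


def ata(
    matrix: ContactMatrix,
    tads: list[GenomicInterval],
    extension: float = 0.5,
    out_size: int = 100,
    interpolation: str = "bilinear",
) -> AggregateResult:
    """Average rescaled TAD windows.

    Each TAD's borders are extended by ``extension`` x TAD size on both
    sides; the extended square submatrix is rescaled to
    ``out_size`` x ``out_size`` and the rescaled windows are averaged.
    TADs whose extended window leaves the matrix are skipped and logged.
    """
    acc = np.zeros((out_size, out_size))
    used = 0
    skipped = []
    for tad in tads:
        size = tad.length
        ext_start = tad.start - extension * size
        ext_end = tad.end + extension * size
        b0 = int(round(ext_start / matrix.bin_size))
        b1 = int(round(ext_end / matrix.bin_size))
        if b0 < 0 or b1 > matrix.n_bins or b1 - b0 < 2:
            skipped.append((tad, "extended window outside matrix"))
            continue
        sub = matrix.values[b0:b1, b0:b1]
        if interpolation == "nearest":
            idx = np.minimum(
                (np.arange(out_size) * sub.shape[0] // out_size), sub.shape[0] - 1
            )
            resized = sub[np.ix_(idx, idx)]
        else:
            resized = _resize_bilinear(sub, out_size)
        acc += resized
        used += 1
    if used == 0:
        raise ValueError("no usable TADs for ATA")
    return AggregateResult(acc / used, used, skipped)


def differential_aggregate(
    a: AggregateResult,
    b: AggregateResult,
    mode: str = "log2ratio",
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Signed comparison of two aggregates (positive where a > b).

    Inputs must come from matrices normalized to the same total. Modes:
    ``log2ratio`` (default, with pseudocount) or ``difference``.
    """
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("aggregate dimensions differ")
    if mode == "difference":
        return a.matrix - b.matrix
    if mode == "log2ratio":
        return np.log2((a.matrix + pseudocount) / (b.matrix + pseudocount))
    raise ValueError(f"unknown mode {mode!r}")


def apa_loop_score(result: AggregateResult, center_exclude: int | None = None) -> float:
    """Central-pixel enrichment over the surrounding region.

    Score = value of the center pixel divided by the mean of the pixels
    at Chebyshev distance > ``center_exclude`` from the center (default
    one quarter of the window size). Scores > 1 indicate focal
    enrichment at the aggregated coordinates.
    """
    w = result.size
    if w < 5:
        raise ValueError("aggregate too small for a loop score (need >= 5x5)")
    if center_exclude is None:
        center_exclude = w // 4
    c = w // 2
    ii, jj = np.meshgrid(np.arange(w), np.arange(w), indexing="ij")
    cheb = np.maximum(np.abs(ii - c), np.abs(jj - c))
    ring = cheb > center_exclude
    surround = result.matrix[ring].mean()
    if surround == 0:
        raise ValueError("surrounding region has zero mean")
    return float(result.matrix[c, c] / surround)
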