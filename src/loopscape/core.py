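"""Core containers and matrix-level transforms.

Genomic coordinates are 0-based, half-open throughout the package.
Contact matrices are dense, symmetric, intra-chromosomal; supported sizes
are bounded by memory (roughly <= 25,000 bins per chromosome at working
resolution), which is a documented contract of the dense representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ContactMatrix",
    "Track",
    "normalize_to_total",
    "observed_over_expected",
    "relative_contact_probability",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ContactMatrix:
    """Binned intra-chromosomal contact matrix.

    ``values[i, j]`` is the contact frequency between bins ``i`` and ``j``;
    the matrix must be symmetric (tolerance 1e-9) with nonnegative entries.
    The matrix total is the sum over the full symmetric matrix (each
    off-diagonal pair counted twice, the diagonal once).
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    resolution_tag: str = ""
    normalized_to: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if np.nanmax(np.abs(v - v.T), initial=0.0) > 1e-9:
            raise ValueError("contact matrix must be symmetric (tol 1e-9)")
        if np.nanmin(v, initial=0.0) < 0:
            raise ValueError("contact matrix entries must be nonnegative")
        self.values = v
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def bin_index(self, position: float) -> int:
        """Bin containing a base-pair position."""
        idx = int(position // self.bin_size)
        if not 0 <= idx < self.n_bins:
            raise IndexError(f"position {position} outside matrix bounds")
        return idx

    def covered_bins(self) -> np.ndarray:
        """Boolean mask of bins with any contact signal."""
        return self.values.sum(axis=0) > 0


@dataclass
class Track:
    """A per-position scalar signal (eigenvector, DI, DamID log-ratio).

    ``positions`` are bin starts (bp), strictly increasing; ``values`` may
    contain NaN for masked positions.
    """

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


def normalize_to_total(matrix: ContactMatrix, target_total: float = 100e6) -> ContactMatrix:
    """Scale a contact matrix so its full symmetric sum equals ``target_total``.

    Matrices from different conditions are brought to a common total
    (conventionally 100 million contacts) before any differential analysis.
    """
    total = matrix.total
    if total <= 0:
        raise ValueError("cannot normalize an all-zero contact matrix")
    scaled = matrix.values * (float(target_total) / total)
    return replace(matrix, values=scaled, normalized_to=float(target_total))


def observed_over_expected(matrix: ContactMatrix) -> ContactMatrix:
    """Divide each diagonal by its mean over covered bin pairs.

    The expected contact frequency at distance k is estimated as the mean
    of diagonal k over pairs of covered bins, so each diagonal of the
    result has mean 1 over those pairs. Diagonals with zero mean map to 0
    (with a warning) rather than NaN so downstream correlations stay
    defined.
    """
    n = matrix.n_bins
    if n < 2:
        raise ValueError("observed/expected requires at least 2 bins")
    v = matrix.values
    covered = matrix.covered_bins()
    out = np.zeros_like(v)
    zero_diags = []
    for k in range(n):
        diag = np.diagonal(v, offset=k)
        pair_mask = covered[: n - k] & covered[k:]
        if pair_mask.any():
            m = diag[pair_mask].mean()
        else:
            m = 0.0
        if m > 0:
            vals = diag / m
        else:
            vals = np.zeros_like(diag)
            zero_diags.append(k)
        idx = np.arange(n - k)
        out[idx, idx + k] = vals
        out[idx + k, idx] = vals
    if zero_diags:
        warnings.warn(
            f"{len(zero_diags)} diagonals had zero mean; set to 0",
            stacklevel=2,
        )
    return replace(matrix, values=out)


def _log_distance_bins(min_bp: float, max_bp: float, bins_per_decade: int) -> np.ndarray:
    lo, hi = np.log10(min_bp), np.log10(max_bp)
    n_edges = max(int(np.ceil((hi - lo) * bins_per_decade)) + 1, 2)
    return np.logspace(lo, hi, n_edges)


def relative_contact_probability(
    matrices: ContactMatrix | list[ContactMatrix],
    bins_per_decade: int = 10,
    edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Contact probability as a function of genomic distance.

    For each log-spaced distance bin the mean contact frequency per bin
    pair is computed and the curve is renormalized to sum to 1, making it
    invariant to overall sequencing depth. With several replicate matrices
    the mean curve and the standard error of the mean (SEM) across
    replicates are returned.

    Returns a DataFrame with columns ``distance`` (geometric midpoint, bp),
    ``probability``, ``sem``, ``n_pairs`` and ``empty`` (flag for distance
    bins containing no matrix diagonal).
    """
    if isinstance(matrices, ContactMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValueError("need at least one matrix")
    bs = matrices[0].bin_size
    n = matrices[0].n_bins
    if any(m.bin_size != bs or m.n_bins != n for m in matrices):
        raise ValueError("replicate matrices must share bin size and shape")
    if n < 3:
        raise ValueError("matrix too small for a distance curve")
    if edges is None:
        edges = _log_distance_bins(bs, (n - 1) * bs, bins_per_decade)
    edges = np.asarray(edges, dtype=float)
    mids = np.sqrt(edges[:-1] * edges[1:])
    n_dist = n - 1
    dist_bp = np.arange(1, n) * float(bs)
    which = np.digitize(dist_bp, edges) - 1
    valid = (which >= 0) & (which < len(mids))

    curves = np.zeros((len(matrices), len(mids)))
    pair_counts = np.zeros(len(mids))
    for r, m in enumerate(matrices):
        sums = np.array([np.diagonal(m.values, offset=k).sum() for k in range(1, n)])
        npairs = np.arange(n - 1, 0, -1, dtype=float)
        bin_sum = np.zeros(len(mids))
        bin_pairs = np.zeros(len(mids))
        np.add.at(bin_sum, which[valid], sums[valid])
        np.add.at(bin_pairs, which[valid], npairs[valid])
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_per_pair = np.where(bin_pairs > 0, bin_sum / bin_pairs, 0.0)
        tot = mean_per_pair.sum()
        curves[r] = mean_per_pair / tot if tot > 0 else mean_per_pair
        pair_counts = bin_pairs
    prob = curves.mean(axis=0)
    if len(matrices) > 1:
        sem = curves.std(axis=0, ddof=1) / np.sqrt(len(matrices))
    else:
        sem = np.zeros(len(mids))
    empty = pair_counts == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty distance bins (probability 0)", stacklevel=2)
    return pd.DataFrame(
        {
            "distance": mids,
            "probability": prob,
            "sem": sem,
            "n_pairs": pair_counts,
            "empty": empty,
        }
    )


def rcp_slope(curve: pd.DataFrame) -> float:
    """Log-log slope of an RCP curve (ignoring empty bins)."""
    from scipy import stats

    ok = (~curve["empty"]) & (curve["probability"] > 0)
    res = stats.linregress(
        np.log10(curve.loc[ok, "distance"]), np.log10(curve.loc[ok, "probability"])
    )
    return float(res.slope)
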