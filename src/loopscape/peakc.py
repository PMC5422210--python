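"""Multi-replicate 4C peak calling.

The model assumes the 4C background contact frequency decreases
monotonically with distance from the viewpoint, independently on the
upstream and downstream side. Per replicate the background is the
least-squares non-increasing fit of coverage against distance
(isotonic regression, solved exactly by pool-adjacent-violators). Each
fragment end is scored by both the ratio R = obs / background and the
difference D = obs - background: R catches strong relative enrichment at
low coverage, D catches large absolute gains where R stays modest.

Replicates are combined non-parametrically with the rank product: R and D
are ranked high-to-low, the average of the two ranks is ranked again to
give one rank per fragment per replicate, and the per-replicate ranks are
multiplied. With n fragments and k replicates the rank product r is
converted to a p-value through the Gamma approximation

    P = 1 - F_Gamma(k, 1)( -ln( r / (n+1)^k ) )

which is exact when ranks are continuous uniform on (0, n+1): -ln of a
product of k uniforms is Gamma(k)-distributed. For k = 1 it reduces to
the closed form P = r / (n+1). Exact enumeration of the discrete rank
product distribution is possible in principle but prohibitive for the
fragment counts seen in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .core import GenomicInterval

__all__ = [
    "FourCProfile",
    "PeakCResult",
    "fit_monotonic_background",
    "enrichment_stats",
    "combined_rank",
    "rank_product_p",
    "call_peaks",
    "peakc_analysis",
]


@dataclass
class FourCProfile:
    """Fragment-end coverage around one viewpoint, for one replicate."""

    viewpoint: GenomicInterval
    positions: np.ndarray  # fragment-end positions, strictly increasing (bp)
    counts: np.ndarray  # coverage per fragment end, >= 0
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.positions.shape != self.counts.shape:
            raise ValueError("positions and counts must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def viewpoint_center(self) -> float:
        return self.viewpoint.midpoint

    def sides(self) -> np.ndarray:
        """Per-fragment side label: -1 upstream, +1 downstream."""
        return np.where(self.positions < self.viewpoint_center, -1, 1)

    def exclusion_mask(self, exclusion_zone: float) -> np.ndarray:
        """True for fragments kept (outside the viewpoint exclusion zone)."""
        return np.abs(self.positions - self.viewpoint_center) >= exclusion_zone


@dataclass
class PeakCResult:
    """Per-fragment statistics of a multi-replicate peak-calling run."""

    viewpoint: GenomicInterval
    positions: np.ndarray  # n fragments (intersection across replicates)
    observed: np.ndarray  # (k, n)
    expected: np.ndarray  # (k, n) monotone background
    ratio: np.ndarray  # (k, n) R
    delta: np.ndarray  # (k, n) D
    ranks: np.ndarray  # (k, n) combined rank, 1 = most enriched
    rank_product: np.ndarray  # (n,)
    pvalue: np.ndarray  # (n,)
    n: int
    k: int
    significant: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions.astype(int)})
        for r in range(self.k):
            df[f"obs_{r + 1}"] = self.observed[r]
            df[f"bg_{r + 1}"] = self.expected[r]
            df[f"R_{r + 1}"] = self.ratio[r]
            df[f"delta_{r + 1}"] = self.delta[r]
            df[f"rank_{r + 1}"] = self.ranks[r]
        df["rank_product"] = self.rank_product
        df["pvalue"] = self.pvalue
        if self.significant is not None:
            df["significant"] = self.significant
        return df


def fit_monotonic_background(
    profile: FourCProfile, exclusion_zone: float = 0.0
) -> np.ndarray:
    """Least-squares non-increasing background per side of the viewpoint.

    Returns the expected coverage for every fragment of the profile
    (fragments inside the exclusion zone get NaN). A side with fewer than
    2 fragments keeps its observed values (degenerate fit) with a warning.
    """
    keep = profile.exclusion_mask(exclusion_zone)
    sides = profile.sides()
    expected = np.full(len(profile.positions), np.nan)
    dist = np.abs(profile.positions - profile.viewpoint_center)
    for side in (-1, 1):
        m = keep & (sides == side)
        if m.sum() == 0:
            continue
        if m.sum() < 2:
            warnings.warn(
                f"side {side:+d} has <2 fragments; background = observed",
                stacklevel=2,
            )
            expected[m] = profile.counts[m]
            continue
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        expected[m] = iso.fit_transform(dist[m], profile.counts[m])
    return expected


def enrichment_stats(
    observed: np.ndarray, expected: np.ndarray, eps: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Ratio R = obs / max(expected, eps) and difference D = obs - expected.

    The pseudocount ``eps`` (1 read by default) guards the ratio against
    zero background on sparse count data.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    ratio = observed / np.maximum(expected, eps)
    delta = observed - expected
    return ratio, delta


def combined_rank(ratio: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Rank fragments of one replicate by enrichment (1 = most enriched).

    R and D are each ranked high-to-low, the two ranks are averaged, and
    the averages are ranked again. Ties receive average ranks at every
    stage, so ranks may be half-integers.
    """
    r_rank = stats.rankdata(-np.asarray(ratio))
    d_rank = stats.rankdata(-np.asarray(delta))
    return stats.rankdata(0.5 * (r_rank + d_rank))


def rank_product_p(ranks: np.ndarray, n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rank product r and Gamma-approximation p-value per fragment.

    ``ranks`` has shape (k, n_fragments) with every entry in [1, n].
    """
    ranks = np.atleast_2d(np.asarray(ranks, dtype=float))
    if ranks.shape[0] != k:
        raise ValueError("ranks must have one row per replicate")
    if np.any(ranks < 1) or np.any(ranks > n):
        raise ValueError(f"ranks must lie in [1, {n}]")
    r = ranks.prod(axis=0)
    rho = r / (n + 1.0) ** k
    p = stats.gamma.sf(-np.log(rho), a=k)
    # worst-rank boundary: rho = 1 -> P = 1 exactly
    p = np.where(rho >= 1.0, 1.0, p)
    return r, p


def call_peaks(
    result: PeakCResult,
    alpha: float = 0.01,
    merge_gap: int = 1,
    min_fragments: int = 3,
    fragment_span: float | None = None,
) -> list[GenomicInterval]:
    """Segment significant fragments into peak intervals.

    Fragments with P < ``alpha`` are significant; runs of significant
    fragments separated by at most ``merge_gap`` non-significant fragments
    merge into one peak. Peaks supported by fewer than ``min_fragments``
    significant fragments are discarded — isolated significant fragments
    are expected by chance at any alpha and a real 4C interaction spans
    several restriction fragments.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sig = result.pvalue < alpha
    result.significant = sig
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return []
    # group significant fragments, allowing merge_gap intervening fragments
    groups: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if i - groups[-1][-1] <= merge_gap + 1:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])
    span = fragment_span
    if span is None:
        diffs = np.diff(result.positions)
        span = float(np.median(diffs)) if diffs.size else 1.0
    peaks = []
    for g in groups:
        if len(g) < min_fragments:
            continue
        start = result.positions[g[0]]
        end = result.positions[g[-1]] + span
        peaks.append(GenomicInterval(result.viewpoint.chrom, int(start), int(end)))
    return peaks


def peakc_analysis(
    profiles: list[FourCProfile],
    exclusion_zone: float = 10_000.0,
    eps: float = 1.0,
) -> PeakCResult:
    """Run the full multi-replicate analysis on a set of 4C profiles.

    Replicates are restricted to their common fragment set (logged when
    the sets differ); the viewpoint exclusion zone (default 10 kb) removes
    the overamplified fragments immediately around the viewpoint from both
    fitting and testing.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    vp = profiles[0].viewpoint
    common = set(profiles[0].positions.tolist())
    for p in profiles[1:]:
        if p.viewpoint != vp:
            raise ValueError("all replicates must share the viewpoint")
        common &= set(p.positions.tolist())
    if any(len(common) != len(p.positions) for p in profiles):
        warnings.warn(
            "replicates have unequal fragment sets; using the intersection",
            stacklevel=2,
        )
    keep_mask = profiles[0].exclusion_mask(exclusion_zone)
    positions = np.asarray(
        sorted(
            pos
            for pos, k in zip(profiles[0].positions, keep_mask)
            if k and pos in common
        )
    )
    n = len(positions)
    if n < 4:
        raise ValueError("too few fragments outside the exclusion zone")
    k = len(profiles)
    observed = np.empty((k, n))
    expected = np.empty((k, n))
    ratio = np.empty((k, n))
    delta = np.empty((k, n))
    ranks = np.empty((k, n))
    for r, prof in enumerate(profiles):
        sel = np.isin(prof.positions, positions)
        sub = FourCProfile(
            vp, prof.positions[sel], prof.counts[sel], replicate=prof.replicate
        )
        bg = fit_monotonic_background(sub)
        observed[r] = sub.counts
        expected[r] = bg
        ratio[r], delta[r] = enrichment_stats(sub.counts, bg, eps=eps)
        ranks[r] = combined_rank(ratio[r], delta[r])
    rp, pval = rank_product_p(ranks, n=n, k=k)
    return PeakCResult(
        viewpoint=vp,
        positions=positions,
        observed=observed,
        expected=expected,
        ratio=ratio,
        delta=delta,
        ranks=ranks,
        rank_product=rp,
        pvalue=pval,
        n=n,
        k=k,
    )
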