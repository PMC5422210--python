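"""A/B compartment scoring, compartment-switch detection, and DamID LADs.

Compartments: the distance-normalized (observed/expected) contact matrix
is turned into a Pearson correlation matrix over covered bins, and the
leading eigenvector of that correlation matrix scores each bin; its sign
is oriented against a reference track (e.g. gene density) so that the A
compartment is positive. Switches between two conditions are bins whose
score changes sign AND whose absolute difference exceeds a threshold set
to (85th - 15th percentile of the wild-type scores) / 2.

DamID: lamina association per 50 kb-extended GATC fragment is the log2
ratio of Lamin-Dam over Dam-only coverage. LADs are runs of enriched
fragments; runs may be bridged across non-enriched fragments as long as
the non-enriched base pairs stay strictly below 20% of the resulting LAD
length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ContactMatrix, GenomicInterval, Track, observed_over_expected
from .digestion import ExtendedGATCFragment

__all__ = [
    "SwitchCall",
    "DamIDTrack",
    "compartment_eigenvector",
    "detect_switches",
    "switch_totals_mb",
    "damid_log_ratio",
    "call_lads",
]


@dataclass(frozen=True)
class SwitchCall:
    interval: GenomicInterval
    direction: str  # "AtoB" | "BtoA"
    wildtype_score: float  # mean over merged bins
    mutant_score: float
    threshold: float


@dataclass
class DamIDTrack:
    """log2(Lamin-Dam / Dam-only) per extended GATC fragment."""

    fragments: list[ExtendedGATCFragment]
    values: np.ndarray  # NaN where masked (no coverage in either sample)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.fragments) != len(self.values):
            raise ValueError("fragments and values must have equal length")


def compartment_eigenvector(
    matrix: ContactMatrix, reference: np.ndarray | None = None
) -> Track:
    """Leading eigenvector of the Hi-C correlation matrix, per bin.

    Zero-coverage bins are removed before the correlation and reinserted
    as NaN. When ``reference`` (one value per bin, e.g. gene density) is
    given, the eigenvector sign is flipped so its correlation with the
    reference is positive.
    """
    covered = matrix.covered_bins()
    if covered.sum() < 10:
        raise ValueError("need at least 10 covered bins")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        oe = observed_over_expected(matrix)
    sub = oe.values[np.ix_(covered, covered)]
    if np.allclose(sub.std(axis=1), 0):
        raise ValueError("degenerate (constant) correlation matrix")
    corr = np.corrcoef(sub)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix (constant rows)")
    eigvals, eigvecs = np.linalg.eigh(corr)
    ev = eigvecs[:, -1]  # eigenvector of the largest eigenvalue
    scores = np.full(matrix.n_bins, np.nan)
    scores[covered] = ev
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        r = np.corrcoef(ev, reference[covered])[0, 1]
        if r < 0:
            scores = -scores
    positions = np.arange(matrix.n_bins) * matrix.bin_size
    return Track(matrix.chrom, positions, scores)


def detect_switches(
    wildtype: Track, mutant: Track, percentiles: tuple[float, float] = (15.0, 85.0)
) -> list[SwitchCall]:
    """Bins that robustly switch compartment between two conditions.

    Threshold = (P85 - P15 of the wild-type scores) / 2. A bin switches
    when |mutant - wildtype| > threshold and the scores have opposite
    signs; adjacent switching bins of the same direction are merged.
    """
    if len(wildtype) != len(mutant) or not np.array_equal(
        wildtype.positions, mutant.positions
    ):
        raise ValueError("tracks must be defined on identical bins")
    wt, mut = wildtype.values, mutant.values
    lo, hi = np.nanpercentile(wt, list(percentiles))
    threshold = (hi - lo) / 2.0
    valid = np.isfinite(wt) & np.isfinite(mut)
    flips = valid & (np.abs(mut - wt) > threshold) & (wt * mut < 0)
    direction = np.where(wt > 0, "AtoB", "BtoA")
    bin_size = (
        int(wildtype.positions[1] - wildtype.positions[0])
        if len(wildtype) > 1
        else 1
    )
    calls: list[SwitchCall] = []
    idx = np.flatnonzero(flips)
    if idx.size == 0:
        return calls
    run = [int(idx[0])]
    for i in idx[1:]:
        if i == run[-1] + 1 and direction[i] == direction[run[0]]:
            run.append(int(i))
        else:
            calls.append(_make_switch(wildtype, wt, mut, run, direction, bin_size, threshold))
            run = [int(i)]
    calls.append(_make_switch(wildtype, wt, mut, run, direction, bin_size, threshold))
    return calls


def _make_switch(track, wt, mut, run, direction, bin_size, threshold) -> SwitchCall:
    start = int(track.positions[run[0]])
    end = int(track.positions[run[-1]]) + bin_size
    return SwitchCall(
        GenomicInterval(track.chrom, start, end),
        direction=str(direction[run[0]]),
        wildtype_score=float(np.mean(wt[run])),
        mutant_score=float(np.mean(mut[run])),
        threshold=float(threshold),
    )


def switch_totals_mb(calls: list[SwitchCall]) -> dict[str, float]:
    """Total switched megabases per direction."""
    out = {"AtoB": 0.0, "BtoA": 0.0}
    for c in calls:
        out[c.direction] += c.interval.length / 1e6
    return out


def damid_log_ratio(
    fragments: list[ExtendedGATCFragment],
    lamin_counts: np.ndarray,
    damonly_counts: np.ndarray,
    pseudocount: float = 1.0,
) -> DamIDTrack:
    """log2((lamin + psi) / (damonly + psi)); both-zero fragments masked."""
    lamin = np.asarray(lamin_counts, dtype=float)
    dam = np.asarray(damonly_counts, dtype=float)
    if not (len(fragments) == len(lamin) == len(dam)):
        raise ValueError("fragment and count arrays must match")
    vals = np.log2((lamin + pseudocount) / (dam + pseudocount))
    vals[(lamin == 0) & (dam == 0)] = np.nan
    return DamIDTrack(fragments, vals)


@dataclass
class _Run:
    start: int
    end: int
    enriched_bp: int
    frag_lo: int
    frag_hi: int  # inclusive fragment index range

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def non_enriched_bp(self) -> int:
        return self.length - self.enriched_bp


def call_lads(
    track: DamIDTrack,
    enrichment_threshold: float = 0.0,
    max_gap_fraction: float = 0.2,
) -> list[GenomicInterval]:
    """Segment a DamID track into lamina-associated domains.

    Runs of enriched fragments (log ratio > ``enrichment_threshold``;
    masked fragments count as not enriched) seed LADs. Adjacent LADs are
    merged across non-enriched stretches as long as the total non-enriched
    base pairs inside the merged LAD stay strictly below
    ``max_gap_fraction`` of its length. Merging is best-first (the pair
    with the smallest non-enriched fraction merges first), which makes the
    result symmetric under coordinate reflection.
    """
    frags = track.fragments
    vals = track.values
    enriched = np.zeros(len(frags), dtype=bool)
    finite = np.isfinite(vals)
    enriched[finite] = vals[finite] > enrichment_threshold
    # seed runs of consecutive enriched fragments
    runs: list[_Run] = []
    i = 0
    while i < len(frags):
        if not enriched[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(frags) and enriched[j + 1]:
            j += 1
        bp = sum(frags[t].interval.length for t in range(i, j + 1))
        runs.append(
            _Run(frags[i].interval.start, frags[j].interval.end, bp, i, j)
        )
        i = j + 1
    if not runs:
        return []

    def merged(a: _Run, b: _Run) -> _Run:
        return _Run(a.start, b.end, a.enriched_bp + b.enriched_bp, a.frag_lo, b.frag_hi)

    # best-first bridging: always take the admissible adjacent pair with
    # the smallest non-enriched fraction
    while len(runs) > 1:
        best_k, best_frac = -1, None
        for k in range(len(runs) - 1):
            cand = merged(runs[k], runs[k + 1])
            frac = cand.non_enriched_bp / cand.length
            if frac < max_gap_fraction and (best_frac is None or frac < best_frac):
                best_k, best_frac = k, frac
        if best_k < 0:
            break
        runs[best_k : best_k + 2] = [merged(runs[best_k], runs[best_k + 1])]
    chrom = frags[0].interval.chrom
    return [GenomicInterval(chrom, r.start, r.end) for r in runs]
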