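"""Ground-truth synthetic data for every analysis stage.

The generators are statistical stand-ins for chromosome-conformation and
DamID data, not polymer simulations: contact matrices combine a power-law
distance decay with multiplicative planted features (TAD blocks, loop
pixels, a compartment plaid) and Poisson counting noise; 4C profiles have
a strictly decreasing background per side of the viewpoint with planted
multiplicative peaks and negative-binomial (overdispersed) counts; DamID
tracks are two-level Gaussian log-ratio tracks with planted LADs. Every
generator is deterministic under a fixed seed and returns the planted
truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import ContactMatrix, GenomicInterval
from .digestion import ExtendedGATCFragment
from .peakc import FourCProfile
from .compartments import DamIDTrack

__all__ = [
    "SyntheticTruth",
    "gen_contact_matrix",
    "gen_4c_profile",
    "gen_damid_track",
    "gen_loop_set",
]


@dataclass
class SyntheticTruth:
    """Planted features of one synthetic dataset (JSON-serializable)."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)
    tads: list = field(default_factory=list)  # [start_bin, end_bin, factor]
    loops: list = field(default_factory=list)  # [i, j, factor]
    compartment_vector: list = field(default_factory=list)
    peaks: list = field(default_factory=list)  # [position, fold]
    lads: list = field(default_factory=list)  # [start_bp, end_bp]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def gen_contact_matrix(
    n_bins: int = 400,
    bin_size: int = 10_000,
    decay_exponent: float = -1.0,
    base: float = 100.0,
    tads: list[tuple[int, int, float]] | None = None,
    loops: list[tuple[int, int, float]] | None = None,
    loop_width: int = 1,
    compartment_vector: np.ndarray | None = None,
    kappa: float = 0.3,
    noise: bool = True,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[ContactMatrix, SyntheticTruth]:
    """Distance-decaying contact matrix with planted features.

    Expected counts are E[C_ij] = base * max(|i-j|, 1)^decay_exponent
    multiplied by the TAD block factor, the loop pixel factor and the
    compartment plaid (1 + kappa * v_i * v_j); observed counts are
    Poisson draws mirrored onto both triangles (exactly symmetric).
    """
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    tads = tads or []
    loops = loops or []
    rng = np.random.default_rng(seed)
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    expect = base * np.maximum(dist, 1).astype(float) ** decay_exponent
    for a, b, factor in tads:
        if factor < 1:
            raise ValueError("TAD enrichment factors must be >= 1")
        expect[a:b, a:b] *= factor
    for i, j, factor in loops:
        if factor < 1:
            raise ValueError("loop enrichment factors must be >= 1")
        lo_i, hi_i = max(i - loop_width + 1, 0), min(i + loop_width, n_bins)
        lo_j, hi_j = max(j - loop_width + 1, 0), min(j + loop_width, n_bins)
        expect[lo_i:hi_i, lo_j:hi_j] *= factor
        expect[lo_j:hi_j, lo_i:hi_i] *= factor
    cvec = None
    if compartment_vector is not None:
        cvec = np.asarray(compartment_vector, dtype=float)
        if len(cvec) != n_bins:
            raise ValueError("compartment vector length mismatch")
        plaid = 1.0 + kappa * cvec[:, None] * cvec[None, :]
        expect *= np.clip(plaid, 0.05, None)
    if noise:
        draw = rng.poisson(expect).astype(float)
        upper = np.triu(draw)
        values = upper + np.triu(upper, 1).T
    else:
        values = 0.5 * (expect + expect.T)
    truth = SyntheticTruth(
        seed=seed,
        kind="contact_matrix",
        params={
            "n_bins": n_bins,
            "bin_size": bin_size,
            "decay_exponent": decay_exponent,
            "base": base,
            "kappa": kappa,
            "noise": noise,
        },
        tads=[list(t) for t in tads],
        loops=[list(l) for l in loops],
        compartment_vector=[] if cvec is None else cvec.tolist(),
    )
    return ContactMatrix(chrom=chrom, bin_size=bin_size, values=values), truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Gamma-Poisson).

    dispersion = 0 returns the mean exactly (noise-free limit).
    """
    if dispersion == 0:
        return mean.astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def gen_4c_profile(
    n_fragments_per_side: int = 150,
    fragment_spacing: float = 1_000.0,
    viewpoint_pos: float = 1_000_000.0,
    background_scale: float = 300.0,
    decay_exponent: float = -1.0,
    decay_offset: float = 5_000.0,
    peaks: list[tuple[float, float]] | None = None,
    peak_width: float = 5_000.0,
    dispersion: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[list[FourCProfile], SyntheticTruth]:
    """Replicate 4C profiles with a monotone background and planted peaks.

    The background mean at distance d from the viewpoint is
    background_scale * ((d + decay_offset)/decay_offset)^decay_exponent —
    strictly decreasing per side. Each planted peak multiplies the
    background by its fold over ``peak_width`` bp around its position.
    Counts are negative binomial per fragment (Var = mu + dispersion*mu^2).
    """
    peaks = peaks or []
    if any(fold <= 1 for _, fold in peaks):
        raise ValueError("peak folds must be > 1")
    rng = np.random.default_rng(seed)
    vp = GenomicInterval(chrom, int(viewpoint_pos) - 2_000, int(viewpoint_pos) + 2_000)
    offsets = (np.arange(1, n_fragments_per_side + 1)) * fragment_spacing
    jitter = rng.uniform(-0.3, 0.3, size=2 * n_fragments_per_side) * fragment_spacing
    positions = np.sort(
        np.concatenate([viewpoint_pos - offsets, viewpoint_pos + offsets]) + jitter
    )
    dist = np.abs(positions - viewpoint_pos)
    mean = background_scale * ((dist + decay_offset) / decay_offset) ** decay_exponent
    for pos, fold in peaks:
        in_peak = np.abs(positions - pos) <= peak_width / 2
        mean = np.where(in_peak, mean * fold, mean)
    profiles = []
    for r in range(replicates):
        counts = _nb_draw(rng, mean, dispersion)
        profiles.append(
            FourCProfile(vp, positions, counts, replicate=f"rep{r + 1}")
        )
    truth = SyntheticTruth(
        seed=seed,
        kind="4c_profile",
        params={
            "n_fragments_per_side": n_fragments_per_side,
            "fragment_spacing": fragment_spacing,
            "viewpoint_pos": viewpoint_pos,
            "background_scale": background_scale,
            "decay_exponent": decay_exponent,
            "decay_offset": decay_offset,
            "peak_width": peak_width,
            "dispersion": dispersion,
            "replicates": replicates,
        },
        peaks=[list(p) for p in peaks],
    )
    return profiles, truth


def gen_damid_track(
    n_fragments: int = 200,
    fragment_size: float = 50_000.0,
    lads: list[tuple[int, int]] | None = None,
    in_level: float = 1.0,
    out_level: float = -1.0,
    sigma: float = 0.3,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[DamIDTrack, SyntheticTruth]:
    """Two-level DamID log-ratio track with planted LADs.

    ``lads`` are (start_fragment, end_fragment) index spans (half-open).
    Fragment sizes are jittered around ``fragment_size`` so exact rule
    ties are measure-zero; log-ratios are Gaussian around ``in_level``
    inside planted LADs and ``out_level`` outside.
    """
    if in_level <= out_level:
        raise ValueError("in_level must exceed out_level")
    lads = lads or []
    rng = np.random.default_rng(seed)
    sizes = np.round(fragment_size * rng.uniform(0.8, 1.2, size=n_fragments)).astype(int)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    frags = [
        ExtendedGATCFragment(
            GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1])), n_fragments=1
        )
        for i in range(n_fragments)
    ]
    inside = np.zeros(n_fragments, dtype=bool)
    for a, b in lads:
        inside[a:b] = True
    level = np.where(inside, in_level, out_level)
    values = level + (rng.normal(0.0, sigma, size=n_fragments) if sigma > 0 else 0.0)
    truth = SyntheticTruth(
        seed=seed,
        kind="damid_track",
        params={
            "n_fragments": n_fragments,
            "fragment_size": fragment_size,
            "in_level": in_level,
            "out_level": out_level,
            "sigma": sigma,
        },
        lads=[[int(bounds[a]), int(bounds[b])] for a, b in lads],
    )
    return DamIDTrack(frags, values), truth


def gen_loop_set(
    n_loops: int = 200,
    median_length: float = 370_000.0,
    sigma_log: float = 0.5,
    anchor_size: int = 10_000,
    span: int = 100_000_000,
    resolution: int = 10_000,
    seed: int = 0,
    chrom: str = "chrS",
):
    """Loops with log-normal lengths (median = ``median_length``)."""
    from .loops import Loop

    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.normal(np.log(median_length), sigma_log, size=n_loops))
    starts = rng.uniform(0, span - lengths.max() - 2 * anchor_size, size=n_loops)
    out = []
    for s, ln in zip(starts, lengths):
        a5 = GenomicInterval(chrom, int(s), int(s) + anchor_size)
        a3s = int(s + ln)
        out.append(Loop(a5, GenomicInterval(chrom, a3s, a3s + anchor_size),
                        resolution=resolution))
    out.sort(key=lambda lp: lp.anchor5.start)
    return out
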