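"""Readers and writers for the plain-text interchange formats.

Matrices travel as 3-column triplet text (bin_i, bin_j, count) with a
``#chrom=``/``#bin_size=`` header; intervals as BED, loops as BEDPE,
tracks as bedGraph. All coordinates on disk are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ContactMatrix, GenomicInterval, Track


# ---------------------------------------------------------------- matrices

def write_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the upper triangle (incl. diagonal) as triplet text."""
    i, j = np.triu_indices(matrix.n_bins)
    vals = matrix.values[i, j]
    nz = vals != 0
    with open(path, "w") as fh:
        fh.write(f"#chrom={matrix.chrom}\n")
        fh.write(f"#bin_size={matrix.bin_size}\n")
        fh.write(f"#n_bins={matrix.n_bins}\n")
        for a, b, v in zip(i[nz], j[nz], vals[nz]):
            fh.write(f"{a}\t{b}\t{v:.10g}\n")


def read_matrix(path: str | Path) -> ContactMatrix:
    """Read triplet text written by :func:`write_matrix` (or a cooler-style
    single-chromosome dump with the same header lines)."""
    chrom, bin_size, n_bins = None, None, None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "chrom":
                    chrom = val
                elif key == "bin_size":
                    bin_size = int(val)
                elif key == "n_bins":
                    n_bins = int(val)
                continue
            i, j, v = line.split("\t")
            rows.append((int(i), int(j), float(v)))
    if chrom is None or bin_size is None:
        raise ValueError(f"{path}: missing #chrom= / #bin_size= header")
    if n_bins is None:
        n_bins = max(max(i, j) for i, j, _ in rows) + 1 if rows else 0
    values = np.zeros((n_bins, n_bins))
    for i, j, v in rows:
        values[i, j] = v
        values[j, i] = v
    return ContactMatrix(chrom=chrom, bin_size=bin_size, values=values)


# ---------------------------------------------------------------- intervals

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 and f[5] in "+-." else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals, path: str | Path, names=None) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            name = names[k] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bedgraph(path: str | Path) -> Track:
    chroms, starts, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chroms.append(f[0])
            starts.append(int(f[1]))
            vals.append(float(f[3]))
    if not chroms:
        raise ValueError(f"{path}: empty bedGraph")
    if len(set(chroms)) != 1:
        raise ValueError(f"{path}: expected a single chromosome per file")
    order = np.argsort(starts)
    return Track(chroms[0], np.asarray(starts)[order], np.asarray(vals)[order])


def write_bedgraph(track: Track, path: str | Path, span: int = 1) -> None:
    with open(path, "w") as fh:
        for pos, val in zip(track.positions, track.values):
            if np.isnan(val):
                continue
            fh.write(f"{track.chrom}\t{pos}\t{pos + span}\t{val:.6g}\n")


# ---------------------------------------------------------------- loops

def read_bedpe(path: str | Path, resolution: int = 10_000):
    """Read loops from BEDPE (first six columns used)."""
    from .loops import Loop

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            a5 = GenomicInterval(f[0], int(f[1]), int(f[2]))
            a3 = GenomicInterval(f[3], int(f[4]), int(f[5]))
            out.append(Loop(a5, a3, resolution=resolution))
    return out


def write_bedpe(loops, path: str | Path) -> None:
    """10-column BEDPE; the strand columns carry the orientation class."""
    with open(path, "w") as fh:
        for k, lp in enumerate(loops):
            ori = getattr(lp, "orientation", None) or "."
            fh.write(
                f"{lp.anchor5.chrom}\t{lp.anchor5.start}\t{lp.anchor5.end}\t"
                f"{lp.anchor3.chrom}\t{lp.anchor3.start}\t{lp.anchor3.end}\t"
                f"loop_{k}\t0\t{ori}\t{lp.source}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}
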