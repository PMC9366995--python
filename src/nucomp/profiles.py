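"""Minimal bidirectional complexity profiles.

A complexity profile assigns to each position i the number of bits the
compressor needs for symbol x_i given everything before it (causal order).
Compressing the sequence in both directions and taking the pointwise minimum,

    B(x_i) = min( C_fwd(x_i), C_bwd(x_i) ),

makes repeated material cheap regardless of which copy comes first: the
forward pass prices the second copy of a duplication cheaply, the backward
pass the first. The backward pass here is plain reversal of the sequence
(direction of reading, not strand); a reverse-complement backward pass is
available behind a flag, though IR structure is normally captured by the IR
model modes instead.

For visualization the profile is low-pass filtered with a normalized Blackman
window (mirror padding at the edges), and low-complexity regions can be
called as threshold runs on the smoothed series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from nucomp.fcm import CompressorConfig, compress_sequence

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class ComplexityProfile:
    """Per-position code lengths in both directions and their minimum.

    Series are aligned to the original coordinates: ``bits_backward[i]`` is
    the cost of x_i in the end-to-start pass, re-mirrored so index i always
    refers to x_i.
    """

    accession: str
    bits_forward: np.ndarray
    bits_backward: np.ndarray
    bits_min: np.ndarray
    smoothed: np.ndarray | None = None
    window: int | None = None

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.bits_forward) + 1)

    def __len__(self) -> int:
        return len(self.bits_forward)


def bidirectional_profile(
    seq: str,
    config: CompressorConfig,
    accession: str = "",
    backward: str = "reverse",
) -> ComplexityProfile:
    """Compute forward, backward and minimal per-position code lengths.

    ``backward`` selects the end-to-start reading: ``"reverse"`` (default)
    compresses the reversed sequence, ``"revcomp"`` the reverse complement.
    Either way the backward series is re-mirrored into original coordinates
    before the pointwise minimum is taken.
    """
    if len(seq) < 2:
        raise ValueError("profile needs a sequence of length >= 2")
    if backward not in ("reverse", "revcomp"):
        raise ValueError("backward must be 'reverse' or 'revcomp'")
    fwd = compress_sequence(seq, config).per_symbol_bits
    rev_seq = seq[::-1] if backward == "reverse" else reverse_complement(seq)
    bwd = compress_sequence(rev_seq, config).per_symbol_bits[::-1].copy()
    return ComplexityProfile(
        accession=accession,
        bits_forward=fwd,
        bits_backward=bwd,
        bits_min=np.minimum(fwd, bwd),
    )


def smooth_profile(series: np.ndarray, window: int) -> np.ndarray:
    """Low-pass filter a profile with a normalized Blackman window.

    The window must be odd and no longer than the series. Weights are
    normalized to sum to 1 (a constant series is reproduced exactly) and the
    edges use mirror padding, so the output has the input's length.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return series.copy()
    kernel = np.blackman(window)
    kernel /= kernel.sum()
    half = window // 2
    padded = np.pad(series, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def call_regions(
    smoothed: np.ndarray, threshold: float, min_len: int = 1
) -> list[tuple[int, int]]:
    """Maximal runs with smoothed value strictly below ``threshold``.

    Returns sorted, non-overlapping 1-based closed intervals of length
    at least ``min_len``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    below = np.asarray(smoothed) < threshold
    regions = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                regions.append((start + 1, i))
            start = None
    if start is not None and len(below) - start >= min_len:
        regions.append((start + 1, len(below)))
    return regions


def write_profile_tsv(profile: ComplexityProfile, path: str | Path) -> None:
    """Profile as TSV: position (1-based), forward, backward, min[, smoothed]."""
    cols = [profile.positions, profile.bits_forward, profile.bits_backward, profile.bits_min]
    header = "position\tforward\tbackward\tmin"
    if profile.smoothed is not None:
        cols.append(profile.smoothed)
        header += "\tsmoothed"
    with open(path, "w") as handle:
        handle.write(header + "\n")
        for row in zip(*cols):
            pos = int(row[0])
            vals = "\t".join(f"{v:.6f}" for v in row[1:])
            handle.write(f"{pos}\t{vals}\n")


def write_regions_bed(
    regions: list[tuple[int, int]], path: str | Path, name: str = "region"
) -> None:
    """Write 1-based closed intervals as BED (0-based, half-open)."""
    with open(path, "w") as handle:
        for i, (start, end) in enumerate(regions, start=1):
            handle.write(f"{name}\t{start - 1}\t{end}\t{name}_{i}\n")
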