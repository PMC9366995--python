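"""Scalar complexity and composition measures per genome.

The central quantity is the normalized compression

    NC(x) = C(x) / (2 |x|),

where C(x) is the compressed size of x in bits and 2 = log2(4) bits is the
per-base capacity of the quaternary alphabet. NC near 1 means the sequence is
essentially incompressible; NC near 0 means it is highly redundant. Derived
measures:

* NR(x) = 1 - NC(x), the normalized redundancy;
* NCC = 1 - NC_IR2 (compression capacity of the IR-only mode), kept only when
  strictly positive — a non-positive value means the IR-only compressor could
  not beat the capacity bound and carries no IR signal;
* DIFF = NC_IR0 - NC_IR1, the gain from adding IR detection to the regular
  context model (negative values are retained and reported).

The per-genome feature vector bundles these with sequence length (SL) and
GC-content for the classification harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from nucomp.fcm import CompressorConfig, compress_sequence, level16
from nucomp.io_seq import GenomeRecord, RANKS

#: Default classification feature set (the six named per-genome measures).
DEFAULT_FEATURES = ("SL", "GC", "NC_best", "NC_IR0", "NC_IR1", "NC_IR2")
#: Additional derived columns carried in feature tables.
EXTRA_FEATURES = ("NCC", "DIFF", "NR")


@dataclass
class FeatureVector:
    """Per-genome measures keyed by accession; NCC is None when 1 - NC_IR2 <= 0."""

    accession: str
    SL: int
    GC: float
    NC_best: float
    NC_IR0: float
    NC_IR1: float
    NC_IR2: float
    NCC: float | None
    DIFF: float
    NR: float


def normalized_compression(total_bits: float, length: int) -> float:
    """NC = total_bits / (2 * length)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if total_bits < 0:
        raise ValueError("total_bits must be non-negative")
    return total_bits / (2.0 * length)


def gc_content(seq: str) -> float:
    """Percentage of G and C bases in the sequence."""
    if not seq:
        raise ValueError("empty sequence")
    gc = sum(1 for c in seq if c in "GC")
    return 100.0 * gc / len(seq)


def ncc_ir2(nc_ir2: float) -> float | None:
    """NCC = 1 - NC_IR2 when strictly positive, else None (excluded)."""
    if nc_ir2 < 0:
        raise ValueError("NC must be non-negative")
    value = 1.0 - nc_ir2
    return value if value > 0.0 else None


def ir_difference(nc_ir0: float, nc_ir1: float) -> float:
    """DIFF = NC_IR0 - NC_IR1; may be negative."""
    if nc_ir0 < 0 or nc_ir1 < 0:
        raise ValueError("NC values must be non-negative")
    return nc_ir0 - nc_ir1


def normalized_redundancy(nc: float) -> float:
    """NR = 1 - NC."""
    if nc < 0:
        raise ValueError("NC must be non-negative")
    return 1.0 - nc


def feature_vector(
    record: GenomeRecord, config: CompressorConfig | None = None
) -> FeatureVector:
    """Compute the full per-genome feature vector.

    Runs the compressor four times: with the configuration as given
    (NC_best), and with the IR override forced to 0, 1, and 2. Deterministic
    for a fixed (record, config).
    """
    config = config if config is not None else level16()
    n = record.length
    nc_best = normalized_compression(
        compress_sequence(record.residues, config).total_bits, n
    )
    ncs = {}
    for mode in (0, 1, 2):
        res = compress_sequence(record.residues, config.with_ir_override(mode))
        ncs[mode] = normalized_compression(res.total_bits, n)
    for value in (nc_best, *ncs.values()):
        if not math.isfinite(value):
            raise ValueError(f"non-finite NC for {record.accession}")
    return FeatureVector(
        accession=record.accession,
        SL=n,
        GC=gc_content(record.residues),
        NC_best=nc_best,
        NC_IR0=ncs[0],
        NC_IR1=ncs[1],
        NC_IR2=ncs[2],
        NCC=ncc_ir2(ncs[2]),
        DIFF=ir_difference(ncs[0], ncs[1]),
        NR=normalized_redundancy(nc_best),
    )


def feature_table(
    records: Iterable[GenomeRecord], config: CompressorConfig | None = None
) -> pd.DataFrame:
    """Feature vectors for many records as a DataFrame (one row per accession).

    Taxonomy annotation present on the records (lineage ranks, genome type) is
    joined in as extra columns so the table can feed the landscape and
    classification modules directly. NCC is NaN where absent.
    """
    rows = []
    for rec in records:
        fv = feature_vector(rec, config)
        row = {
            "accession": fv.accession,
            "SL": fv.SL,
            "GC": fv.GC,
            "NC_best": fv.NC_best,
            "NC_IR0": fv.NC_IR0,
            "NC_IR1": fv.NC_IR1,
            "NC_IR2": fv.NC_IR2,
            "NCC": float("nan") if fv.NCC is None else fv.NCC,
            "DIFF": fv.DIFF,
            "NR": fv.NR,
            "genome_type": rec.genome_type,
        }
        for rank in RANKS:
            row[rank] = rec.lineage.get(rank)
        rows.append(row)
    if not rows:
        raise ValueError("no records to featurize")
    df = pd.DataFrame(rows)
    if df["accession"].duplicated().any():
        raise ValueError("duplicate accessions in feature table")
    return df.set_index("accession", drop=False)
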