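"""FASTA ingestion, alphabet sanitization, and taxonomy metadata handling.

Sequences are stored over the quaternary DNA alphabet {A, C, G, T}; RNA input
is accepted and U is mapped to T so a single alphabet serves the compressor.
Any other symbol (IUPAC ambiguity codes, gaps, etc.) is replaced by a base
drawn uniformly at random from a seeded generator, so ingestion is
reproducible. Taxonomy arrives as a TSV sidecar keyed by accession and records
can be filtered down to those with a complete, classified lineage from realm
to genus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
#: Taxonomic ranks required for a "complete" lineage, shallowest first.
RANKS = ("realm", "kingdom", "phylum", "class", "order", "family", "genus")
GENOME_TYPES = ("dsDNA", "ssDNA", "dsRNA", "ssRNA", "mixed-DNA", "unknown")

METADATA_COLUMNS = ("accession", "genome_type") + RANKS

# Case folding plus U->T; everything else left for the replacement pass.
_CLEAN = str.maketrans("acgtuU", "ACGTTT")
_VALID = frozenset(ALPHABET)


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


@dataclass
class GenomeRecord:
    """One sanitized nucleotide sequence with optional taxonomy annotation.

    Attributes
    ----------
    accession : str
        Identifier (FASTA header token before the first whitespace).
    residues : str
        Sequence over {A, C, G, T}.
    genome_type : str
        One of :data:`GENOME_TYPES`; ``"unknown"`` until annotated.
    lineage : dict
        Mapping rank -> taxon name for the ranks in :data:`RANKS`;
        entries may be absent.
    n_sanitized : int
        Number of symbols replaced during sanitization.
    """

    accession: str
    residues: str
    genome_type: str = "unknown"
    lineage: dict = field(default_factory=dict)
    n_sanitized: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.accession!r} has a zero-length sequence")
        if not _VALID.issuperset(self.residues):
            bad = sorted(set(self.residues) - _VALID)
            raise ValueError(
                f"record {self.accession!r} contains non-ACGT symbols {bad}; "
                "sanitize before constructing GenomeRecord"
            )
        if self.n_sanitized > len(self.residues):
            raise ValueError("n_sanitized cannot exceed sequence length")

    @property
    def length(self) -> int:
        return len(self.residues)


def _sanitize(raw: str, rng: np.random.Generator) -> tuple[str, int]:
    s = raw.translate(_CLEAN)
    bad = [i for i, c in enumerate(s) if c not in _VALID]
    if not bad:
        return s, 0
    chars = list(s)
    # one draw per replaced symbol, consumed in sequence order
    for i in bad:
        chars[i] = ALPHABET[rng.integers(4)]
    return "".join(chars), len(bad)


def sanitize_sequence(raw: str, seed: int) -> tuple[str, int]:
    """Map a raw sequence onto {A, C, G, T}.

    Case is folded, U/u becomes T, and every remaining non-ACGT symbol is
    replaced by a uniformly random base from a generator seeded with ``seed``
    (so replacements are reproducible). Returns the cleaned sequence and the
    number of replacements; U->T mapping and case folding are not counted.
    """
    if not raw:
        raise ValueError("cannot sanitize a zero-length sequence")
    return _sanitize(raw, np.random.default_rng(seed))


def read_fasta(path: str | Path, seed: int) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into sanitized :class:`GenomeRecord` s.

    The replacement generator is seeded once per file; draws are consumed in
    record order, then in sequence order within each record. The accession is
    the header token before the first whitespace. A sequence line before any
    header is a :class:`FastaParseError` naming the offending line; an empty
    file yields an empty list with a warning.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno} contains sequence data before any "
                    "'>' header"
                )
            break
        else:
            warnings.warn(f"{path}: empty FASTA file, no records read", stacklevel=2)
            return []
    rng = np.random.default_rng(seed)
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            residues, n_replaced = _sanitize(str(rec.seq), rng)
            records.append(
                GenomeRecord(accession=rec.id, residues=residues, n_sanitized=n_replaced)
            )
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA (accession-only headers, wrapped lines)."""
    seqs = [SeqRecord(Seq(r.residues), id=r.accession, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the taxonomy/metadata sidecar TSV.

    Expected header columns: accession, genome_type, realm, kingdom, phylum,
    class, order, family, genus. Accessions must be unique.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table is missing columns: {missing}")
    if meta["accession"].duplicated().any():
        dupes = meta.loc[meta["accession"].duplicated(), "accession"].tolist()
        raise ValueError(f"duplicate accessions in metadata: {dupes}")
    return meta.set_index("accession", drop=False)


def _lineage_complete(lineage: Mapping[str, str]) -> bool:
    for rank in RANKS:
        name = lineage.get(rank)
        if name is None or not str(name).strip() or str(name) == "nan":
            return False
        if "unclassified" in str(name).lower():
            return False
    return True


def apply_taxonomy_filter(
    records: Iterable[GenomeRecord], meta: pd.DataFrame
) -> list[GenomeRecord]:
    """Keep records with complete, classified lineages and annotate them.

    A record is retained only if its metadata row has a non-empty value for
    every rank realm..genus and no rank name contains the token
    "unclassified" (case-insensitive). Retained records are returned as
    copies annotated with their lineage and genome type. Records absent from
    the table are treated as lacking taxonomy and dropped.
    """
    kept = []
    for rec in records:
        if rec.accession not in meta.index:
            continue
        row = meta.loc[rec.accession]
        lineage = {r: row[r] for r in RANKS if pd.notna(row[r])}
        if not _lineage_complete(lineage):
            continue
        gtype = row["genome_type"]
        if pd.isna(gtype) or gtype not in GENOME_TYPES:
            gtype = "unknown"
        kept.append(replace(rec, genome_type=gtype, lineage=dict(lineage)))
    return kept
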