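import numpy as np
import pandas as pd
import pytest

from nucomp.fcm import CompressorConfig, ModelSpec, level16
from nucomp.io_seq import RANKS, GenomeRecord


@pytest.fixture
def k1_config() -> CompressorConfig:
    """Single order-1 Laplace model (alpha=1), the closed-form reference case."""
    return CompressorConfig((ModelSpec(order_k=1, alpha=1.0, gamma=0.7, ir_mode=0),), label="k1")


@pytest.fixture
def lvl16() -> CompressorConfig:
    return level16()


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing FASTA content to a temp file."""

    def _write(content: str, name: str = "test.fa"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def make_lineage(suffix: str = "1") -> dict:
    return {rank: f"{rank}_{suffix}" for rank in RANKS}


@pytest.fixture
def metadata_frame():
    """Factory building a metadata table from (accession, genome_type, lineage) rows."""

    def _build(rows):
        data = []
        for accession, gtype, lineage in rows:
            row = {"accession": accession, "genome_type": gtype}
            row.update({rank: lineage.get(rank) for rank in RANKS})
            data.append(row)
        return pd.DataFrame(data).set_index("accession", drop=False)

    return _build


@pytest.fixture
def lineage_table():
    """Lineage-complete feature table for landscape tests (no compression runs)."""

    def _build(n_per_genus=3, genera=("g1", "g2"), families=("f1",), seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        i = 0
        for fam in families:
            for genus in genera:
                for _ in range(n_per_genus):
                    row = {
                        "accession": f"acc{i}",
                        "SL": float(rng.integers(1000, 2000)),
                        "GC": float(rng.uniform(30, 70)),
                        "NC_best": float(rng.uniform(0.5, 1.0)),
                        "NCC": float(rng.uniform(0.0, 0.5)),
                        "genome_type": "dsDNA",
                        "realm": "r1",
                        "kingdom": "k1",
                        "phylum": "p1",
                        "class": "c1",
                        "order": "o1",
                        "family": fam,
                        "genus": f"{fam}_{genus}",
                    }
                    rows.append(row)
                    i += 1
        return pd.DataFrame(rows).set_index("accession", drop=False)

    return _build


def make_record(accession: str, residues: str, lineage: dict | None = None,
                genome_type: str = "unknown") -> GenomeRecord:
    return GenomeRecord(
        accession=accession,
        residues=residues,
        genome_type=genome_type,
        lineage=lineage or {},
    )
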