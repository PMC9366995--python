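"""Dataset-level analysis: outlier filtering, per-rank aggregation, cladograms.

Feature tables (one row per genome, measures plus lineage columns) are
filtered for outliers with a single-pass mean +/- k*sigma rule, summarized
per taxonomic rank or genome type, and aggregated into a rank cladogram
(realm -> genus) whose nodes carry the leaf-count-weighted mean of a chosen
measure. Trees export to Newick (internal node labels preserved, names with
spaces quoted) alongside a TSV of node statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from nucomp.io_seq import RANKS

DEFAULT_OUTLIER_MEASURES = ("SL", "GC", "NC_best")
AGGREGATION_KEYS = ("genome_type",) + RANKS
DEFAULT_AGG_MEASURES = ("SL", "GC", "NC_best", "NC_IR0", "NC_IR1", "NC_IR2", "NCC", "DIFF", "NR")


def outlier_filter(
    table: pd.DataFrame,
    k: float = 3.0,
    measures=DEFAULT_OUTLIER_MEASURES,
) -> tuple[pd.DataFrame, list[str]]:
    """Single-pass mean +/- k*sigma filter over the listed measures.

    Statistics (population sigma, ddof=0) are computed once over the full
    input table; a row is removed when any listed measure falls *strictly*
    outside [mu - k*sigma, mu + k*sigma], so boundary values are kept. A
    measure with zero spread removes nothing. Returns the kept table and the
    removed accessions. Deliberately not iterated: a second pass over the
    kept rows could remove more.
    """
    if table.empty:
        raise ValueError("cannot filter an empty table")
    if k <= 0:
        raise ValueError("k must be positive")
    keep = pd.Series(True, index=table.index)
    for m in measures:
        if m not in table.columns:
            raise KeyError(f"measure {m!r} not in table")
        col = table[m].astype(float)
        mu = col.mean()
        sigma = col.std(ddof=0)
        if sigma == 0 or not np.isfinite(sigma):
            continue
        keep &= (col >= mu - k * sigma) & (col <= mu + k * sigma)
    removed = table.index[~keep].tolist()
    return table.loc[keep], removed


def aggregate_by_rank(
    table: pd.DataFrame, rank: str, measures=DEFAULT_AGG_MEASURES
) -> pd.DataFrame:
    """Per-group mean and count of each measure at one rank.

    ``rank`` is ``"genome_type"`` or one of the seven lineage ranks. Counts
    are of non-missing values, so NCC means cover only rows where NCC is
    present (strictly positive by construction).
    """
    if rank not in AGGREGATION_KEYS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {AGGREGATION_KEYS}")
    measures = [m for m in measures if m in table.columns]
    return table.groupby(rank)[measures].agg(["mean", "count"])


@dataclass
class TaxonNode:
    """Node of the rank cladogram with per-measure summary statistics."""

    rank: str
    name: str
    children: list = field(default_factory=list)
    mean: float = float("nan")
    count: int = 0

    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self):
        yield self
        for child in self.children:
            yield from child.iter_nodes()


def build_cladogram(table: pd.DataFrame, measure: str = "NC_best") -> TaxonNode:
    """Build the realm->genus rank tree annotated with one measure.

    Every node carries the mean of ``measure`` over the genome rows beneath
    it (count = rows with the measure present), so internal means are
    leaf-count-weighted by construction. Children are ordered
    lexicographically for determinism. Requires lineage-complete rows.
    """
    if measure not in table.columns:
        raise KeyError(f"measure {measure!r} not in table")
    for rank in RANKS:
        if rank not in table.columns or table[rank].isna().any():
            raise ValueError(f"table must be lineage-complete (rank {rank!r})")

    def _build(rows: pd.DataFrame, depth: int, rank: str, name: str) -> TaxonNode:
        vals = rows[measure].dropna()
        node = TaxonNode(
            rank=rank,
            name=name,
            mean=float(vals.mean()) if len(vals) else float("nan"),
            count=int(len(vals)),
        )
        if depth < len(RANKS):
            child_rank = RANKS[depth]
            for child_name, sub in sorted(rows.groupby(child_rank), key=lambda kv: kv[0]):
                node.children.append(_build(sub, depth + 1, child_rank, child_name))
        return node

    return _build(table, 0, "root", "root")


def export_cladogram(
    tree: TaxonNode, tree_path: str | Path, stats_path: str | Path | None = None
) -> None:
    """Write the cladogram as Newick plus a TSV of node statistics.

    Internal nodes keep their taxon names as labels (quoted when they contain
    spaces); the companion TSV lists rank, name, measure mean and count for
    every node. The Newick output parses with standard readers.
    """
    if tree.is_leaf():
        raise ValueError("cannot export an empty cladogram (root has no children)")
    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)

    def _attach(node: TaxonNode, dnode) -> None:
        for child in node.children:
            dchild = dnode.new_child()
            if child.is_leaf():
                dchild.taxon = tns.new_taxon(child.name)
            else:
                dchild.label = child.name
            _attach(child, dchild)

    dtree.seed_node.label = tree.name
    _attach(tree, dtree.seed_node)
    with open(tree_path, "w") as handle:
        handle.write(
            dtree.as_string(schema="newick", suppress_rooting=True, preserve_spaces=True)
        )
    if stats_path is not None:
        rows = [
            {"rank": n.rank, "name": n.name, "mean": n.mean, "count": n.count}
            for n in tree.iter_nodes()
        ]
        pd.DataFrame(rows).to_csv(stats_path, sep="\t", index=False)


def import_cladogram(
    tree_path: str | Path, stats_path: str | Path
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Read back an exported cladogram (topology via dendropy) and its stats."""
    dtree = dendropy.Tree.get(
        path=str(tree_path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    stats = pd.read_csv(stats_path, sep="\t")
    return dtree, stats
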