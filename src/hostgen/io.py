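"""TSV readers/writers for count tables, metadata and taxonomy.

All tables are tab-delimited UTF-8 with a header row.  The count table
has hosts in rows (first column = host id) and ASVs in columns; the
metadata table is keyed by host id with ``site``, ``host_species`` and
``host_family`` columns; the taxonomy table is keyed by ASV id with at
least a ``phylum`` column.
"""

from __future__ import annotations

import pandas as pd

from .datamodel import META_COLUMNS, CommunityTable, CommunityTableError, Taxonomy
from .trees import PhyloTree, read_tree, write_tree  # re-exported

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0, **kw)
    except Exception as exc:
        raise CommunityTableError(f"malformed TSV {path}: {exc}") from exc


def read_community_table(counts_path, metadata_path) -> CommunityTable:
    """Read and validate a host x ASV count table plus host metadata.

    Hosts present in the counts but absent from the metadata are an
    error (named in the message); all-zero ASV columns are retained.
    """
    counts = _read_tsv(counts_path)
    values = counts.to_numpy()
    try:
        as_float = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise CommunityTableError(f"non-numeric count in {counts_path}") from exc
    if (as_float != as_float.astype(int)).any():
        raise CommunityTableError(f"non-integer count in {counts_path}")
    counts = counts.astype(int)
    metadata = _read_tsv(metadata_path, dtype=str)
    return CommunityTable(counts, metadata)


def write_community_table(table: CommunityTable, counts_path, metadata_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="host_id")
    table.metadata[list(META_COLUMNS)].to_csv(
        metadata_path, sep="\t", index_label="host_id"
    )


def read_taxonomy(path) -> Taxonomy:
    return Taxonomy(_read_tsv(path, dtype=str))


def write_taxonomy(taxonomy: Taxonomy, path) -> None:
    taxonomy.table.to_csv(path, sep="\t", index_label="asv_id")
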