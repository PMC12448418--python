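"""Core containers for host-by-ASV community data.

The central object is :class:`CommunityTable`: a hosts-in-rows,
ASVs-in-columns count matrix together with per-host metadata (sampling
site, host species, host family).  All "column" language elsewhere in the
package (column-shuffle nulls, column prevalences) refers to ASVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("site", "host_species", "host_family")


class CommunityTableError(ValueError):
    """Raised when a community table or its metadata fails validation."""


@dataclass
class CommunityTable:
    """Host x ASV count matrix plus per-host metadata.

    Parameters
    ----------
    counts
        DataFrame with host identifiers as the index and ASV identifiers
        as columns.  Entries must be non-negative integers.  All-zero ASV
        columns are legal and retained (singletons and absences are kept
        so occupancy is decided at compute time, not load time).
    metadata
        DataFrame indexed by host identifier with columns ``site``,
        ``host_species`` and ``host_family``.  Every host in ``counts``
        must be present.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise CommunityTableError("duplicate host or ASV identifiers")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise CommunityTableError("counts must be integral")
            counts = counts.astype(np.int64)
        if values.size and counts.to_numpy().min() < 0:
            raise CommunityTableError("counts must be non-negative")
        missing = counts.index.difference(self.metadata.index)
        if len(missing):
            raise CommunityTableError(
                f"hosts missing from metadata: {', '.join(map(str, missing))}"
            )
        absent = [c for c in META_COLUMNS if c not in self.metadata.columns]
        if absent:
            raise CommunityTableError(f"metadata missing columns: {absent}")
        # align metadata rows to the count rows; drop extraneous hosts
        object.__setattr__(self, "counts", counts)
        object.__setattr__(
            self, "metadata", self.metadata.loc[counts.index, list(META_COLUMNS)]
        )

    # -- basic accessors -------------------------------------------------
    @property
    def host_ids(self) -> list:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_hosts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    @property
    def site(self) -> pd.Series:
        return self.metadata["site"]

    @property
    def host_species(self) -> pd.Series:
        return self.metadata["host_species"]

    @property
    def host_family(self) -> pd.Series:
        return self.metadata["host_family"]

    @property
    def depths(self) -> pd.Series:
        """Per-host library depth (row sums)."""
        return self.counts.sum(axis=1)

    def prevalence(self) -> pd.Series:
        """Number of hosts in which each ASV occurs (count > 0)."""
        return (self.counts > 0).sum(axis=0)

    def subset_hosts(self, hosts: Sequence) -> "CommunityTable":
        """Row subset preserving all ASV columns (zero columns retained)."""
        return CommunityTable(self.counts.loc[list(hosts)], self.metadata)

    def equals(self, other: "CommunityTable") -> bool:
        return self.counts.equals(other.counts) and self.metadata.equals(
            other.metadata
        )


@dataclass
class Taxonomy:
    """Per-ASV taxonomic labels (at minimum a phylum, possibly 'unassigned').

    ``table`` is indexed by ASV id with columns ``phylum`` and ``class_``
    (and optionally ``lineage``, a semicolon-joined rank string).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise CommunityTableError("duplicate ASV ids in taxonomy")
        if "phylum" not in self.table.columns:
            raise CommunityTableError("taxonomy requires a 'phylum' column")
        if "class_" not in self.table.columns:
            self.table = self.table.assign(class_="unassigned")
        self.table = self.table.fillna({"phylum": "unassigned"})

    @property
    def asv_ids(self) -> list:
        return list(self.table.index)

    def phylum_of(self, asv_id) -> str:
        return str(self.table.loc[asv_id, "phylum"])


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis.

    Defaults mirror the study design: subsamples of 14 hosts per site
    drawn 100 times, 50 replicates for the modularity comparison, an
    exact-test threshold of 0.01 per tail, a "low prevalence" cutoff of
    five hosts (strictly below five, i.e. <= 4), and a Bonferroni-corrected
    alpha of 1.31e-4 used when summarizing the comparison tables.
    """

    subsample_hosts: int = 14
    n_replicates: int = 100
    n_replicates_modularity: int = 50
    pair_alpha: float = 0.01
    prevalence_threshold: int = 5
    bonferroni_alpha: float = 1.31e-4
    rng_seed: int = 0
    # secondary knobs
    min_family_samples: int = 8
    c_min: int | None = None  # None -> minimum retained host depth
    n_null_pd: int = 999
    n_permutations: int = 999
    modularity_restarts: int = 20
    filter_before_normalize: bool = True
    focal_phyla: tuple = ("Proteobacteria", "Firmicutes")

    def __post_init__(self) -> None:
        if not (0.0 < self.pair_alpha < 1.0):
            raise ValueError("pair_alpha must lie in (0, 1)")
        if self.subsample_hosts < 2:
            raise ValueError("subsample_hosts must be >= 2")


# -- structural filters -------------------------------------------------

def filter_host_families(table: CommunityTable, min_samples: int = 8) -> CommunityTable:
    """Drop hosts belonging to families with fewer than ``min_samples`` hosts.

    The default removes families with seven or fewer sampled hosts.
    Raises if nothing survives the filter.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    sizes = table.host_family.value_counts()
    keep_families = sizes.index[sizes >= min_samples]
    keep = table.host_family.isin(keep_families)
    if not keep.any():
        raise CommunityTableError(
            f"no host family has >= {min_samples} samples; table would be empty"
        )
    return CommunityTable(table.counts.loc[keep.to_numpy()], table.metadata)


def to_presence_absence(table: CommunityTable) -> CommunityTable:
    """Binarize counts: 1 where count > 0, else 0.  Metadata unchanged."""
    return CommunityTable((table.counts > 0).astype(np.int64), table.metadata)


def phylum_members(
    taxonomy: Taxonomy,
    phylum_label: str,
    synonyms: Mapping[str, str] | None = None,
) -> set:
    """ASVs assigned to ``phylum_label``, optionally via a synonym map.

    ``synonyms`` maps lower-rank or legacy labels onto phylum labels
    (e.g. ``{"Clostridia": "Firmicutes"}``), so ASVs recorded under a class
    or order formerly placed in the phylum are summed into it.  An unknown
    label yields an empty set with a warning.
    """
    synonyms = dict(synonyms or {})
    phyla = taxonomy.table["phylum"].astype(str)
    resolved = phyla.map(lambda p: synonyms.get(p, p))
    members = set(taxonomy.table.index[resolved == phylum_label])
    if not members:
        known = set(resolved)
        if phylum_label not in known:
            warnings.warn(
                f"phylum label {phylum_label!r} not present in taxonomy",
                stacklevel=2,
            )
    return members
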