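"""Shared fixtures: hand-built tables and session-scoped synthetic data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hostgen.datamodel import CommunityTable, Taxonomy
from hostgen.synthetic import SyntheticSpec, simulate_community, simulate_host_tree


@pytest.fixture
def make_table():
    """Factory: CommunityTable from a counts array and optional labels."""

    def _make(counts, sites=None, species=None, families=None, host_ids=None, asv_ids=None):
        counts = np.asarray(counts)
        n_h, n_a = counts.shape
        host_ids = host_ids or [f"h{i + 1}" for i in range(n_h)]
        asv_ids = asv_ids or [f"a{j + 1}" for j in range(n_a)]
        meta = pd.DataFrame(
            {
                "site": sites or ["s1"] * n_h,
                "host_species": species or [f"sp{i + 1}" for i in range(n_h)],
                "host_family": families or ["famA"] * n_h,
            },
            index=host_ids,
        )
        return CommunityTable(
            pd.DataFrame(counts, index=host_ids, columns=asv_ids), meta
        )

    return _make


@pytest.fixture(scope="session")
def host_tree16():
    return simulate_host_tree(16, seed=5)


@pytest.fixture(scope="session")
def default_dataset():
    """One realization of the default six-site synthetic design."""
    spec = SyntheticSpec(seed=42)
    host_tree = simulate_host_tree(spec.host_tree_tips, seed=42)
    table, taxonomy, bact_tree, truth = simulate_community(spec, host_tree)
    return spec, host_tree, table, taxonomy, bact_tree, truth


@pytest.fixture
def small_taxonomy():
    return Taxonomy(
        pd.DataFrame(
            {
                "phylum": [
                    "Proteobacteria",
                    "Proteobacteria",
                    "Proteobacteria",
                    "Firmicutes",
                    "Clostridia",
                ],
                "class_": [
                    "Gammaproteobacteria",
                    "Alphaproteobacteria",
                    "Gammaproteobacteria",
                    "Bacilli",
                    "Clostridia",
                ],
            },
            index=[f"a{i + 1}" for i in range(5)],
        )
    )
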