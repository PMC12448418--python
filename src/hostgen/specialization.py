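"""Host-phylogenetic specialization and prevalence metrics.

An ASV's host specialization is the standardized effect size (SES) of
the Faith's PD of its occupied hosts against a richness-preserving null:
null tip sets of the same size are drawn uniformly from all tree tips.
Negative SES marks host specialists (occupied hosts cluster in the
tree), positive SES marks phylogenetic generalists.  Host individuals
map to species tips, so PD is computed over the set of distinct occupied
species: duplicate individuals of one species collapse onto one tip.

Prevalence metrics are computed on repeated fixed-size host subsamples
per site (the study's 14-host, 100-replicate design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CommunityTable
from .trees import PhyloTree, TreeError


@dataclass
class SESResult:
    pd_obs: float
    null_mean: float
    null_sd: float
    z: float  # nan when the null is degenerate (sd == 0)
    rank_p: float
    n_null: int

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.z)


@dataclass
class ReplicateMetrics:
    site: str
    replicate_index: int
    median_within_host_richness: float
    site_richness: int
    prop_low_prevalence: float
    max_prevalence: int
    n_occurring: int


def faith_pd(tips: Iterable[str], tree: PhyloTree) -> float:
    """Faith's PD of a tip set (root included)."""
    return tree.faith_pd(tips)


def hosts_to_species_tips(
    hosts: Iterable, species_of_host: Mapping, tree: PhyloTree
) -> set:
    """Map host individuals to the distinct species tips they represent."""
    tips = {species_of_host[h] for h in hosts}
    missing = tips - set(tree.tips)
    if missing:
        raise TreeError(f"host species not in tree: {sorted(missing)}")
    return tips


class SESCalculator:
    """SES-PD with richness-shared null distributions.

    The uniform-resampling null depends only on the tip-set size, so one
    calculator precomputes (lazily, per richness) a shared null sample of
    ``n_null`` PD values and reuses it for every ASV of that richness.
    """

    def __init__(
        self,
        tree: PhyloTree,
        n_null: int = 999,
        seed: int = 0,
        pool: Iterable[str] | None = None,
    ):
        """``pool`` restricts null draws to a tip subset.

        Pass the species actually present in the host community under
        analysis (the equivalent of pruning the tree to the community);
        the default ``None`` draws from every tree tip.
        """
        self.tree = tree
        self.n_null = n_null
        self._seed = seed
        if pool is None:
            self._pool = np.arange(tree.n_tips)
        else:
            index = {t: i for i, t in enumerate(tree.tips)}
            self._pool = np.array(sorted(index[t] for t in set(pool)))
            if len(self._pool) == 0:
                raise TreeError("empty null pool")
        self._null: dict[int, np.ndarray] = {}

    def _null_pd(self, k: int) -> np.ndarray:
        if k not in self._null:
            n_pool = len(self._pool)
            rng = np.random.default_rng(np.random.SeedSequence([self._seed, k]))
            sets = np.zeros((self.n_null, self.tree.n_tips), dtype=bool)
            if k >= n_pool:
                sets[:, self._pool] = True
            else:
                # k smallest of random keys per row = uniform k-subset
                keys = rng.random((self.n_null, n_pool))
                idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
                chosen = self._pool[idx]
                np.put_along_axis(sets, chosen, True, axis=1)
            self._null[k] = self.tree.faith_pd_sets(sets)
        return self._null[k]

    def z_for_sets(self, sets: np.ndarray) -> np.ndarray:
        """Vectorized z-scores for many tip sets (rows of a boolean matrix).

        Rows with zero tips or a degenerate null (sd == 0) yield NaN.
        """
        sets = np.asarray(sets, dtype=bool)
        ks = sets.sum(axis=1)
        z = np.full(len(ks), np.nan)
        nonzero = ks > 0
        if not nonzero.any():
            return z
        pd_obs = np.full(len(ks), np.nan)
        pd_obs[nonzero] = self.tree.faith_pd_sets(sets[nonzero])
        for k in np.unique(ks[nonzero]):
            null = self._null_pd(int(k))
            sd = float(null.std(ddof=1))
            if sd > 1e-9 * max(1.0, abs(float(null.mean()))):
                mask = ks == k
                z[mask] = (pd_obs[mask] - null.mean()) / sd
        return z

    def ses(self, tip_labels: Iterable[str]) -> SESResult:
        tips = set(tip_labels)
        if not tips:
            raise TreeError("empty occupied tip set")
        pd_obs = self.tree.faith_pd(tips)
        null = self._null_pd(len(tips))
        mean = float(null.mean())
        sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
        degenerate = sd <= 1e-9 * max(1.0, abs(mean))
        z = float("nan") if degenerate else (pd_obs - mean) / sd
        rank_p = (1.0 + float((null <= pd_obs + 1e-12).sum())) / (len(null) + 1.0)
        return SESResult(pd_obs, mean, sd, z, rank_p, len(null))


def ses_pd(
    occupied_hosts: Iterable,
    host_tree: PhyloTree,
    species_of_host: Mapping | None = None,
    n_null: int = 999,
    seed: int = 0,
    pool: Iterable | None = None,
) -> SESResult:
    """SES of Faith's PD for one occupied-host set against the uniform null.

    ``species_of_host`` maps host individuals to tree tips; pass ``None``
    when hosts are tips already.  When every tip is occupied, or the tree
    geometry makes all equal-richness sets equal in PD (a star), the null
    is degenerate: ``z`` is NaN and ``degenerate`` is set.
    """
    hosts = list(occupied_hosts)
    if species_of_host is not None:
        tips = hosts_to_species_tips(hosts, species_of_host, host_tree)
    else:
        tips = set(hosts)
        unknown = tips - set(host_tree.tips)
        if unknown:
            raise TreeError(f"occupied set maps to no tree tips: {sorted(unknown)}")
    calc = SESCalculator(host_tree, n_null=n_null, seed=seed, pool=pool)
    return calc.ses(tips)


def subsample_hosts(
    table: CommunityTable, site: str, n: int, seed: int
) -> CommunityTable:
    """Draw ``n`` hosts of one site without replacement (columns retained)."""
    site_hosts = [h for h, s in table.site.items() if s == site]
    if len(site_hosts) < n:
        raise ValueError(f"site {site!r} has {len(site_hosts)} hosts < n={n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(len(site_hosts), size=n, replace=False)
    return table.subset_hosts([site_hosts[i] for i in sorted(chosen)])


def replicate_metrics(
    replicate: CommunityTable,
    asv_subset: Iterable | None = None,
    threshold: int = 5,
    site: str = "",
    replicate_index: int = 0,
) -> ReplicateMetrics:
    """Richness and prevalence summaries for one subsample replicate.

    Richness counts ASVs with >= 1 occurrence; ``prop_low_prevalence`` is
    the fraction of occurring ASVs seen in strictly fewer than
    ``threshold`` hosts; ``max_prevalence`` is the largest column
    prevalence.  With an ``asv_subset``, metrics are restricted to those
    columns; a subset disjoint from the occurring ASVs yields NaN
    metrics rather than zeros.
    """
    counts = replicate.counts
    if asv_subset is not None:
        cols = [a for a in counts.columns if a in set(asv_subset)]
        counts = counts[cols]
    presence = counts > 0
    prevalence = presence.sum(axis=0)
    occurring = prevalence[prevalence > 0]
    if len(occurring) == 0:
        return ReplicateMetrics(
            site, replicate_index, float("nan"), 0, float("nan"), 0, 0
        )
    return ReplicateMetrics(
        site=site,
        replicate_index=replicate_index,
        median_within_host_richness=float(presence.sum(axis=1).median()),
        site_richness=int(len(occurring)),
        prop_low_prevalence=float((occurring < threshold).mean()),
        max_prevalence=int(occurring.max()),
        n_occurring=int(len(occurring)),
    )


def mean_asv_summary(
    prevalence_by_site: Mapping[str, float],
    ses_by_site: Mapping[str, float],
    hosts_sampled: int,
) -> tuple[float, float]:
    """Mean prevalence proportion and mean SES across occupied sites.

    ``prevalence_by_site`` holds host counts for the sites where the ASV
    occurred (prevalence >= 1); sites where it is absent must simply be
    left out.  Prevalence is expressed as a proportion of the
    ``hosts_sampled`` per site.  SES entries may be NaN (degenerate
    nulls) and are ignored in the mean.
    """
    prevs = [v for v in prevalence_by_site.values() if v > 0]
    if not prevs:
        raise ValueError("ASV occurs in no site")
    mean_prev = float(np.mean(prevs)) / hosts_sampled
    ses_vals = [v for v in ses_by_site.values() if np.isfinite(v)]
    mean_ses = float(np.mean(ses_vals)) if ses_vals else float("nan")
    return mean_prev, mean_ses


def patristic_distance(tree: PhyloTree, a: str, b: str) -> float:
    return tree.patristic_distance(a, b)


def nearest_neighbor_distances(tree: PhyloTree) -> pd.Series:
    return tree.nearest_neighbor_distances()
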