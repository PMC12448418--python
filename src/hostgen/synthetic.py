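"""Synthetic multi-site host-microbiome communities with planted structure.

The generator emulates the statistical structure of a latitudinal
cloacal-microbiome survey: six sites with a graded number of host
species drawn as nested pools from one global host phylogeny, host
individuals sampled per site, and an ASV panel mixing

* clade-restricted **specialists** (high occupancy inside one host
  clade, near-zero outside),
* uniform **generalists** (one occupancy probability for every host),
* a large low-occupancy **background** class that naturally yields many
  singletons, and
* planted **cohorts** whose members share a per-host latent switch that
  multiplies their occupancy odds, producing positive co-occurrence.

Occupied cells receive lognormal abundances and each host's counts are
scaled to a random target depth, so SRS normalization has real work to
do.  Ground-truth roles, specialist clades and cohort pairs are returned
for parameter-recovery tests.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .datamodel import CommunityTable, Taxonomy
from .trees import PhyloTree

# default per-site host species richness, echoing a temperate-to-tropics
# survey gradient, and per-site individual sample sizes (smallest = 15 so
# that the standard 14-host subsample is one fewer than the smallest site)
DEFAULT_SPECIES_PER_SITE = (5, 12, 15, 15, 29, 30)
DEFAULT_HOSTS_PER_SITE = (15, 20, 24, 24, 28, 30)
_BACKGROUND_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Planctomycetota",
    "Actinobacteriota",
    "Bacteroidota",
)
_CLASS_OF = {
    "Firmicutes": ("Clostridia", "Bacilli"),
    "Proteobacteria": ("Gammaproteobacteria", "Alphaproteobacteria"),
}


class SyntheticSpecError(ValueError):
    pass


def _default_cohorts():
    # five planted pairs among the generalist block (indices are global
    # ASV indices; generalists follow the specialist block)
    return [((40 + 2 * k, 40 + 2 * k + 1), 1000.0) for k in range(5)]


@dataclass
class SyntheticSpec:
    n_sites: int = 6
    hosts_per_site: Sequence[int] = DEFAULT_HOSTS_PER_SITE
    species_per_site: Sequence[int] = DEFAULT_SPECIES_PER_SITE
    host_tree_tips: int = 30
    n_specialists: int = 40
    n_generalists: int = 20
    n_background: int = 240
    cohorts: list = field(default_factory=_default_cohorts)
    specialist_clade_occupancy: float = 0.8
    specialist_out_occupancy: float = 0.02
    generalist_occupancy: float = 0.35
    background_occupancy: float = 0.015
    cohort_latent_rate: float = 0.5
    depth_range: tuple = (2000, 20000)
    abundance_meanlog: float = 1.0
    abundance_sdlog: float = 1.0
    phylum_assignment: dict = field(
        default_factory=lambda: {
            "specialist": "Firmicutes",
            "generalist": "Proteobacteria",
            "cohort": "Proteobacteria",
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.specialist_clade_occupancy,
            self.specialist_out_occupancy,
            self.generalist_occupancy,
            self.background_occupancy,
            self.cohort_latent_rate,
        ):
            if not (0.0 <= p <= 1.0):
                raise SyntheticSpecError(f"probability {p} outside [0, 1]")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise SyntheticSpecError("invalid depth_range")
        if len(self.hosts_per_site) != self.n_sites:
            raise SyntheticSpecError("hosts_per_site length != n_sites")
        if len(self.species_per_site) != self.n_sites:
            raise SyntheticSpecError("species_per_site length != n_sites")
        spec_idx = set(range(self.n_specialists))
        seen: set = set()
        for members, boost in self.cohorts:
            mset = set(members)
            if mset & spec_idx:
                raise SyntheticSpecError("cohort sets must be disjoint from specialists")
            if mset & seen:
                raise SyntheticSpecError("cohort sets must be mutually disjoint")
            if boost <= 0:
                raise SyntheticSpecError("cohort boost must be positive")
            seen |= mset

    @property
    def n_asvs(self) -> int:
        return self.n_specialists + self.n_generalists + self.n_background


@dataclass
class PlantedTruth:
    role: pd.Series  # per-ASV: specialist | generalist | background | cohort_k
    specialist_clade: dict  # specialist ASV id -> frozenset of host-species tips
    cohort_pairs: list  # (asv_a, asv_b) expected positive
    singleton_fraction: float  # realized fraction of occurring ASVs with prevalence 1


def simulate_host_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> PhyloTree:
    """Yule (pure-birth) tree with exponential branch lengths.

    Deterministic given ``seed``; tips are labeled sp01, sp02, ...
    """
    if n_tips < 3:
        raise SyntheticSpecError("n_tips must be >= 3")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace(
        [f"sp{i + 1:02d}" for i in range(n_tips)]
    )
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=rng,
    )
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    return PhyloTree(tree)


def _boosted(p: float, boost: float, latent_on: bool) -> float:
    """Multiply (latent on) or divide (latent off) the occupancy odds."""
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    if np.isinf(boost):
        return 1.0 if latent_on else 0.0
    odds = p / (1.0 - p)
    odds = odds * boost if latent_on else odds / boost
    return odds / (1.0 + odds)


def simulate_community(
    spec: SyntheticSpec, host_tree: PhyloTree
) -> tuple[CommunityTable, Taxonomy, PhyloTree, PlantedTruth]:
    """Draw one synthetic dataset under ``spec`` on ``host_tree``.

    Returns the count table (hosts x ASVs with per-host site/species/
    family metadata), the taxonomy, a bacterial phylogeny over the ASVs
    (cohort members placed at mid-range patristic separation so
    nearest-neighbor comparisons are meaningful), and the planted truth.
    Bit-identical output for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    tips = list(host_tree.tips)
    if max(spec.species_per_site) > len(tips):
        raise SyntheticSpecError("species_per_site exceeds host tree tips")

    # nested species pools grade richness across sites
    pool_order = list(rng.permutation(tips))
    site_names = [f"site{i + 1}" for i in range(spec.n_sites)]
    host_ids, host_species, host_site = [], [], []
    for i, site in enumerate(site_names):
        pool = pool_order[: spec.species_per_site[i]]
        for j in range(spec.hosts_per_site[i]):
            host_ids.append(f"{site}_h{j + 1:02d}")
            host_species.append(pool[rng.integers(len(pool))])
            host_site.append(site)
    n_hosts = len(host_ids)
    species_arr = np.array(host_species)

    # host families: partition the tree into disjoint clades (largest
    # clades no bigger than ~1/3 of the tips) so related species share a
    # family label; stragglers form their own families
    fam_clades = sorted(
        host_tree.clades(min_size=2, max_frac=0.34), key=len, reverse=True
    )
    family_of: dict = {}
    fam_idx = 0
    for clade in fam_clades:
        if not (clade & set(family_of)):
            for t in clade:
                family_of[t] = f"fam{fam_idx}"
            fam_idx += 1
    for t in tips:
        if t not in family_of:
            family_of[t] = f"fam{fam_idx}"
            fam_idx += 1
    host_family = [family_of[s] for s in host_species]

    # roles
    n_spec, n_gen = spec.n_specialists, spec.n_generalists
    asv_ids = [f"asv{k + 1:04d}" for k in range(spec.n_asvs)]
    roles = np.array(
        ["specialist"] * n_spec
        + ["generalist"] * n_gen
        + ["background"] * spec.n_background,
        dtype=object,
    )
    boost_of = np.ones(spec.n_asvs)
    cohort_of = np.full(spec.n_asvs, -1)
    for k, (members, boost) in enumerate(spec.cohorts):
        for idx in members:
            if idx >= spec.n_asvs:
                raise SyntheticSpecError(f"cohort index {idx} out of range")
            roles[idx] = f"cohort_{k}"
            boost_of[idx] = boost
            cohort_of[idx] = k

    # specialist clades
    clades = host_tree.clades(min_size=2, max_frac=0.6)
    if not clades:
        raise SyntheticSpecError("host tree has no clade of >= 2 tips")
    specialist_clade: dict = {}
    clade_mask = np.zeros((n_spec, n_hosts), dtype=bool)
    for s in range(n_spec):
        clade = clades[rng.integers(len(clades))]
        specialist_clade[asv_ids[s]] = frozenset(clade)
        clade_mask[s] = np.isin(species_arr, list(clade))

    # occupancy probabilities per (host, ASV)
    prob = np.empty((n_hosts, spec.n_asvs))
    prob[:, :n_spec] = np.where(
        clade_mask.T, spec.specialist_clade_occupancy, spec.specialist_out_occupancy
    )
    prob[:, n_spec : n_spec + n_gen] = spec.generalist_occupancy
    prob[:, n_spec + n_gen :] = spec.background_occupancy

    # cohort latent switches modulate the odds of members jointly
    for k in range(len(spec.cohorts)):
        members = np.flatnonzero(cohort_of == k)
        boost = boost_of[members[0]]
        z = rng.random(n_hosts) < spec.cohort_latent_rate
        for idx in members:
            base = prob[:, idx].copy()
            prob[:, idx] = [
                _boosted(p, boost, on) for p, on in zip(base, z)
            ]

    occupancy = rng.random((n_hosts, spec.n_asvs)) < prob

    # abundances: lognormal weights on occupied cells, then exact
    # largest-remainder allocation of a random target depth per host,
    # reserving one read per occupied cell so occupancy survives scaling
    counts = np.zeros((n_hosts, spec.n_asvs), dtype=np.int64)
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, size=n_hosts)
    for h in range(n_hosts):
        occ = np.flatnonzero(occupancy[h])
        if len(occ) == 0:
            # guarantee no empty host: seed one background ASV; fall back
            # to a generalist, then anything (never break planted
            # specialist clades unless no alternative exists)
            pool = np.flatnonzero(roles == "background")
            if len(pool) == 0:
                pool = np.flatnonzero(roles == "generalist")
            if len(pool) == 0:
                pool = np.arange(spec.n_asvs)
            occ = np.array([int(pool[rng.integers(len(pool))])])
            occupancy[h, occ[0]] = True
        w = rng.lognormal(spec.abundance_meanlog, spec.abundance_sdlog, size=len(occ))
        target = int(depths[h]) - len(occ)
        scaled = w * (target / w.sum())
        floors = np.floor(scaled).astype(np.int64)
        frac = scaled - floors
        short = target - int(floors.sum())
        if short > 0:
            order = np.argsort(-frac, kind="stable")
            floors[order[:short]] += 1
        counts[h, occ] = floors + 1

    table = CommunityTable(
        pd.DataFrame(counts, index=host_ids, columns=asv_ids),
        pd.DataFrame(
            {
                "site": host_site,
                "host_species": host_species,
                "host_family": host_family,
            },
            index=host_ids,
        ),
    )

    # taxonomy from role -> phylum map; background spread across phyla
    phyla = []
    for r in roles:
        key = "cohort" if r.startswith("cohort") else r
        label = spec.phylum_assignment.get(key)
        if label is None:
            label = _BACKGROUND_PHYLA[rng.integers(len(_BACKGROUND_PHYLA))]
        phyla.append(label)
    classes = [
        _CLASS_OF[p][rng.integers(2)] if p in _CLASS_OF else "unassigned"
        for p in phyla
    ]
    taxonomy = Taxonomy(
        pd.DataFrame({"phylum": phyla, "class_": classes}, index=asv_ids)
    )

    # bacterial tree: Yule over the ASVs; cohort pairs mapped onto tip
    # pairs of mid-range patristic separation
    bact_seed = int(np.random.SeedSequence([spec.seed, 2]).generate_state(1)[0] % 2**31)
    raw = simulate_host_tree(spec.n_asvs, seed=bact_seed)
    dmat = raw.patristic_matrix().to_numpy()
    iu = np.triu_indices_from(dmat, k=1)
    # mid-range band: clearly above nearest-neighbor separations yet
    # below the all-pairs mean (tip distances on Yule trees skew left, so
    # the band must sit below the median to stay under the mean)
    lo, hi = np.percentile(dmat[iu], [20, 45])
    raw_tips = list(raw.tips)
    assignment: dict = {}
    used: set = set()
    for k, (members, _) in enumerate(spec.cohorts):
        members = list(members)
        candidates = [
            (i, j)
            for i in range(len(raw_tips))
            for j in range(i + 1, len(raw_tips))
            if lo <= dmat[i, j] <= hi and i not in used and j not in used
        ]
        for pair_pos in range(0, len(members) - 1, 2):
            i, j = candidates[rng.integers(len(candidates))]
            assignment[raw_tips[i]] = asv_ids[members[pair_pos]]
            assignment[raw_tips[j]] = asv_ids[members[pair_pos + 1]]
            used |= {i, j}
            candidates = [c for c in candidates if c[0] not in (i, j) and c[1] not in (i, j)]
    remaining_asvs = [a for a in asv_ids if a not in set(assignment.values())]
    remaining_tips = [t for i, t in enumerate(raw_tips) if i not in used]
    perm = rng.permutation(len(remaining_tips))
    for t, a_idx in zip(remaining_tips, perm):
        assignment[t] = remaining_asvs[a_idx]
    for leaf in raw._tree.leaf_node_iter():
        leaf.taxon.label = assignment[leaf.taxon.label]
    bacterial_tree = PhyloTree(raw._tree)

    prevalence = (counts > 0).sum(axis=0)
    occurring = prevalence[prevalence > 0]
    truth = PlantedTruth(
        role=pd.Series(roles, index=asv_ids),
        specialist_clade=specialist_clade,
        cohort_pairs=[
            (asv_ids[a], asv_ids[b])
            for members, _ in spec.cohorts
            for a, b in itertools.combinations(sorted(members), 2)
        ],
        singleton_fraction=float((occurring == 1).mean()),
    )
    return table, taxonomy, bacterial_tree, truth
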