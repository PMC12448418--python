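"""Exact probabilistic pairwise co-occurrence testing and its nulls.

For two ASVs with prevalences N1 and N2 among N hosts, the number of
shared hosts j under random, independent placement follows

    P(j) = C(N1, j) * C(N - N1, N2 - j) / C(N, N2),

the hypergeometric law.  A pair is *positive* when the upper tail
P(J >= j_obs) falls below alpha, *negative* when the lower tail
P(J <= j_obs) does, and *random* otherwise; both tails include the
observed value, the standard convention for discrete exact tests.

Two null constructions accompany the test: the column-shuffle null
(permute each ASV's occupancy vector independently, preserving every
column multiset and hence all prevalences while destroying host
associations) and the prevalence-matched null (replace each member of a
pair by a random ASV of identical prevalence).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import CommunityTable, Taxonomy
from .specialization import SESCalculator, SESResult, hosts_to_species_tips
from .trees import PhyloTree


class CooccurrenceError(ValueError):
    pass


@dataclass
class PairTest:
    asv_a: object
    asv_b: object
    n_hosts: int
    prev_a: int
    prev_b: int
    shared_obs: int
    p_lt: float
    p_gt: float
    classification: str  # positive | negative | random


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def shared_host_pmf(N: int, N1: int, N2: int, j: int) -> float:
    """P(two ASVs of prevalence N1, N2 share exactly j of N hosts).

    Computed in log space for stability.  Infeasible j (outside
    [max(0, N1+N2-N), min(N1, N2)]) returns 0; invalid prevalences raise.
    """
    if not (0 <= N1 <= N and 0 <= N2 <= N):
        raise CooccurrenceError(f"invalid prevalences N1={N1}, N2={N2} for N={N}")
    if j < max(0, N1 + N2 - N) or j > min(N1, N2):
        return 0.0
    logp = _log_comb(N1, j) + _log_comb(N - N1, N2 - j) - _log_comb(N, N2)
    return float(np.exp(logp))


@lru_cache(maxsize=100_000)
def _tails(N: int, N1: int, N2: int):
    """(j_min, p_lt array, p_gt array) over the feasible range of j."""
    j_min = max(0, N1 + N2 - N)
    j_max = min(N1, N2)
    js = np.arange(j_min, j_max + 1)
    pmf = np.array([shared_host_pmf(N, N1, N2, int(j)) for j in js])
    pmf = pmf / pmf.sum()  # guard rounding; analytically sums to 1
    return j_min, np.cumsum(pmf), np.cumsum(pmf[::-1])[::-1]


def pair_test(
    N: int, N1: int, N2: int, j_obs: int, alpha: float = 0.01, asv_a=None, asv_b=None
) -> PairTest:
    """Exact two-tailed co-occurrence test for one ASV pair."""
    j_min = max(0, N1 + N2 - N)
    j_max = min(N1, N2)
    if not (j_min <= j_obs <= j_max):
        raise CooccurrenceError(
            f"observed overlap {j_obs} infeasible for N={N}, N1={N1}, N2={N2}"
        )
    j0, lt, gt = _tails(N, N1, N2)
    p_lt = float(lt[j_obs - j0])
    p_gt = float(gt[j_obs - j0])
    assert p_lt + p_gt >= 1.0 - 1e-9  # both tails contain the observed value
    if p_gt < alpha:
        cls = "positive"
    elif p_lt < alpha:
        cls = "negative"
    else:
        cls = "random"
    return PairTest(asv_a, asv_b, N, N1, N2, j_obs, p_lt, p_gt, cls)


@lru_cache(maxsize=16)
def _tail_lookup(N: int):
    """Dense (N1, N2, j) -> tail probability tables for host count N."""
    lt = np.ones((N + 1, N + 1, N + 1))
    gt = np.ones((N + 1, N + 1, N + 1))
    for n1 in range(N + 1):
        for n2 in range(N + 1):
            j0, l, g = _tails(N, n1, n2)
            lt[n1, n2, j0 : j0 + len(l)] = l
            gt[n1, n2, j0 : j0 + len(g)] = g
    return lt, gt


def classify_all_pairs(
    presence: CommunityTable,
    alpha: float = 0.01,
    min_expected: float | None = None,
) -> pd.DataFrame:
    """Exact co-occurrence test for every unordered pair of occurring ASVs.

    ``presence`` must be binary.  No multiple-testing correction is
    applied.  ``min_expected`` optionally reproduces the convention of
    dropping pairs whose expected overlap N1*N2/N is below the given
    value; the default tests all pairs.

    Returns a DataFrame with one row per tested pair and a
    ``classification`` column in {positive, negative, random}.
    """
    mat = presence.counts.to_numpy()
    if mat.size and not np.isin(mat, (0, 1)).all():
        raise CooccurrenceError("classify_all_pairs requires a binary table")
    prev = mat.sum(axis=0)
    keep = np.flatnonzero(prev >= 1)
    if len(keep) < 2:
        raise CooccurrenceError("fewer than 2 occurring ASVs")
    sub = mat[:, keep]
    shared = sub.T @ sub
    n = mat.shape[0]
    asvs = np.asarray([presence.asv_ids[i] for i in keep], dtype=object)
    ia, ib = np.triu_indices(len(keep), k=1)
    n1, n2 = prev[keep][ia], prev[keep][ib]
    j = shared[ia, ib]
    if min_expected is not None:
        mask = (n1 * n2) / n >= min_expected
        ia, ib, n1, n2, j = ia[mask], ib[mask], n1[mask], n2[mask], j[mask]
    lt_tab, gt_tab = _tail_lookup(n)
    p_lt = lt_tab[n1, n2, j]
    p_gt = gt_tab[n1, n2, j]
    classification = np.where(
        p_gt < alpha, "positive", np.where(p_lt < alpha, "negative", "random")
    )
    return pd.DataFrame(
        {
            "asv_a": asvs[ia],
            "asv_b": asvs[ib],
            "n_hosts": n,
            "prev_a": n1,
            "prev_b": n2,
            "shared_obs": j,
            "p_lt": p_lt,
            "p_gt": p_gt,
            "classification": classification,
        }
    )


def shuffle_null(table: CommunityTable, seed: int) -> CommunityTable:
    """Column-shuffle null: permute each ASV column independently.

    Every column multiset (and so every ASV prevalence) is preserved
    exactly; host row totals generally change.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shuffled = rng.permuted(table.counts.to_numpy(), axis=0)
    return CommunityTable(
        pd.DataFrame(shuffled, index=table.counts.index, columns=table.counts.columns),
        table.metadata,
    )


def prevalence_matched_pair(
    pair: PairTest, presence: CommunityTable, seed: int
) -> tuple:
    """Draw a prevalence-matched surrogate for each member of a pair.

    Each surrogate is sampled uniformly among ASVs with *identical*
    prevalence, excluding both pair members.  When no exact match
    exists, the nearest-prevalence ASV is taken and the substitution is
    reported in the returned flags.

    Returns ``(asv_for_a, asv_for_b, exact_a, exact_b)``.
    """
    if presence.n_asvs < 4:
        raise CooccurrenceError("need >= 4 ASVs for prevalence matching")
    prev = presence.prevalence()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out, exact = [], []
    taken = {pair.asv_a, pair.asv_b}
    for target in (pair.prev_a, pair.prev_b):
        pool = [a for a in presence.asv_ids if a not in taken and prev[a] == target]
        if pool:
            choice = pool[rng.integers(len(pool))]
            exact.append(True)
        else:
            candidates = [a for a in presence.asv_ids if a not in taken]
            gaps = np.array([abs(int(prev[a]) - target) for a in candidates])
            nearest = np.flatnonzero(gaps == gaps.min())
            choice = candidates[nearest[rng.integers(len(nearest))]]
            exact.append(False)
            warnings.warn(
                f"no prevalence-{target} match; nearest used ({choice})",
                stacklevel=2,
            )
        out.append(choice)
        taken.add(choice)
    return out[0], out[1], exact[0], exact[1]


def shared_host_specialization(
    pair: PairTest,
    presence: CommunityTable,
    host_tree: PhyloTree,
    species_of_host: Mapping | None = None,
    n_null: int = 999,
    seed: int = 0,
    calculator: SESCalculator | None = None,
) -> SESResult:
    """SES-PD of the hosts occupied by *both* members of a pair.

    Tests whether the shared hosts are more phylogenetically related than
    a uniform draw of equally many tips.  An empty intersection raises.
    """
    col_a = presence.counts[pair.asv_a] > 0
    col_b = presence.counts[pair.asv_b] > 0
    shared_hosts = [h for h, both in (col_a & col_b).items() if both]
    if not shared_hosts:
        raise CooccurrenceError("pair shares no hosts; SES undefined")
    if species_of_host is not None:
        tips = hosts_to_species_tips(shared_hosts, species_of_host, host_tree)
    else:
        tips = set(shared_hosts)
    if calculator is None:
        calculator = SESCalculator(host_tree, n_null=n_null, seed=seed)
    return calculator.ses(tips)


def phylum_pair_excess(
    pairs: pd.DataFrame, members: Iterable, asv_universe: Iterable
) -> tuple[float, float]:
    """Observed vs expected fraction of positive pairs within one phylum.

    ``members`` is the phylum's ASV id set and ``asv_universe`` the ASVs
    of the dataset the pairs were drawn from.  Expected under random
    pairing is the squared phylum fraction.  Raises when there are no
    positive pairs (the run is then excluded from downstream t-tests).
    """
    members = set(members)
    universe = list(asv_universe)
    positive = pairs[pairs["classification"] == "positive"]
    if len(positive) == 0:
        raise CooccurrenceError("no positive pairs; excess undefined")
    both = (
        positive["asv_a"].isin(members) & positive["asv_b"].isin(members)
    ).mean()
    frac = sum(a in members for a in universe) / len(universe)
    return float(both), float(frac**2)


def pair_distance_summary(
    pairs: pd.DataFrame, bacterial_tree: PhyloTree
) -> dict[str, np.ndarray]:
    """Patristic-distance distributions for co-occurring pairs vs the tree.

    Returns three arrays: distances between the given (typically
    positive) pairs, nearest-neighbor distances over all tree tips, and
    all pairwise tip distances.  Pairs with a member missing from the
    tree are skipped with a warning.
    """
    tips = set(bacterial_tree.tips)
    pair_d = []
    for a, b in zip(pairs["asv_a"], pairs["asv_b"]):
        if a not in tips or b not in tips:
            warnings.warn(f"pair ({a}, {b}) missing from tree; skipped", stacklevel=2)
            continue
        pair_d.append(bacterial_tree.patristic_distance(a, b))
    dmat = bacterial_tree.patristic_matrix().to_numpy()
    iu = np.triu_indices_from(dmat, k=1)
    return {
        "pair": np.asarray(pair_d, dtype=float),
        "nearest_neighbor": bacterial_tree.nearest_neighbor_distances().to_numpy(),
        "all_pairs": dmat[iu],
    }
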