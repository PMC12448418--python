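"""Host-ASV bipartite networks and Barber modularity.

A presence/absence table becomes a two-mode network in which an ASV is
linked to every host it occupies (ASVs interact only through shared
hosts).  ASVs occurring in fewer than ``min_hosts`` hosts (default 2)
are excluded at construction.  Barber's bipartite form of Newman
modularity scores a partition of hosts and ASVs into modules:

    Q = (1/m) * sum_s (e_s - K_s * L_s / m)

with e_s the within-module edges, K_s and L_s the module's host- and
ASV-side degree sums, and m the total edge count.  The trivial
one-module partition scores exactly 0.

Optimization uses label propagation seeded from singleton host modules
followed by greedy module agglomeration, repeated over random restarts
(the LPAwb+ recipe); an exhaustive enumerator over all set partitions
guards correctness on small networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cooccurrence import shuffle_null
from .datamodel import CommunityTable, to_presence_absence
from .specialization import subsample_hosts


class NetworkError(ValueError):
    pass


@dataclass
class BipartiteNetwork:
    host_nodes: tuple
    asv_nodes: tuple
    incidence: np.ndarray  # hosts x asvs, bool

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=bool)
        if inc.shape != (len(self.host_nodes), len(self.asv_nodes)):
            raise NetworkError("incidence shape mismatch")
        if inc.sum() == 0:
            raise NetworkError("empty network")
        self.incidence = inc

    @property
    def m(self) -> int:
        return int(self.incidence.sum())

    @property
    def host_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    @property
    def asv_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0)

    @property
    def edges(self) -> list:
        hs, As = np.nonzero(self.incidence)
        return [(self.host_nodes[h], self.asv_nodes[a]) for h, a in zip(hs, As)]

    @property
    def n_nodes(self) -> int:
        return len(self.host_nodes) + len(self.asv_nodes)


@dataclass
class ModularityResult:
    partition: dict  # node label -> module id
    Q: float
    n_modules: int
    restarts_used: int


def build_network(presence: CommunityTable, min_hosts: int = 2) -> BipartiteNetwork:
    """Bipartite host-ASV network from a binary table.

    ASVs with prevalence < ``min_hosts`` are dropped; hosts left with no
    edges are dropped too.
    """
    mat = presence.counts.to_numpy()
    if mat.size and not np.isin(mat, (0, 1)).all():
        raise NetworkError("build_network requires a binary table")
    keep_asv = mat.sum(axis=0) >= min_hosts
    sub = mat[:, keep_asv]
    keep_host = sub.sum(axis=1) >= 1
    sub = sub[keep_host]
    if sub.size == 0 or sub.sum() == 0:
        raise NetworkError("network empty after degree filtering")
    return BipartiteNetwork(
        tuple(h for h, k in zip(presence.host_ids, keep_host) if k),
        tuple(a for a, k in zip(presence.asv_ids, keep_asv) if k),
        sub.astype(bool),
    )


def _labels_to_arrays(network: BipartiteNetwork, partition: Mapping):
    try:
        hl = np.array([partition[h] for h in network.host_nodes])
        al = np.array([partition[a] for a in network.asv_nodes])
    except KeyError as exc:
        raise NetworkError(f"node missing from partition: {exc}") from exc
    return hl, al


def _q_from_arrays(inc: np.ndarray, hl: np.ndarray, al: np.ndarray) -> float:
    m = inc.sum()
    labels = np.unique(np.concatenate([hl, al]))
    q = 0.0
    hd = inc.sum(axis=1)
    ad = inc.sum(axis=0)
    for lab in labels:
        hmask = hl == lab
        amask = al == lab
        e_s = inc[np.ix_(hmask, amask)].sum()
        q += e_s - hd[hmask].sum() * ad[amask].sum() / m
    return float(q / m)


def barber_q(network: BipartiteNetwork, partition: Mapping) -> float:
    """Barber bipartite modularity of a full node partition."""
    hl, al = _labels_to_arrays(network, partition)
    return _q_from_arrays(network.incidence, hl, al)


def _propagate(inc, hl, al, hd, ad, m, rng, max_sweeps=60):
    """Label propagation: each node greedily adopts the Q-best module.

    A node of degree d moving to module s changes Q by
    (e_to_s - d * D_s / m) / m up to a constant, with D_s the opposite
    side's degree sum in s; per-module degree sums are maintained
    incrementally.  Moves to an empty module (score 0) are allowed so Q
    never decreases.
    """
    n_h, n_a = inc.shape
    size = n_h + n_a  # label universe
    ksum = np.zeros(size)  # host-degree sum per module
    lsum = np.zeros(size)  # asv-degree sum per module
    np.add.at(ksum, hl, hd)
    np.add.at(lsum, al, ad)
    nbrs_a = [np.flatnonzero(inc[:, a]) for a in range(n_a)]
    nbrs_h = [np.flatnonzero(inc[h]) for h in range(n_h)]

    def sweep_side(order, labels, own_deg, neigh_of, neigh_labels, opp_sum, own_sum):
        moved = False
        for i in order:
            cur = labels[i]
            counts = np.bincount(neigh_labels[neigh_of[i]], minlength=size)
            cand = np.flatnonzero(counts)
            score = counts[cand] - own_deg[i] * opp_sum[cand] / m
            cur_score = (
                score[np.searchsorted(cand, cur)]
                if cur in cand
                else -own_deg[i] * opp_sum[cur] / m
            )
            best_idx = int(np.argmax(score))
            best, best_score = int(cand[best_idx]), score[best_idx]
            if best_score < -1e-12:  # an empty module beats every candidate
                empty = np.flatnonzero((ksum == 0) & (lsum == 0))
                if len(empty):
                    best, best_score = int(empty[0]), 0.0
            if best != cur and best_score > cur_score + 1e-12:
                own_sum[cur] -= own_deg[i]
                own_sum[best] += own_deg[i]
                labels[i] = best
                moved = True
        return moved

    for _ in range(max_sweeps):
        moved_a = sweep_side(
            rng.permutation(n_a), al, ad, nbrs_a, hl, ksum, lsum
        )
        moved_h = sweep_side(
            rng.permutation(n_h), hl, hd, nbrs_h, al, lsum, ksum
        )
        if not (moved_a or moved_h):
            break
    return hl, al


def _agglomerate(inc, hl, al, hd, ad, m):
    """Greedy module merging while the best merge increases Q.

    Merging modules s and t changes Q by
    (E_between(s, t) - (K_s*L_t + K_t*L_s) / m) / m.
    """
    while True:
        labels, inv = np.unique(np.concatenate([hl, al]), return_inverse=True)
        L = len(labels)
        if L < 2:
            return hl, al
        hli, ali = inv[: len(hl)], inv[len(hl):]
        hh = np.zeros((len(hl), L))
        hh[np.arange(len(hl)), hli] = 1.0
        ha = np.zeros((len(al), L))
        ha[np.arange(len(al)), ali] = 1.0
        cross = hh.T @ inc @ ha  # cross[s, t] = edges hosts-in-s x asvs-in-t
        k = hh.T @ hd
        l = ha.T @ ad
        gain = (cross + cross.T - (np.outer(k, l) + np.outer(l, k)) / m) / m
        np.fill_diagonal(gain, -np.inf)
        s, t = np.unravel_index(int(np.argmax(gain)), gain.shape)
        if gain[s, t] <= 1e-12:
            return hl, al
        la, lb = labels[s], labels[t]
        hl[hl == lb] = la
        al[al == lb] = la


def optimize_modules(
    network: BipartiteNetwork, restarts: int = 20, seed: int = 0
) -> ModularityResult:
    """Maximize Barber Q by repeated label propagation + agglomeration.

    Deterministic given ``seed``; the best partition over ``restarts``
    independent runs is returned, never worse than the one-module
    baseline Q = 0.
    """
    inc = network.incidence.astype(np.int64)
    hd, ad = inc.sum(axis=1), inc.sum(axis=0)
    m = inc.sum()
    n_h, n_a = inc.shape
    best_q, best = -np.inf, None
    seeds = np.random.SeedSequence(seed).spawn(max(restarts, 1))
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        # diversify restarts: host-side singletons, ASV-side singletons,
        # or a random coarse partition
        mode = r % 3
        if mode == 0:
            hl = np.arange(n_h)
            al = np.array([rng.choice(np.flatnonzero(inc[:, a])) for a in range(n_a)])
        elif mode == 1:
            al = np.arange(n_h, n_h + n_a)
            hl = np.array([int(n_h + rng.choice(np.flatnonzero(inc[h]))) for h in range(n_h)])
        else:
            k = int(rng.integers(2, max(3, min(n_h, n_a) + 1)))
            hl = rng.integers(k, size=n_h)
            al = rng.integers(k, size=n_a)
        for _ in range(4):
            hl, al = _propagate(inc, hl, al, hd, ad, m, rng)
            hl, al = _agglomerate(inc, hl, al, hd, ad, m)
        q = _q_from_arrays(network.incidence, hl, al)
        if q > best_q:
            best_q, best = q, (hl.copy(), al.copy())
    hl, al = best
    if best_q < 0.0:  # fall back to the trivial partition (Q = 0)
        hl = np.zeros(n_h, dtype=int)
        al = np.zeros(n_a, dtype=int)
        best_q = 0.0
    # relabel modules 0..k-1 in order of first appearance
    combined = np.concatenate([hl, al])
    _, relabeled = np.unique(combined, return_inverse=True)
    partition = {
        **{h: int(relabeled[i]) for i, h in enumerate(network.host_nodes)},
        **{
            a: int(relabeled[n_h + i])
            for i, a in enumerate(network.asv_nodes)
        },
    }
    return ModularityResult(
        partition=partition,
        Q=float(best_q),
        n_modules=int(len(np.unique(relabeled))),
        restarts_used=len(seeds),
    )


def exhaustive_max_q(network: BipartiteNetwork) -> tuple[float, dict]:
    """Brute-force maximum Q over all set partitions of the nodes.

    Reference implementation for small networks only (node count <= ~12;
    the partition count is the Bell number of the node count).
    """
    inc = network.incidence.astype(np.int64)
    n_h, n_a = inc.shape
    n = n_h + n_a
    if n > 14:
        raise NetworkError("exhaustive search is limited to small networks")
    m = int(inc.sum())
    hd, ad = inc.sum(axis=1), inc.sum(axis=0)
    # per-node (side, degree, neighbor indices in the combined ordering)
    nodes = [
        (0, int(hd[h]), tuple(n_h + a for a in np.flatnonzero(inc[h])))
        for h in range(n_h)
    ] + [
        (1, int(ad[a]), tuple(int(h) for h in np.flatnonzero(inc[:, a])))
        for a in range(n_a)
    ]
    best_q, best_assign = -np.inf, None
    assign = [-1] * n
    e_blk = [0] * n  # within-block edges
    k_blk = [0] * n  # host-side degree sum
    l_blk = [0] * n  # asv-side degree sum

    def recurse(i: int, n_blocks: int, total_e: float, total_kl: float):
        nonlocal best_q, best_assign
        if i == n:
            q = (total_e - total_kl / m) / m
            if q > best_q:
                best_q, best_assign = q, assign.copy()
            return
        side, deg, neigh = nodes[i]
        for b in range(min(n_blocks + 1, n)):
            e_new = sum(1 for j in neigh if j < i and assign[j] == b)
            if side == 0:
                d_kl = deg * l_blk[b]
                k_blk[b] += deg
            else:
                d_kl = deg * k_blk[b]
                l_blk[b] += deg
            e_blk[b] += e_new
            assign[i] = b
            recurse(i + 1, max(n_blocks, b + 1), total_e + e_new, total_kl + d_kl)
            assign[i] = -1
            e_blk[b] -= e_new
            if side == 0:
                k_blk[b] -= deg
            else:
                l_blk[b] -= deg

    recurse(0, 0, 0.0, 0.0)
    nodes = list(network.host_nodes) + list(network.asv_nodes)
    return float(best_q), {node: int(b) for node, b in zip(nodes, best_assign)}


def modularity_comparison(
    table: CommunityTable,
    site: str,
    n_hosts: int = 14,
    reps: int = 50,
    restarts: int = 20,
    seed: int = 0,
    min_hosts: int = 2,
) -> pd.DataFrame:
    """Paired real/column-shuffle-null modularity over subsample replicates.

    Each replicate subsamples ``n_hosts`` hosts of ``site``, binarizes,
    builds the network and optimizes Q; the matched null shuffles each
    ASV column of the same replicate before building its network.
    Degenerate replicates (empty networks) are skipped and flagged.
    """
    rows = []
    seeds = np.random.SeedSequence([seed]).spawn(reps)
    for r, ss in enumerate(seeds):
        child = ss.generate_state(3) % (2**31)
        replicate = to_presence_absence(
            subsample_hosts(table, site, n_hosts, int(child[0]))
        )
        null = shuffle_null(replicate, int(child[1]))
        try:
            net_real = build_network(replicate, min_hosts)
            net_null = build_network(null, min_hosts)
        except NetworkError:
            continue
        res_real = optimize_modules(net_real, restarts, int(child[2]))
        res_null = optimize_modules(net_null, restarts, int(child[2]) + 1)
        rows.append(
            (site, r, res_real.Q, res_null.Q, res_real.n_modules, res_null.n_modules)
        )
    return pd.DataFrame(
        rows,
        columns=["site", "replicate", "q_real", "q_null", "modules_real", "modules_null"],
    )
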