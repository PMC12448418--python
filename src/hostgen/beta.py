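"""Community structure: Bray-Curtis distances, PERMANOVA, dispersion.

The PERMANOVA follows the McArdle-Anderson partition of a Gower-centered
inner-product matrix with sequential (type-I-like) sums of squares, so a
model ``site + family + site:family`` is decomposed in that order, the
way vegan's ``adonis2(..., by="terms")`` does.  Significance comes from
permuting hosts jointly across all factors.  The dispersion test is the
``betadisper`` construction: distances to group centroids in principal
coordinate space with negative eigenvalues handled by the real/imaginary
split, followed by a one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from .datamodel import CommunityTable


class BetaError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise BetaError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise BetaError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise BetaError("distance matrix diagonal must be zero")
        if v.min() < 0:
            raise BetaError("distances must be non-negative")
        self.values = v

    def reorder(self, labels: Sequence) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


@dataclass
class PermanovaResult:
    terms: list
    F: dict
    R2: dict
    p: dict
    df: dict
    n_permutations: int


@dataclass
class DispersionResult:
    group_mean_distance: dict
    anova_F: float
    anova_p: float
    distances: pd.Series = field(repr=False, default=None)


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between host communities.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); entries lie in [0, 1].
    All-zero host rows are rejected by name (the distance is undefined).
    """
    counts = table.counts.to_numpy(dtype=float)
    zero = counts.sum(axis=1) == 0
    if zero.any():
        bad = [h for h, z in zip(table.host_ids, zero) if z]
        raise BetaError(f"all-zero host rows: {', '.join(map(str, bad))}")
    d = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(table.host_ids, d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _term_labels(term: str, factors: Mapping[str, np.ndarray]) -> np.ndarray:
    parts = term.split(":")
    for p in parts:
        if p not in factors:
            raise BetaError(f"unknown factor {p!r} in term {term!r}")
    combined = factors[parts[0]].astype(str)
    for p in parts[1:]:
        combined = np.char.add(np.char.add(combined, "\x1f"), factors[p].astype(str))
    return combined


def permanova(
    dist: DistanceMatrix,
    factors: Mapping[str, Sequence],
    terms: Sequence[str] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    permutations: Iterable[np.ndarray] | None = None,
) -> PermanovaResult:
    """Sequential multi-factor PERMANOVA on a distance matrix.

    ``factors`` maps factor names to per-host labels aligned with
    ``dist.labels``; ``terms`` is the ordered model (``"a:b"`` denotes an
    interaction) and defaults to the factors in mapping order.  When
    ``permutations`` is given (an iterable of index arrays), those exact
    permutations are used instead of ``n_permutations`` random ones —
    this supports exhaustive enumeration on small designs.
    """
    n = len(dist.labels)
    factors = {k: np.asarray(v) for k, v in factors.items()}
    for name, v in factors.items():
        if len(v) != n:
            raise BetaError(f"factor {name!r} length != number of hosts")
        counts = pd.Series(v).value_counts()
        if len(counts) < 2:
            raise BetaError(f"factor {name!r} has a single level")
    if terms is None:
        terms = list(factors)
    terms = list(terms)

    g = _gower_center(dist.values)
    ss_total = float(np.trace(g))

    # cumulative hat matrices; sequential SS per term
    x = np.ones((n, 1))
    prev_hat = x @ np.linalg.pinv(x)
    prev_rank = 1
    deltas, dfs = [], []
    for term in terms:
        x = np.hstack([x, _dummy(_term_labels(term, factors))])
        hat = x @ np.linalg.pinv(x)
        rank = int(np.linalg.matrix_rank(x))
        df = rank - prev_rank
        if df < 1:
            raise BetaError(f"term {term!r} adds no degrees of freedom (confounded)")
        deltas.append(hat - prev_hat)
        dfs.append(df)
        prev_hat, prev_rank = hat, rank
    resid = np.eye(n) - prev_hat
    df_res = n - prev_rank
    if df_res < 1:
        raise BetaError("no residual degrees of freedom (model saturated)")

    def term_stats(gm: np.ndarray):
        ss = np.array([float(np.sum(d * gm.T)) for d in deltas])
        ss_res = float(np.sum(resid * gm.T))
        f = (ss / np.asarray(dfs)) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = term_stats(g)

    if permutations is not None:
        perms = [np.asarray(p) for p in permutations]
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        perms = [rng.permutation(n) for _ in range(n_permutations)]
        n_perm = n_permutations
    exceed = np.zeros(len(terms))
    for p in perms:
        gp = g[np.ix_(p, p)]
        _, f_perm = term_stats(gp)
        exceed += f_perm >= f_obs - 1e-12
    if permutations is not None:
        # exhaustive: the observed assignment is assumed to be in the list
        pvals = exceed / n_perm
    else:
        pvals = (1.0 + exceed) / (1.0 + n_perm)

    return PermanovaResult(
        terms=terms,
        F={t: float(f) for t, f in zip(terms, f_obs)},
        R2={t: float(ss / ss_total) for t, ss in zip(terms, ss_obs)},
        p={t: float(pv) for t, pv in zip(terms, pvals)},
        df={t: int(d) for t, d in zip(terms, dfs)},
        n_permutations=n_perm,
    )


def dispersion_test(
    dist: DistanceMatrix, grouping: Sequence, use_medians: bool = False
) -> DispersionResult:
    """Homogeneity of multivariate dispersions (betadisper-style).

    Hosts are embedded by eigendecomposition of the Gower-centered
    matrix; distance to the group centroid combines positive- and
    negative-eigenvalue axes as sqrt(max(d+^2 - d-^2, 0)).  Groups of
    size 1 are excluded with a warning.  ``use_medians`` substitutes the
    coordinate-wise median for the centroid.
    """
    grouping = np.asarray(grouping)
    n = len(dist.labels)
    if len(grouping) != n:
        raise BetaError("grouping length != number of hosts")
    sizes = pd.Series(grouping).value_counts()
    singletons = sizes.index[sizes < 2]
    if len(singletons):
        warnings.warn(
            f"excluding groups of size 1: {list(singletons)}", stacklevel=2
        )
    keep = ~pd.Series(grouping).isin(singletons).to_numpy()
    if keep.sum() == 0 or len(pd.unique(grouping[keep])) < 2:
        raise BetaError("need >= 2 groups with >= 2 hosts each")
    d = dist.values[np.ix_(keep, keep)]
    grouping = grouping[keep]
    labels = [l for l, k in zip(dist.labels, keep) if k]

    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    nonzero = np.abs(eigval) > 1e-10 * max(1.0, np.abs(eigval).max())
    coords = eigvec[:, nonzero] * np.sqrt(np.abs(eigval[nonzero]))
    pos = eigval[nonzero] > 0

    dists = np.empty(len(labels))
    center_fn = np.median if use_medians else np.mean
    for grp in pd.unique(grouping):
        rows = grouping == grp
        center = center_fn(coords[rows], axis=0)
        sq = (coords[rows] - center) ** 2
        d2 = sq[:, pos].sum(axis=1) - sq[:, ~pos].sum(axis=1)
        dists[rows] = np.sqrt(np.clip(d2, 0.0, None))

    groups = [dists[grouping == grp] for grp in pd.unique(grouping)]
    if all(np.allclose(grp, groups[0].mean()) for grp in groups) and len(
        {round(float(g_.mean()), 12) for g_ in groups}
    ) == 1:
        anova_f, anova_p = 0.0, 1.0
    else:
        anova_f, anova_p = f_oneway(*groups)
    return DispersionResult(
        group_mean_distance={
            str(grp): float(dists[grouping == grp].mean())
            for grp in pd.unique(grouping)
        },
        anova_F=float(anova_f),
        anova_p=float(anova_p),
        distances=pd.Series(dists, index=labels),
    )
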