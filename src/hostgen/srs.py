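"""Scaling with ranked subsampling (SRS) depth normalization.

SRS equalizes library depth across samples while preserving the rank
structure of each sample's counts far better than random rarefaction.
Each sample's counts are scaled by ``c_min / total``; integer parts are
kept, and the remaining ``c_min - sum(floors)`` single units are handed
out in descending order of fractional part.  Exact fractional-part ties
are broken uniformly at random (seeded), the only source of randomness.

Within a sample, a feature with a larger input count never receives a
smaller output than a feature with a smaller input count, except among
tied fractional parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CommunityTable


class DepthError(ValueError):
    """Raised when depths cannot support the requested c_min."""


@dataclass
class SRSParams:
    c_min: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_min < 1:
            raise ValueError("c_min must be >= 1")


def srs_normalize_sample(counts, params: SRSParams) -> np.ndarray:
    """Normalize one sample's count vector to sum exactly to ``c_min``."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < params.c_min:
        raise DepthError(f"sample depth {total} below c_min {params.c_min}")
    scaled = counts * (params.c_min / total)
    floors = np.floor(scaled).astype(np.int64)
    remainder = params.c_min - int(floors.sum())
    if remainder > 0:
        frac = scaled - floors
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
        # random permutation first, then stable sort by descending fractional
        # part: ties end up in uniformly random relative order.
        perm = rng.permutation(len(counts))
        order = perm[np.argsort(-frac[perm], kind="stable")]
        floors[order[:remainder]] += 1
    return floors


def srs_normalize_table(
    table: CommunityTable, params: SRSParams
) -> tuple[CommunityTable, list]:
    """Normalize every host row to ``c_min``; shallow hosts are excluded.

    Returns the normalized table and the list of excluded host ids
    (depth < c_min).  Raises if every host is excluded.  Each host's tie
    RNG is seeded from the global seed plus the host's row position, so
    results do not depend on processing order.
    """
    depths = table.depths
    excluded = [h for h, d in depths.items() if d < params.c_min]
    kept = [h for h in table.host_ids if h not in set(excluded)]
    if not kept:
        raise DepthError("all hosts fall below c_min")
    rows = {}
    for pos, host in enumerate(table.host_ids):
        if host not in set(excluded):
            host_seed = int(
                np.random.SeedSequence([params.seed, pos]).generate_state(1)[0]
                % (2**31)
            )
            rows[host] = srs_normalize_sample(
                table.counts.loc[host].to_numpy(),
                SRSParams(c_min=params.c_min, seed=host_seed),
            )
    normalized = pd.DataFrame.from_dict(
        rows, orient="index", columns=table.counts.columns
    ).loc[kept]
    return CommunityTable(normalized, table.metadata), excluded
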