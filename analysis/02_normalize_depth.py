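#!/usr/bin/env python
"""Filter small host families and SRS-normalize sequencing depth.

Hosts from families with fewer than eight samples are removed, then
every remaining host is scaled-with-ranked-subsampling normalized to
the minimum retained depth.  Writes the normalized count table and the
exclusion list under results/normalized/.
"""

from pathlib import Path

import pandas as pd

from hostgen.datamodel import filter_host_families
from hostgen.io import read_community_table, write_community_table
from hostgen.srs import SRSParams, srs_normalize_table

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    table = read_community_table(ROOT / "data/counts.tsv", ROOT / "data/metadata.tsv")
    filtered = filter_host_families(table, min_samples=8)
    dropped = table.n_hosts - filtered.n_hosts
    c_min = int(filtered.depths.min())
    normalized, excluded = srs_normalize_table(filtered, SRSParams(c_min=c_min, seed=SEED))

    out = ROOT / "normalized"
    out.mkdir(parents=True, exist_ok=True)
    write_community_table(normalized, out / "counts.tsv", out / "metadata.tsv")
    pd.Series(excluded, name="host_id").to_csv(out / "excluded_hosts.tsv", sep="\t", index=False)

    print(f"family filter removed {dropped} hosts from small families")
    print(f"SRS target depth c_min = {c_min}; {len(excluded)} hosts below target excluded")
    print(f"{normalized.n_hosts} hosts normalized; every row now sums to {c_min}")
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
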