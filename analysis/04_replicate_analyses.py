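#!/usr/bin/env python
"""Per-site subsample replicates: richness, prevalence, SES-PD, pair tests.

For every site, repeatedly subsamples 14 hosts and records (per
replicate) richness and prevalence metrics for all ASVs and per focal
phylum, per-ASV host-specialization (SES-PD), exact pairwise
co-occurrence against the column-shuffle and prevalence-matched nulls,
and the Proteobacteria pair-excess statistic.  Also builds the per-ASV
cross-site summary (mean prevalence proportion vs mean SES).  Writes
results/replicates/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hostgen.datamodel import AnalysisConfig, phylum_members, to_presence_absence
from hostgen.io import read_community_table, read_taxonomy, read_tree
from hostgen.pipeline import DEFAULT_SYNONYMS, run_site_replicates

ROOT = Path(__file__).resolve().parent.parent / "results"
CONFIG = AnalysisConfig(n_replicates=25, n_null_pd=499, rng_seed=42)


def main() -> None:
    table = read_community_table(
        ROOT / "normalized/counts.tsv", ROOT / "normalized/metadata.tsv"
    )
    taxonomy = read_taxonomy(ROOT / "data/taxonomy.tsv")
    host_tree = read_tree(ROOT / "data/host_tree.nwk")
    bact_tree = read_tree(ROOT / "data/bacterial_tree.nwk")
    presence = to_presence_absence(table)
    phylum_sets = {
        ph: phylum_members(taxonomy, ph, DEFAULT_SYNONYMS)
        for ph in CONFIG.focal_phyla
    }

    sites = sorted(presence.site.unique())
    metrics, pairs, excess = [], [], []
    accum = {}
    for site in sites:
        res = run_site_replicates(
            presence, site, CONFIG, host_tree, phylum_sets, bact_tree, CONFIG.rng_seed
        )
        metrics.append(res["metrics"])
        pairs.append(res["pairs"])
        excess.append(res["excess"])
        accum[site] = res
        print(f"{site}: {CONFIG.n_replicates} replicates, "
              f"mean positive pairs {res['pairs'].n_positive.mean():.1f} "
              f"(null {res['pairs'].n_positive_null.mean():.1f})")

    out = ROOT / "replicates"
    out.mkdir(parents=True, exist_ok=True)
    pd.concat(metrics).to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6g")
    pd.concat(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False, float_format="%.6g")
    pd.concat(excess).to_csv(out / "phylum_excess.tsv", sep="\t", index=False, float_format="%.6g")

    rows = []
    for i, asv in enumerate(presence.asv_ids):
        prev = {s: accum[s]["prev_sum"][i] / accum[s]["occ_count"][i]
                for s in sites if accum[s]["occ_count"][i] > 0}
        zs = {s: accum[s]["z_sum"][i] / accum[s]["z_count"][i]
              for s in sites if accum[s]["z_count"][i] > 0}
        if not prev:
            continue
        rows.append(dict(
            asv_id=asv,
            phylum=taxonomy.phylum_of(asv),
            n_sites=len(prev),
            mean_prevalence_proportion=np.mean(list(prev.values())) / CONFIG.subsample_hosts,
            mean_ses=np.mean(list(zs.values())) if zs else np.nan,
        ))
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "asv_summary.tsv", sep="\t", index=False, float_format="%.6g")

    by_phylum = summary.groupby("phylum")[["mean_prevalence_proportion", "mean_ses"]].mean()
    print("\nper-phylum means across occupied sites:")
    print(by_phylum.round(3).to_string())
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
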