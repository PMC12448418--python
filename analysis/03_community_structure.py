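#!/usr/bin/env python
"""Test community structure: PERMANOVA and dispersion homogeneity.

Bray-Curtis distances between host communities are partitioned by
sampling site, host family, and their interaction (sequential sums of
squares), for all ASVs and for each focal phylum; betadisper-style
dispersion tests check the homogeneity assumption.  Writes
results/beta/permanova.tsv and dispersion.tsv.
"""

import warnings
from pathlib import Path

import pandas as pd

from hostgen.beta import bray_curtis, dispersion_test, permanova
from hostgen.datamodel import CommunityTable, phylum_members
from hostgen.io import read_community_table, read_taxonomy
from hostgen.pipeline import DEFAULT_SYNONYMS

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42
TERMS = ["site", "host_family", "site:host_family"]


def main() -> None:
    table = read_community_table(
        ROOT / "normalized/counts.tsv", ROOT / "normalized/metadata.tsv"
    )
    taxonomy = read_taxonomy(ROOT / "data/taxonomy.tsv")
    subsets = {"all": None}
    for ph in ("Proteobacteria", "Firmicutes"):
        subsets[ph] = phylum_members(taxonomy, ph, DEFAULT_SYNONYMS)

    perm_rows, disp_rows = [], []
    for name, subset in subsets.items():
        sub = table
        if subset is not None:
            counts = table.counts[[a for a in table.asv_ids if a in subset]]
            keep = counts.sum(axis=1) > 0
            sub = CommunityTable(counts.loc[keep], table.metadata)
        dist = bray_curtis(sub)
        factors = {
            "site": sub.site.to_numpy(),
            "host_family": sub.host_family.to_numpy(),
        }
        res = permanova(dist, factors, TERMS, n_permutations=999, seed=SEED)
        for term in res.terms:
            perm_rows.append(
                dict(subset=name, term=term, df=res.df[term], F=res.F[term],
                     R2=res.R2[term], p=res.p[term])
            )
        for grouping in ("site", "host_family"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = dispersion_test(dist, factors[grouping])
            disp_rows.append(dict(subset=name, grouping=grouping, F=d.anova_F, p=d.anova_p))

    out = ROOT / "beta"
    out.mkdir(parents=True, exist_ok=True)
    perm = pd.DataFrame(perm_rows)
    disp = pd.DataFrame(disp_rows)
    perm.to_csv(out / "permanova.tsv", sep="\t", index=False, float_format="%.6g")
    disp.to_csv(out / "dispersion.tsv", sep="\t", index=False, float_format="%.6g")

    print("PERMANOVA (sequential SS, 999 permutations):")
    print(perm.to_string(index=False))
    sig = perm[perm.p < 0.05]
    print(f"\n{len(sig)} of {len(perm)} terms significant at 0.05; "
          "dispersion homogeneity:")
    print(disp.to_string(index=False))
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
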