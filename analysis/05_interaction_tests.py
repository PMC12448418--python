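#!/usr/bin/env python
"""Inferential layer over the replicate tables: t-tests, ANOVA, Tukey.

Reads results/replicates/ and asks the study's questions: do real
subsamples hold more positively co-occurring pairs than their shuffle
nulls?  Are members of positive pairs high- or low-prevalence?  Do the
shared hosts of a pair cluster phylogenetically relative to the nulls?
Is the within-Proteobacteria share of positive pairs above the squared-
proportion expectation?  How do richness/prevalence/SES metrics differ
across sites (ANOVA + Tukey) and between the focal phyla?
Writes results/interactions/.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from hostgen.compare_stats import anova_tukey, bonferroni, t_test

ROOT = Path(__file__).resolve().parent.parent / "results"
ALPHA_CORRECTED = 1.31e-4  # Bonferroni-corrected threshold used throughout


def tidy_t(comparison, site, x, y, alternative):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = t_test(x, y, alternative)
    return dict(comparison=comparison, site=site, statistic=res.statistic,
                p=res.p, alternative=alternative)


def main() -> None:
    pairs = pd.read_csv(ROOT / "replicates/pairs.tsv", sep="\t")
    metrics = pd.read_csv(ROOT / "replicates/metrics.tsv", sep="\t")
    excess = pd.read_csv(ROOT / "replicates/phylum_excess.tsv", sep="\t")

    rows = []
    for site, g in pairs.groupby("site"):
        rows.append(tidy_t("positive_pairs_real_vs_null", site,
                           g.n_positive, g.n_positive_null, "greater"))
        rows.append(tidy_t("negative_pairs_real_vs_null", site,
                           g.n_negative, g.n_negative_null, "two-sided"))
        rows.append(tidy_t("positive_pair_prevalence_real_vs_null", site,
                           g.prev_positive, g.prev_positive_null, "two-sided"))
        rows.append(tidy_t("shared_host_ses_real_vs_null", site,
                           g.shared_ses, g.shared_ses_null, "two-sided"))
        rows.append(tidy_t("shared_host_ses_real_vs_matched", site,
                           g.shared_ses, g.shared_ses_matched, "two-sided"))
    for site, g in excess.groupby("site"):
        rows.append(tidy_t("proteobacteria_pair_excess", site,
                           g.observed, g.expected, "greater"))
    # phylum contrasts within sites
    for site, g in metrics.groupby("site"):
        proteo = g[g.subset == "Proteobacteria"]
        firmi = g[g.subset == "Firmicutes"]
        rows.append(tidy_t("max_prevalence_proteo_gt_firmicutes", site,
                           proteo.max_prevalence, firmi.max_prevalence, "greater"))
        rows.append(tidy_t("median_ses_firmicutes_lt_proteo", site,
                           firmi.median_ses, proteo.median_ses, "less"))
    ttests = pd.DataFrame([r for r in rows if r])

    anova_rows, tukey_rows = [], []
    all_m = metrics[metrics.subset == "all"]
    targets = [(c, all_m, c) for c in
               ("median_within_host_richness", "site_richness",
                "prop_low_prevalence", "max_prevalence", "median_ses")]
    targets += [("n_positive_pairs", pairs, "n_positive"),
                ("n_negative_pairs", pairs, "n_negative")]
    for label, frame, col in targets:
        vals = frame[col].to_numpy(float)
        ok = np.isfinite(vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = anova_tukey(vals[ok], frame["site"].to_numpy()[ok])
        anova_rows.append(dict(metric=label, F=res.statistic, p=res.p))
        for (a, b), padj in res.tukey_p.items():
            tukey_rows.append(dict(metric=label, group_a=a, group_b=b, p_adj=padj))

    out = ROOT / "interactions"
    out.mkdir(parents=True, exist_ok=True)
    ttests.to_csv(out / "t_tests.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(anova_rows).to_csv(out / "anova.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(tukey_rows).to_csv(out / "tukey.tsv", sep="\t", index=False, float_format="%.6g")

    pos = ttests[ttests.comparison == "positive_pairs_real_vs_null"]
    n_sig = (pos.p < ALPHA_CORRECTED).sum()
    print(f"positive pairs exceed the shuffle null in {n_sig}/{len(pos)} sites "
          f"at the corrected alpha {ALPHA_CORRECTED:g}")
    exc = ttests[ttests.comparison == "proteobacteria_pair_excess"]
    print(f"Proteobacteria-Proteobacteria pair excess significant in "
          f"{(exc.p < ALPHA_CORRECTED).sum()}/{len(exc)} sites")
    print(pd.DataFrame(anova_rows).to_string(index=False))
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
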