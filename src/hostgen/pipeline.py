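"""End-to-end analysis: normalize, subsample, specialize, co-occur, modularize.

``run_full`` wires the stages together on validated inputs:

1. host-family filter (families with fewer than ``min_family_samples``
   hosts removed) and SRS normalization to a common depth ``c_min``;
2. community structure: Bray-Curtis + PERMANOVA (site, host family,
   interaction) and the dispersion homogeneity test, for all ASVs and
   per focal phylum;
3. per site, ``n_replicates`` random 14-host subsamples: richness and
   prevalence metrics, per-ASV SES-PD, exact pairwise co-occurrence with
   a matched column-shuffle null and a prevalence-matched null, shared
   host SES-PD and patristic summaries for positive pairs, and the
   within-phylum pair-excess statistic;
4. per site, paired real/null bipartite modularity over
   ``n_replicates_modularity`` subsamples;
5. replicate-level t-tests / ANOVA / Tukey comparison tables.

Every stochastic stage draws its seed from the single root seed through
``numpy.random.SeedSequence``, so two runs with the same root seed are
byte-identical.  All stage outputs are written as TSV next to a JSON
manifest; nothing is held only in memory.
"""

from __future__ import annotations

import hashlib
import zlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare_stats
from .beta import BetaError, bray_curtis, dispersion_test, permanova
from .cooccurrence import (
    CooccurrenceError,
    classify_all_pairs,
    pair_test,
    phylum_pair_excess,
    prevalence_matched_pair,
    shuffle_null,
)
from .datamodel import (
    AnalysisConfig,
    CommunityTable,
    Taxonomy,
    filter_host_families,
    phylum_members,
    to_presence_absence,
)
from .modularity import modularity_comparison
from .specialization import SESCalculator, subsample_hosts, replicate_metrics
from .srs import SRSParams, srs_normalize_table
from .trees import PhyloTree

DEFAULT_SYNONYMS = {
    "Clostridia": "Firmicutes",
    "Bacilli": "Firmicutes",
    "Bacillota": "Firmicutes",
    "Pseudomonadota": "Proteobacteria",
}


@dataclass
class RunManifest:
    config: dict
    root_seed: int
    c_min: int
    excluded_hosts: list
    sites: list
    skipped_sites: list
    outputs: list
    warnings: list
    input_digests: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")


def _code(label: str) -> int:
    """Stable small integer for a label (process-independent)."""
    return zlib.crc32(str(label).encode()) % (2**20)


def _seed(root: int, *parts: int) -> int:
    return int(
        np.random.SeedSequence([root, *parts]).generate_state(1)[0] % (2**31)
    )


def _species_sets(replicate: CommunityTable, tree: PhyloTree) -> np.ndarray:
    """Boolean (n_asvs x n_tips) matrix of occupied host species per ASV."""
    tip_index = {t: i for i, t in enumerate(tree.tips)}
    mat = replicate.counts.to_numpy() > 0
    s = np.zeros((replicate.n_hosts, tree.n_tips), dtype=bool)
    for h, sp in enumerate(replicate.host_species):
        s[h, tip_index[sp]] = True
    return (s.T @ mat).T > 0


def _pair_member_prevalence(pairs: pd.DataFrame, cls: str) -> float:
    sub = pairs[pairs["classification"] == cls]
    if len(sub) == 0:
        return float("nan")
    return float(pd.concat([sub["prev_a"], sub["prev_b"]]).mean())


def _shared_sets(pairs: pd.DataFrame, replicate: CommunityTable, tree: PhyloTree):
    """Occupied-species sets of the hosts shared by each listed pair."""
    tip_index = {t: i for i, t in enumerate(tree.tips)}
    mat = replicate.counts.to_numpy() > 0
    col = {a: i for i, a in enumerate(replicate.asv_ids)}
    species = [tip_index[sp] for sp in replicate.host_species]
    sets = np.zeros((len(pairs), tree.n_tips), dtype=bool)
    for r, (a, b) in enumerate(zip(pairs["asv_a"], pairs["asv_b"])):
        both = mat[:, col[a]] & mat[:, col[b]]
        for h in np.flatnonzero(both):
            sets[r, species[h]] = True
    return sets


def run_site_replicates(
    presence: CommunityTable,
    site: str,
    config: AnalysisConfig,
    host_tree: PhyloTree,
    phylum_sets: dict,
    bacterial_tree: PhyloTree | None,
    root_seed: int,
) -> dict:
    """Subsample-replicate metrics, pair tests and nulls for one site.

    Returns a dict of DataFrames: ``metrics`` (one row per replicate and
    ASV subset), ``pairs`` (per-replicate pair counts for real, shuffle
    null and prevalence-matched comparisons), ``excess`` (within-phylum
    pair excess), plus per-ASV prevalence/SES accumulators and pooled
    positive-pair patristic distances.
    """
    asv_index = {a: i for i, a in enumerate(presence.asv_ids)}
    prev_sum = np.zeros(presence.n_asvs)
    occ_count = np.zeros(presence.n_asvs)
    z_sum = np.zeros(presence.n_asvs)
    z_count = np.zeros(presence.n_asvs)
    metrics_rows, pair_rows, excess_rows = [], [], []
    pooled_pair_dist = []
    focal = config.focal_phyla[0] if config.focal_phyla else None
    for rep in range(config.n_replicates):
        site_code = _code(site)
        replicate = subsample_hosts(
            presence, site, config.subsample_hosts, _seed(root_seed, 1, site_code, rep)
        )
        # the null pool is the replicate's own host-species set (the
        # equivalent of pruning the host tree to the community at hand)
        calc = SESCalculator(
            host_tree,
            n_null=config.n_null_pd,
            seed=_seed(root_seed, 5, site_code, rep),
            pool=set(replicate.host_species),
        )
        sets = _species_sets(replicate, host_tree)
        z = calc.z_for_sets(sets)
        prevalence = replicate.prevalence().to_numpy()

        idx = np.array([asv_index[a] for a in replicate.asv_ids])
        occurring = prevalence > 0
        prev_sum[idx[occurring]] += prevalence[occurring]
        occ_count[idx[occurring]] += 1
        finite = np.isfinite(z)
        z_sum[idx[finite]] += z[finite]
        z_count[idx[finite]] += 1

        subsets = {"all": None, **phylum_sets}
        for name, subset in subsets.items():
            m = replicate_metrics(
                replicate, subset, config.prevalence_threshold, site, rep
            )
            if subset is None:
                z_subset = z[occurring & finite]
            else:
                in_subset = np.array([a in subset for a in replicate.asv_ids])
                z_subset = z[occurring & finite & in_subset]
            metrics_rows.append(
                {
                    "site": site,
                    "replicate": rep,
                    "subset": name,
                    "median_within_host_richness": m.median_within_host_richness,
                    "site_richness": m.site_richness,
                    "prop_low_prevalence": m.prop_low_prevalence,
                    "max_prevalence": m.max_prevalence,
                    "median_ses": float(np.median(z_subset)) if len(z_subset) else float("nan"),
                }
            )

        pairs = classify_all_pairs(replicate, config.pair_alpha)
        null_rep = shuffle_null(replicate, _seed(root_seed, 2, site_code, rep))
        null_pairs = classify_all_pairs(null_rep, config.pair_alpha)

        pos = pairs[pairs["classification"] == "positive"]
        null_pos = null_pairs[null_pairs["classification"] == "positive"]
        mean_shared_z = float("nan")
        if len(pos):
            zp = calc.z_for_sets(_shared_sets(pos, replicate, host_tree))
            mean_shared_z = float(np.nanmean(zp)) if np.isfinite(zp).any() else float("nan")
        mean_shared_z_null = float("nan")
        if len(null_pos):
            zn = calc.z_for_sets(_shared_sets(null_pos, null_rep, host_tree))
            mean_shared_z_null = (
                float(np.nanmean(zn)) if np.isfinite(zn).any() else float("nan")
            )
        # prevalence-matched surrogate pairs for each real positive pair
        mean_shared_z_matched = float("nan")
        if len(pos):
            matched_rows = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for q, row in enumerate(pos.itertuples()):
                    t = pair_test(
                        row.n_hosts, row.prev_a, row.prev_b, row.shared_obs,
                        config.pair_alpha, row.asv_a, row.asv_b,
                    )
                    ma, mb, _, _ = prevalence_matched_pair(
                        t, replicate, _seed(root_seed, 3, site_code, rep, q)
                    )
                    matched_rows.append({"asv_a": ma, "asv_b": mb})
            zm = calc.z_for_sets(
                _shared_sets(pd.DataFrame(matched_rows), replicate, host_tree)
            )
            mean_shared_z_matched = (
                float(np.nanmean(zm)) if np.isfinite(zm).any() else float("nan")
            )
        if bacterial_tree is not None and len(pos):
            dm = bacterial_tree.patristic_matrix()
            pooled_pair_dist.extend(
                float(dm.loc[a, b]) for a, b in zip(pos["asv_a"], pos["asv_b"])
            )

        pair_rows.append(
            {
                "site": site,
                "replicate": rep,
                "n_positive": int(len(pos)),
                "n_negative": int((pairs["classification"] == "negative").sum()),
                "n_positive_null": int(len(null_pos)),
                "n_negative_null": int(
                    (null_pairs["classification"] == "negative").sum()
                ),
                "prev_positive": _pair_member_prevalence(pairs, "positive"),
                "prev_positive_null": _pair_member_prevalence(null_pairs, "positive"),
                "prev_negative": _pair_member_prevalence(pairs, "negative"),
                "prev_negative_null": _pair_member_prevalence(null_pairs, "negative"),
                "shared_ses": mean_shared_z,
                "shared_ses_null": mean_shared_z_null,
                "shared_ses_matched": mean_shared_z_matched,
            }
        )

        if focal is not None and focal in phylum_sets:
            try:
                obs, exp = phylum_pair_excess(
                    pairs,
                    phylum_sets[focal],
                    [a for a, p in zip(replicate.asv_ids, prevalence) if p > 0],
                )
            except CooccurrenceError:
                obs, exp = float("nan"), float("nan")
            excess_rows.append(
                {"site": site, "replicate": rep, "observed": obs, "expected": exp}
            )

    return {
        "metrics": pd.DataFrame(metrics_rows),
        "pairs": pd.DataFrame(pair_rows),
        "excess": pd.DataFrame(excess_rows),
        "prev_sum": prev_sum,
        "occ_count": occ_count,
        "z_sum": z_sum,
        "z_count": z_count,
        "pair_distances": np.asarray(pooled_pair_dist, dtype=float),
    }


def run_null_comparison(
    presence: CommunityTable,
    site: str,
    config: AnalysisConfig,
    root_seed: int,
) -> pd.DataFrame:
    """Paired real/column-shuffle pair counts per subsample replicate.

    A lightweight view of stage 3 for calibration work: one shuffle null
    per replicate, aligned by replicate index.
    """
    rows = []
    site_code = _code(site)
    for rep in range(config.n_replicates):
        replicate = subsample_hosts(
            presence, site, config.subsample_hosts, _seed(root_seed, 1, site_code, rep)
        )
        pairs = classify_all_pairs(replicate, config.pair_alpha)
        null_rep = shuffle_null(replicate, _seed(root_seed, 2, site_code, rep))
        null_pairs = classify_all_pairs(null_rep, config.pair_alpha)
        rows.append(
            {
                "site": site,
                "replicate": rep,
                "n_positive": int((pairs["classification"] == "positive").sum()),
                "n_negative": int((pairs["classification"] == "negative").sum()),
                "n_positive_null": int(
                    (null_pairs["classification"] == "positive").sum()
                ),
                "n_negative_null": int(
                    (null_pairs["classification"] == "negative").sum()
                ),
            }
        )
    return pd.DataFrame(rows)


def _beta_stage(
    table: CommunityTable, phylum_sets: dict, config: AnalysisConfig, root_seed: int
):
    perm_rows, disp_rows, notes = [], [], []
    subsets = {"all": None, **phylum_sets}
    for name, subset in subsets.items():
        sub = table
        if subset is not None:
            cols = [a for a in table.asv_ids if a in subset]
            counts = table.counts[cols]
            nonzero = counts.sum(axis=1) > 0
            if (~nonzero).any():
                notes.append(
                    f"beta[{name}]: dropped {(~nonzero).sum()} hosts with no {name} reads"
                )
            sub = CommunityTable(counts.loc[nonzero], table.metadata)
        try:
            dist = bray_curtis(sub)
            factors = {
                "site": sub.site.to_numpy(),
                "host_family": sub.host_family.to_numpy(),
            }
            res = permanova(
                dist,
                factors,
                terms=["site", "host_family", "site:host_family"],
                n_permutations=config.n_permutations,
                seed=_seed(root_seed, 4, _code(name)),
            )
            for term in res.terms:
                perm_rows.append(
                    {
                        "subset": name,
                        "term": term,
                        "df": res.df[term],
                        "F": res.F[term],
                        "R2": res.R2[term],
                        "p": res.p[term],
                    }
                )
            for grouping in ("site", "host_family"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d = dispersion_test(dist, factors[grouping])
                disp_rows.append(
                    {
                        "subset": name,
                        "grouping": grouping,
                        "F": d.anova_F,
                        "p": d.anova_p,
                    }
                )
        except BetaError as exc:
            notes.append(f"beta[{name}] skipped: {exc}")
    return pd.DataFrame(perm_rows), pd.DataFrame(disp_rows), notes


def _comparison_stage(
    pair_df: pd.DataFrame,
    metrics_df: pd.DataFrame,
    modularity_df: pd.DataFrame,
    excess_df: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []

    def add(comparison, site, x, y, alternative):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if len(x) < 2 or len(y) < 2:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = compare_stats.t_test(x, y, alternative)
        rows.append(
            {
                "comparison": comparison,
                "site": site,
                "statistic": res.statistic,
                "p": res.p,
                "alternative": alternative,
                "n_x": len(x),
                "n_y": len(y),
            }
        )

    for site, g in pair_df.groupby("site", sort=True):
        add("positive_pairs_real_vs_null", site, g["n_positive"], g["n_positive_null"], "greater")
        add("negative_pairs_real_vs_null", site, g["n_negative"], g["n_negative_null"], "two-sided")
        add("positive_vs_negative_pairs", site, g["n_positive"], g["n_negative"], "greater")
        add("positive_pair_prevalence_real_vs_null", site, g["prev_positive"], g["prev_positive_null"], "two-sided")
        add("shared_host_ses_real_vs_null", site, g["shared_ses"], g["shared_ses_null"], "two-sided")
        add("shared_host_ses_real_vs_matched", site, g["shared_ses"], g["shared_ses_matched"], "two-sided")
    if len(modularity_df):
        for site, g in modularity_df.groupby("site", sort=True):
            add("modularity_real_vs_null", site, g["q_real"], g["q_null"], "greater")
            add("modules_real_vs_null", site, g["modules_real"], g["modules_null"], "greater")
    if len(excess_df):
        for site, g in excess_df.groupby("site", sort=True):
            add("phylum_pair_excess_obs_vs_expected", site, g["observed"], g["expected"], "greater")

    anova_rows = []
    metric_cols = [
        "median_within_host_richness",
        "site_richness",
        "prop_low_prevalence",
        "max_prevalence",
        "median_ses",
    ]
    all_metrics = metrics_df[metrics_df["subset"] == "all"]
    sources = [(c, all_metrics, c) for c in metric_cols]
    sources += [
        ("n_positive_pairs", pair_df, "n_positive"),
        ("n_negative_pairs", pair_df, "n_negative"),
    ]
    for label, frame, col in sources:
        vals = frame[col].to_numpy(dtype=float)
        grp = frame["site"].to_numpy()
        ok = np.isfinite(vals)
        if ok.sum() < 4 or len(set(grp[ok])) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = compare_stats.anova_tukey(vals[ok], grp[ok])
        rows.append(
            {
                "comparison": f"anova_{label}",
                "site": "all",
                "statistic": res.statistic,
                "p": res.p,
                "alternative": "two-sided",
                "n_x": int(ok.sum()),
                "n_y": len(res.groups),
            }
        )
        for (a, b), padj in res.tukey_p.items():
            anova_rows.append(
                {"metric": label, "group_a": a, "group_b": b, "p_adj": padj}
            )

    # focal phylum contrasts within sites (directional, as in the study)
    phyla = [s for s in metrics_df["subset"].unique() if s != "all"]
    if len(phyla) >= 2:
        p0, p1 = phyla[0], phyla[1]
        for site in sorted(metrics_df["site"].unique()):
            g = metrics_df[metrics_df["site"] == site]
            a = g[g["subset"] == p0]
            b = g[g["subset"] == p1]
            add(f"max_prevalence_{p0}_gt_{p1}", site, a["max_prevalence"], b["max_prevalence"], "greater")
            add(f"median_ses_{p1}_lt_{p0}", site, b["median_ses"], a["median_ses"], "less")
    return pd.DataFrame(rows), pd.DataFrame(anova_rows)


def run_full(
    config: AnalysisConfig,
    table: CommunityTable,
    taxonomy: Taxonomy,
    host_tree: PhyloTree,
    bacterial_tree: PhyloTree | None,
    out_dir,
    synonyms: dict | None = None,
    input_paths: dict | None = None,
) -> RunManifest:
    """Run the complete analysis and write all stage outputs under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = config.rng_seed
    notes: list = []

    work = table
    if config.filter_before_normalize:
        work = filter_host_families(work, config.min_family_samples)
    c_min = config.c_min or int(work.depths.min())
    work, excluded = srs_normalize_table(work, SRSParams(c_min=c_min, seed=_seed(root, 0)))
    if excluded:
        notes.append(f"srs: excluded {len(excluded)} hosts below c_min={c_min}")
    if not config.filter_before_normalize:
        work = filter_host_families(work, config.min_family_samples)
    presence = to_presence_absence(work)

    synonyms = {**DEFAULT_SYNONYMS, **(synonyms or {})}
    phylum_sets = {
        ph: phylum_members(taxonomy, ph, synonyms) for ph in config.focal_phyla
    }

    perm_df, disp_df, beta_notes = _beta_stage(work, phylum_sets, config, root)
    notes.extend(beta_notes)

    site_counts = presence.site.value_counts()
    sites = sorted(site_counts.index[site_counts >= config.subsample_hosts])
    skipped = sorted(site_counts.index[site_counts < config.subsample_hosts])
    if skipped:
        notes.append(f"sites below {config.subsample_hosts} hosts skipped: {skipped}")

    metrics_parts, pair_parts, excess_parts, mod_parts = [], [], [], []
    summary_accum = {}
    pair_distances = []
    for site in sites:
        res = run_site_replicates(
            presence, site, config, host_tree, phylum_sets, bacterial_tree, root
        )
        metrics_parts.append(res["metrics"])
        pair_parts.append(res["pairs"])
        excess_parts.append(res["excess"])
        summary_accum[site] = res
        pair_distances.append(res["pair_distances"])
        mod_parts.append(
            modularity_comparison(
                presence,
                site,
                n_hosts=config.subsample_hosts,
                reps=config.n_replicates_modularity,
                restarts=config.modularity_restarts,
                seed=_seed(root, 6, _code(site)),
            )
        )
    metrics_df = pd.concat(metrics_parts, ignore_index=True)
    pair_df = pd.concat(pair_parts, ignore_index=True)
    excess_df = pd.concat(excess_parts, ignore_index=True)
    modularity_df = pd.concat(mod_parts, ignore_index=True)

    # per-ASV cross-site summary (mean prevalence proportion + mean SES
    # over sites where the ASV occurred)
    asv_rows = []
    for i, asv in enumerate(presence.asv_ids):
        site_prev, site_z = {}, {}
        for site in sites:
            r = summary_accum[site]
            if r["occ_count"][i] > 0:
                site_prev[site] = r["prev_sum"][i] / r["occ_count"][i]
            if r["z_count"][i] > 0:
                site_z[site] = r["z_sum"][i] / r["z_count"][i]
        if not site_prev:
            continue
        mean_prev = float(np.mean(list(site_prev.values()))) / config.subsample_hosts
        mean_ses = float(np.mean(list(site_z.values()))) if site_z else float("nan")
        asv_rows.append(
            {
                "asv_id": asv,
                "phylum": taxonomy.phylum_of(asv) if asv in taxonomy.table.index else "unassigned",
                "n_sites": len(site_prev),
                "mean_prevalence_proportion": mean_prev,
                "mean_ses": mean_ses,
            }
        )
    asv_df = pd.DataFrame(asv_rows)

    comparisons_df, tukey_df = _comparison_stage(
        pair_df, metrics_df, modularity_df, excess_df
    )
    if bacterial_tree is not None:
        pooled = np.concatenate(pair_distances) if pair_distances else np.array([])
        nn = bacterial_tree.nearest_neighbor_distances().to_numpy()
        dmat = bacterial_tree.patristic_matrix().to_numpy()
        allp = dmat[np.triu_indices_from(dmat, k=1)]
        for other_name, other in (("nearest_neighbor", nn), ("all_pairs", allp)):
            if len(pooled) >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = compare_stats.t_test(pooled, other, "two-sided")
                comparisons_df = pd.concat(
                    [
                        comparisons_df,
                        pd.DataFrame(
                            [
                                {
                                    "comparison": f"pair_patristic_vs_{other_name}",
                                    "site": "all",
                                    "statistic": res.statistic,
                                    "p": res.p,
                                    "alternative": "two-sided",
                                    "n_x": len(pooled),
                                    "n_y": len(other),
                                }
                            ]
                        ),
                    ],
                    ignore_index=True,
                )

    outputs = {}
    for name, frame in [
        ("replicate_metrics.tsv", metrics_df),
        ("pair_counts.tsv", pair_df),
        ("phylum_excess.tsv", excess_df),
        ("modularity.tsv", modularity_df),
        ("asv_summary.tsv", asv_df),
        ("permanova.tsv", perm_df),
        ("dispersion.tsv", disp_df),
        ("comparisons.tsv", comparisons_df),
        ("tukey.tsv", tukey_df),
    ]:
        path = out / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs[name] = str(path)

    digests = {}
    for key, p in (input_paths or {}).items():
        digests[key] = hashlib.sha256(Path(p).read_bytes()).hexdigest()

    manifest = RunManifest(
        config={k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        root_seed=root,
        c_min=c_min,
        excluded_hosts=list(map(str, excluded)),
        sites=list(sites),
        skipped_sites=list(skipped),
        outputs=sorted(outputs),
        warnings=notes,
        input_digests=digests,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
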