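"""SES-PD host specialization, subsampling, and prevalence metrics."""

import numpy as np
import pandas as pd
import pytest

from hostgen.datamodel import to_presence_absence
from hostgen.specialization import (
    SESCalculator,
    mean_asv_summary,
    replicate_metrics,
    ses_pd,
    subsample_hosts,
)
from hostgen.synthetic import simulate_host_tree
from hostgen.trees import PhyloTree, TreeError


class TestSesPd:
    def test_all_tips_occupied_is_degenerate(self, host_tree16):
        res = ses_pd(list(host_tree16.tips), host_tree16, n_null=99, seed=0)
        assert res.pd_obs == pytest.approx(host_tree16.total_length)
        assert res.degenerate

    def test_star_tree_is_degenerate_for_any_subset(self):
        star = PhyloTree.from_newick(
            "(" + ",".join(f"t{i}:1" for i in range(10)) + "):0;"
        )
        res = ses_pd(["t0", "t3", "t7"], star, n_null=99, seed=1)
        assert res.degenerate
        assert np.isnan(res.z)

    def test_clade_restricted_set_is_negative_across_seeds(self, host_tree16):
        """Tips confined to one small clade have minimal PD, so z < 0 in
        nearly every null realization."""
        clade = min(host_tree16.clades(min_size=2, max_frac=0.3), key=len)
        tips = sorted(clade)[:2]
        neg = sum(
            ses_pd(tips, host_tree16, n_null=199, seed=s).z < 0 for s in range(20)
        )
        assert neg >= 19

    def test_unknown_host_raises(self, host_tree16):
        with pytest.raises(TreeError):
            ses_pd(["nonexistent"], host_tree16, n_null=9, seed=0)

    def test_species_mapping_collapses_individuals(self, host_tree16):
        species = {"i1": host_tree16.tips[0], "i2": host_tree16.tips[0]}
        res = ses_pd(["i1", "i2"], host_tree16, species_of_host=species,
                     n_null=99, seed=0)
        assert res.pd_obs == pytest.approx(
            host_tree16.faith_pd({host_tree16.tips[0]})
        )

    def test_rank_p_in_valid_range(self, host_tree16):
        res = ses_pd(list(host_tree16.tips)[:4], host_tree16, n_null=99, seed=2)
        assert 1 / 100 <= res.rank_p <= 1

    def test_pool_restricts_null_to_community(self, host_tree16):
        pool = list(host_tree16.tips)[:6]
        calc = SESCalculator(host_tree16, n_null=199, seed=0, pool=pool)
        # occupying the whole pool is degenerate under the pooled null
        res = calc.ses(pool)
        assert res.degenerate


class TestSubsampleHosts:
    def test_site_of_exactly_n_is_identity_up_to_order(self, make_table):
        t = make_table(np.ones((3, 2), dtype=int), sites=["s1"] * 3)
        out = subsample_hosts(t, "s1", 3, seed=0)
        assert sorted(out.host_ids) == sorted(t.host_ids)

    def test_determinism_and_column_retention(self, make_table):
        t = make_table(np.eye(6, 4, dtype=int), sites=["s1"] * 6)
        a = subsample_hosts(t, "s1", 3, seed=5)
        b = subsample_hosts(t, "s1", 3, seed=5)
        assert a.host_ids == b.host_ids
        assert a.n_asvs == 4  # zero columns kept

    def test_too_small_site_errors(self, make_table):
        t = make_table(np.ones((2, 2), dtype=int), sites=["s1", "s1"])
        with pytest.raises(ValueError, match="s1"):
            subsample_hosts(t, "s1", 3, seed=0)

    def test_sampling_is_uniform_over_hosts(self, make_table):
        t = make_table(np.ones((10, 2), dtype=int), sites=["s1"] * 10)
        counts = {h: 0 for h in t.host_ids}
        n_draws = 400
        for s in range(n_draws):
            for h in subsample_hosts(t, "s1", 4, seed=s).host_ids:
                counts[h] += 1
        expected = n_draws * 4 / 10
        sd = np.sqrt(n_draws * 0.4 * 0.6)
        for h, c in counts.items():
            assert abs(c - expected) < 5 * sd


class TestReplicateMetrics:
    def test_ubiquitous_asv_max_prevalence(self, make_table):
        t = to_presence_absence(make_table(np.ones((14, 3), dtype=int)))
        m = replicate_metrics(t)
        assert m.max_prevalence == 14

    def test_all_singletons(self, make_table):
        t = make_table(np.eye(5, dtype=int))
        m = replicate_metrics(t, threshold=5)
        assert m.prop_low_prevalence == 1.0
        assert m.median_within_host_richness == 1.0

    def test_prevalence_threshold_is_strictly_below(self, make_table):
        # one ASV at prevalence 4 (below 5), one at exactly 5
        counts = np.zeros((6, 2), dtype=int)
        counts[:4, 0] = 1
        counts[:5, 1] = 1
        m = replicate_metrics(make_table(counts), threshold=5)
        assert m.prop_low_prevalence == pytest.approx(0.5)

    def test_matches_brute_force_recount(self, make_table):
        rng = np.random.default_rng(4)
        counts = (rng.random((14, 30)) < 0.3).astype(int)
        t = make_table(counts)
        m = replicate_metrics(t, threshold=5)
        prev = counts.sum(axis=0)
        occ = prev[prev > 0]
        assert m.site_richness == len(occ)
        assert m.max_prevalence == occ.max()
        assert m.prop_low_prevalence == pytest.approx((occ < 5).mean())
        assert m.median_within_host_richness == pytest.approx(
            float(np.median(counts.sum(axis=1)))
        )

    def test_disjoint_subset_reports_nan_not_zero(self, make_table):
        t = make_table([[1, 0], [1, 0]])
        m = replicate_metrics(t, asv_subset={"a2"})
        assert np.isnan(m.median_within_host_richness)
        assert np.isnan(m.prop_low_prevalence)


class TestMeanAsvSummary:
    def test_single_site_proportion(self):
        prev, ses = mean_asv_summary({"s1": 7}, {"s1": -1.2}, hosts_sampled=14)
        assert prev == pytest.approx(0.5)
        assert ses == pytest.approx(-1.2)

    def test_ses_averages_over_sites(self):
        _, ses = mean_asv_summary({"s1": 3, "s2": 5}, {"s1": -1, "s2": 1}, 14)
        assert ses == pytest.approx(0.0)

    def test_matches_recount_over_simulated_sites(self):
        rng = np.random.default_rng(0)
        prevs = {f"s{i}": int(rng.integers(1, 15)) for i in range(6)}
        zs = {f"s{i}": float(rng.normal()) for i in range(6)}
        mp, mz = mean_asv_summary(prevs, zs, 14)
        assert mp == pytest.approx(np.mean(list(prevs.values())) / 14)
        assert mz == pytest.approx(np.mean(list(zs.values())))

    def test_absent_everywhere_errors(self):
        with pytest.raises(ValueError):
            mean_asv_summary({}, {}, 14)
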