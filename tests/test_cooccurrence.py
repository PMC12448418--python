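"""Exact co-occurrence tests, null constructions, and pair summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from hostgen.cooccurrence import (
    CooccurrenceError,
    classify_all_pairs,
    pair_test,
    phylum_pair_excess,
    prevalence_matched_pair,
    shared_host_pmf,
    shared_host_specialization,
    shuffle_null,
    pair_distance_summary,
)
from hostgen.datamodel import to_presence_absence
from hostgen.specialization import ses_pd
from hostgen.synthetic import simulate_host_tree


def enumerate_overlap_pmf(N, N1, N2, j):
    """Oracle: enumerate all C(N, N2) placements of the second ASV against
    a fixed placement of the first and count overlaps of exactly j."""
    first = set(range(N1))
    hits = total = 0
    for placement in itertools.combinations(range(N), N2):
        total += 1
        hits += len(first & set(placement)) == j
    return hits / total


class TestPmf:
    def test_hand_case_one_sixth(self):
        assert shared_host_pmf(4, 2, 2, 2) == pytest.approx(1 / 6, abs=1e-12)

    def test_enumeration_oracle_small_n(self):
        for N in (4, 5, 6, 7):
            for N1 in range(N + 1):
                for N2 in range(N + 1):
                    for j in range(max(0, N1 + N2 - N), min(N1, N2) + 1):
                        assert shared_host_pmf(N, N1, N2, j) == pytest.approx(
                            enumerate_overlap_pmf(N, N1, N2, j), abs=1e-12
                        )

    def test_matches_scipy_hypergeom(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(2, 40))
            N1 = int(rng.integers(0, N + 1))
            N2 = int(rng.integers(0, N + 1))
            j = int(rng.integers(max(0, N1 + N2 - N), min(N1, N2) + 1))
            assert shared_host_pmf(N, N1, N2, j) == pytest.approx(
                hypergeom.pmf(j, N, N1, N2), abs=1e-12
            )

    def test_ubiquitous_asv_forces_overlap(self):
        assert shared_host_pmf(8, 8, 3, 3) == pytest.approx(1.0)

    def test_infeasible_j_is_zero_and_invalid_prevalence_raises(self):
        assert shared_host_pmf(5, 3, 3, 0) == 0.0
        with pytest.raises(CooccurrenceError):
            shared_host_pmf(5, 6, 2, 1)

    def test_pmf_sums_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            N = int(rng.integers(2, 30))
            N1, N2 = int(rng.integers(0, N + 1)), int(rng.integers(0, N + 1))
            total = sum(
                shared_host_pmf(N, N1, N2, j)
                for j in range(max(0, N1 + N2 - N), min(N1, N2) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestPairTest:
    def test_perfect_overlap_positive(self):
        t = pair_test(14, 7, 7, 7)
        assert t.p_gt == pytest.approx(1 / 3432, abs=1e-12)
        assert t.classification == "positive"

    def test_complete_avoidance_negative(self):
        t = pair_test(10, 5, 5, 0)
        assert t.p_lt == pytest.approx(1 / 252, abs=1e-12)
        assert t.classification == "negative"

    def test_two_singletons_never_significant(self):
        for j in (0, 1):
            t = pair_test(14, 1, 1, j)
            assert t.classification == "random"
            assert t.p_gt in (pytest.approx(1 / 14), pytest.approx(1.0))

    def test_tails_both_contain_observed(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            N = int(rng.integers(3, 20))
            N1, N2 = int(rng.integers(1, N + 1)), int(rng.integers(1, N + 1))
            j = int(rng.integers(max(0, N1 + N2 - N), min(N1, N2) + 1))
            t = pair_test(N, N1, N2, j)
            assert t.p_lt + t.p_gt >= 1 - 1e-9

    def test_tails_match_enumeration(self):
        N, N1, N2 = 8, 4, 5
        for j in range(max(0, N1 + N2 - N), min(N1, N2) + 1):
            t = pair_test(N, N1, N2, j)
            lt = sum(enumerate_overlap_pmf(N, N1, N2, i) for i in range(0, j + 1))
            gt = sum(
                enumerate_overlap_pmf(N, N1, N2, i) for i in range(j, min(N1, N2) + 1)
            )
            assert t.p_lt == pytest.approx(lt, abs=1e-12)
            assert t.p_gt == pytest.approx(gt, abs=1e-12)

    def test_infeasible_observation_raises(self):
        with pytest.raises(CooccurrenceError):
            pair_test(10, 5, 5, 6)


class TestClassifyAllPairs:
    def test_identical_columns_positive(self, make_table):
        counts = np.zeros((14, 3), dtype=int)
        counts[:7, 0] = 1
        counts[:7, 1] = 1
        counts[0, 2] = 1
        pairs = classify_all_pairs(make_table(counts), alpha=0.01)
        row = pairs[(pairs.asv_a == "a1") & (pairs.asv_b == "a2")].iloc[0]
        assert row.classification == "positive"

    def test_zero_prevalence_excluded(self, make_table):
        counts = np.zeros((6, 3), dtype=int)
        counts[:3, 0] = 1
        counts[3:, 1] = 1
        pairs = classify_all_pairs(make_table(counts))
        assert set(pairs.asv_a) | set(pairs.asv_b) == {"a1", "a2"}

    def test_requires_binary(self, make_table):
        with pytest.raises(CooccurrenceError):
            classify_all_pairs(make_table([[2, 1], [1, 1]]))

    def test_expected_overlap_filter(self, make_table):
        counts = np.zeros((14, 3), dtype=int)
        counts[0, 0] = 1  # prevalence 1: expected overlap with anything < 1
        counts[:7, 1] = 1
        counts[:7, 2] = 1
        full = classify_all_pairs(make_table(counts))
        filtered = classify_all_pairs(make_table(counts), min_expected=1.0)
        assert len(full) == 3
        assert len(filtered) == 1

    def test_vectorized_results_match_scalar_pair_test(self, make_table):
        rng = np.random.default_rng(3)
        counts = (rng.random((14, 12)) < 0.4).astype(int)
        pairs = classify_all_pairs(make_table(counts), alpha=0.05)
        for row in pairs.sample(20, random_state=0).itertuples():
            t = pair_test(14, row.prev_a, row.prev_b, row.shared_obs, alpha=0.05)
            assert row.p_lt == pytest.approx(t.p_lt, abs=1e-12)
            assert row.p_gt == pytest.approx(t.p_gt, abs=1e-12)
            assert row.classification == t.classification

    def test_quick_calibration_near_alpha(self, make_table):
        """Independent columns: flagged fraction stays at or below twice
        the nominal 0.01 level (the discrete test is conservative)."""
        rng = np.random.default_rng(9)
        fracs = []
        for _ in range(60):
            counts = (rng.random((14, 50)) < 0.5).astype(int)
            pairs = classify_all_pairs(make_table(counts), alpha=0.01)
            fracs.append((pairs.classification != "random").mean())
        assert 0 <= np.mean(fracs) <= 0.02


class TestShuffleNull:
    def test_constant_column_unchanged(self, make_table):
        t = make_table(np.ones((5, 2), dtype=int))
        assert shuffle_null(t, seed=4).equals(t)

    def test_column_multisets_preserved(self, make_table):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(0, 5, (10, 8)))
        null = shuffle_null(t, seed=1)
        for c in t.counts.columns:
            assert sorted(null.counts[c]) == sorted(t.counts[c])

    def test_positions_uniform_over_seeds(self, make_table):
        t = make_table(np.array([[1], [0], [0], [0]]))
        hits = np.zeros(4)
        n = 400
        for s in range(n):
            hits += shuffle_null(t, seed=s).counts.to_numpy()[:, 0]
        expected = n / 4
        sd = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(hits - expected) < 5 * sd)


class TestPrevalenceMatched:
    def _table(self, make_table):
        counts = np.zeros((10, 6), dtype=int)
        prevs = [3, 3, 3, 5, 5, 7]
        for j, p in enumerate(prevs):
            counts[:p, j] = 1
        return make_table(counts)

    def test_exact_match_when_available(self, make_table):
        t = self._table(make_table)
        pair = pair_test(10, 3, 5, 2, asv_a="a1", asv_b="a4")
        ma, mb, ea, eb = prevalence_matched_pair(pair, t, seed=0)
        assert ea and eb
        assert t.prevalence()[ma] == 3 and ma not in ("a1", "a4")
        assert t.prevalence()[mb] == 5

    def test_fallback_to_nearest_prevalence_warns(self, make_table):
        t = self._table(make_table)
        pair = pair_test(10, 7, 3, 3, asv_a="a6", asv_b="a1")
        with pytest.warns(UserWarning, match="nearest"):
            ma, _, exact_a, _ = prevalence_matched_pair(pair, t, seed=1)
        assert not exact_a
        assert t.prevalence()[ma] == 5  # closest available to 7

    def test_draws_uniform_over_eligible(self, make_table):
        t = self._table(make_table)
        pair = pair_test(10, 5, 7, 4, asv_a="a4", asv_b="a6")
        picks = {"a1": 0, "a2": 0, "a3": 0}
        n = 300
        # member b (prevalence 7) falls back; member a has exact match a5
        for s in range(n):
            ma, _, _, _ = prevalence_matched_pair(
                pair_test(10, 3, 5, 2, asv_a="a1", asv_b="a4"), t, seed=s
            )
            if ma in picks:
                picks[ma] += 1
        # eligible exact matches for prevalence 3 are a2, a3
        assert picks["a1"] == 0
        for k in ("a2", "a3"):
            assert abs(picks[k] - n / 2) < 5 * np.sqrt(n * 0.25)

    def test_too_few_asvs_raises(self, make_table):
        t = make_table(np.ones((4, 3), dtype=int))
        with pytest.raises(CooccurrenceError):
            prevalence_matched_pair(pair_test(4, 4, 4, 4, asv_a="a1", asv_b="a2"), t, 0)


class TestSharedHostSpecialization:
    def test_composition_identity_with_ses_pd(self, make_table, host_tree16):
        tips = list(host_tree16.tips)
        counts = np.zeros((8, 2), dtype=int)
        counts[:5, 0] = 1
        counts[2:8, 1] = 1
        t = make_table(counts, species=tips[:8])
        pair = pair_test(8, 5, 6, 3, asv_a="a1", asv_b="a2")
        res = shared_host_specialization(
            pair, t, host_tree16,
            species_of_host=dict(zip(t.host_ids, t.host_species)),
            n_null=99, seed=3,
        )
        direct = ses_pd(tips[2:5], host_tree16, n_null=99, seed=3)
        assert res.pd_obs == pytest.approx(direct.pd_obs)
        assert res.z == pytest.approx(direct.z)

    def test_empty_intersection_raises(self, make_table, host_tree16):
        counts = np.zeros((4, 2), dtype=int)
        counts[:2, 0] = 1
        counts[2:, 1] = 1
        t = make_table(counts, species=list(host_tree16.tips)[:4])
        pair = pair_test(4, 2, 2, 0, asv_a="a1", asv_b="a2")
        with pytest.raises(CooccurrenceError):
            shared_host_specialization(pair, t, host_tree16, n_null=9, seed=0)


class TestPhylumPairExcess:
    def _pairs(self, rows):
        return pd.DataFrame(
            rows, columns=["asv_a", "asv_b", "classification"]
        )

    def test_squared_proportion_expectation(self):
        pairs = self._pairs([("p1", "p2", "positive"), ("p1", "f1", "positive")])
        obs, exp = phylum_pair_excess(pairs, {"p1", "p2"}, ["p1", "p2", "f1", "f2"])
        assert exp == pytest.approx(0.25)
        assert obs == pytest.approx(0.5)

    def test_all_in_phylum_gives_one(self):
        pairs = self._pairs([("p1", "p2", "positive")])
        obs, exp = phylum_pair_excess(pairs, {"p1", "p2"}, ["p1", "p2"])
        assert obs == 1.0 and exp == 1.0

    def test_no_positive_pairs_raises(self):
        pairs = self._pairs([("p1", "p2", "random")])
        with pytest.raises(CooccurrenceError):
            phylum_pair_excess(pairs, {"p1"}, ["p1", "p2"])


class TestPairDistances:
    def test_mutual_nearest_neighbors_match(self):
        tree = simulate_host_tree(12, seed=1)
        nn = tree.nearest_neighbor_distances()
        d = tree.patristic_matrix()
        # find a mutual nearest-neighbor pair
        for a in tree.tips:
            b = d.loc[a].drop(a).idxmin()
            if d.loc[b].drop(b).idxmin() == a:
                break
        pairs = pd.DataFrame({"asv_a": [a], "asv_b": [b]})
        out = pair_distance_summary(pairs, tree)
        assert out["pair"][0] == pytest.approx(nn[a])
        assert out["pair"][0] == pytest.approx(nn[b])

    def test_distances_match_patristic_and_missing_tip_skipped(self):
        tree = simulate_host_tree(10, seed=2)
        a, b = tree.tips[0], tree.tips[3]
        pairs = pd.DataFrame(
            {"asv_a": [a, "ghost"], "asv_b": [b, tree.tips[1]]}
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = pair_distance_summary(pairs, tree)
        assert len(out["pair"]) == 1
        assert out["pair"][0] == pytest.approx(tree.patristic_distance(a, b))
        assert len(out["all_pairs"]) == 45
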