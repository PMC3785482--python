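import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regks import enrichment as en
from regks.containers import GeneSet, GeneSetCollection


def brute_force_deviation(member_ranks, n, prefer_sign=1):
    """Independent oracle: scan every grid point r in 0..n.

    F_sample(r) - r/n with F_sample the fraction of members at rank <= r.
    Exact integer arithmetic (dev scaled by k*n); max |dev|, ties broken
    toward the group's coherent sign, then the smallest r.
    """
    members = set(member_ranks)
    k = len(members)
    best_key, best = None, None
    for r in range(0, n + 1):
        count = sum(1 for m in members if m <= r)
        dev_scaled = count * n - r * k
        sgn = (dev_scaled > 0) - (dev_scaled < 0)
        key = (abs(dev_scaled), prefer_sign * sgn, -r)
        if best_key is None or key > best_key:
            best_key, best = key, (dev_scaled / (k * n), r)
    return best


def make_ranked(n):
    return en.RankedProfile(
        pd.Series(np.arange(1, n + 1), index=[f"g{i}" for i in range(1, n + 1)])
    )


class TestRankTransform:
    def test_basic_descending_ranks(self):
        profile = pd.Series({"a": 5.0, "b": 3.0, "c": 9.0})
        ranked = en.rank_transform(profile)
        assert ranked.ranks.to_dict() == {"a": 2, "b": 3, "c": 1}

    def test_ties_resolved_deterministically(self):
        profile = pd.Series({"z": 1.0, "a": 1.0, "m": 2.0})
        r1 = en.rank_transform(profile)
        r2 = en.rank_transform(profile.sample(frac=1.0, random_state=0))
        assert r1.ranks.sort_index().equals(r2.ranks.sort_index())
        assert r1.ranks["a"] < r1.ranks["z"]  # tie broken by symbol

    def test_missing_values_rejected_with_names(self):
        profile = pd.Series({"a": 1.0, "bad": np.nan})
        with pytest.raises(ValueError, match="bad"):
            en.rank_transform(profile)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_ranks_always_a_permutation(self, values):
        profile = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
        ranked = en.rank_transform(profile)
        assert sorted(ranked.ranks) == list(range(1, len(values) + 1))


class TestSignedDeviations:
    def test_top_ranked_up_pair(self, ranked10):
        dev = en.signed_deviations(ranked10, ["g1", "g2"], [])
        assert dev.d_u == pytest.approx(0.8)
        assert dev.x_u == pytest.approx(0.2)
        assert dev.d_d == 0.0 and dev.x_d is None

    def test_bottom_ranked_down_pair_mirrors(self, ranked10):
        dev = en.signed_deviations(ranked10, [], ["g9", "g10"])
        assert dev.d_d == pytest.approx(-0.8)
        assert dev.x_d == pytest.approx(0.8)

    def test_saturated_group_has_vanishing_deviation(self):
        n = 50
        ranked = make_ranked(n)
        dev = en.signed_deviations(ranked, list(ranked.ranks.index), [])
        assert abs(dev.d_u) <= 1.0 / n + 1e-12

    def test_empty_both_groups_rejected(self, ranked10):
        with pytest.raises(ValueError, match="empty"):
            en.signed_deviations(ranked10, [], [])

    def test_overlapping_groups_rejected(self, ranked10):
        with pytest.raises(ValueError, match="disjoint"):
            en.signed_deviations(ranked10, ["g1"], ["g1"])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            k = int(rng.integers(1, n + 1))
            ranks = 1 + rng.choice(n, size=k, replace=False)
            ranked = make_ranked(n)
            members = [f"g{r}" for r in ranks]
            dev = en.signed_deviations(ranked, members, [])
            d_oracle, r_oracle = brute_force_deviation(ranks, n)
            assert dev.d_u == pytest.approx(d_oracle, abs=1e-12)
            assert dev.x_u == pytest.approx(r_oracle / n, abs=1e-12)


class TestCombinedStatistic:
    def test_no_down_regulatees_reduces_to_d_u(self):
        assert en.combined_statistic(0.6, 5, 0.0, 0) == 0.6

    def test_no_up_regulatees_reduces_to_minus_d_d(self):
        assert en.combined_statistic(0.0, 0, -0.7, 3) == pytest.approx(0.7)

    def test_coherent_case(self):
        assert en.combined_statistic(0.8, 2, -0.8, 2) == pytest.approx(0.8)

    def test_membership_weighting(self):
        # 3 up at d=0.9 against 1 noisy down at d=+0.3: down cannot overwhelm
        assert en.combined_statistic(0.9, 3, 0.3, 1) == pytest.approx(0.6)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            en.combined_statistic(0.0, 0, 0.0, 0)

    def test_continuity_removing_last_down_regulatee(self):
        """d_UpDown -> d_u continuously as the down group shrinks away."""
        n = 40
        ranked = make_ranked(n)
        up = [f"g{r}" for r in (1, 3, 5, 7)]
        dev_up_only = en.signed_deviations(ranked, up, [])
        d_limit = en.combined_statistic(dev_up_only.d_u, len(up), 0.0, 0)
        dev_with_down = en.signed_deviations(ranked, up, ["g20"])
        d_near = en.combined_statistic(dev_with_down.d_u, len(up), dev_with_down.d_d, 1)
        # a single mid-ranked down gene perturbs the statistic by at most 1/(k+1)
        assert abs(d_near - d_limit) <= 1.0 / (len(up) + 1) + 0.3

    def test_mirror_symmetry_of_profile_negation(self):
        """Negating the profile and swapping groups preserves d_UpDown."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            values = rng.normal(size=n)
            genes = [f"g{i}" for i in range(n)]
            profile = pd.Series(values, index=genes)
            k_u, k_d = int(rng.integers(1, 3)), int(rng.integers(1, 3))
            members = rng.choice(genes, size=k_u + k_d, replace=False)
            up, down = list(members[:k_u]), list(members[k_u:])
            r_fwd = en.rank_transform(profile)
            dev = en.signed_deviations(r_fwd, up, down)
            d_fwd = en.combined_statistic(dev.d_u, k_u, dev.d_d, k_d)
            r_rev = en.rank_transform(-profile)
            dev_rev = en.signed_deviations(r_rev, down, up)
            d_rev = en.combined_statistic(dev_rev.d_u, k_d, dev_rev.d_d, k_u)
            assert d_rev == pytest.approx(d_fwd, abs=1e-12)

    @given(st.data())
    @settings(deadline=None, max_examples=80)
    def test_statistic_always_bounded(self, data):
        n = data.draw(st.integers(2, 20))
        k = data.draw(st.integers(1, n))
        k_u = data.draw(st.integers(0, k))
        ranks = data.draw(
            st.permutations(range(1, n + 1)).map(lambda p: p[:k])
        )
        ranked = make_ranked(n)
        up = [f"g{r}" for r in ranks[:k_u]]
        down = [f"g{r}" for r in ranks[k_u:]]
        if not up and not down:
            return
        dev = en.signed_deviations(ranked, up, down)
        d = en.combined_statistic(dev.d_u, len(up), dev.d_d, len(down))
        assert -1.0 <= d <= 1.0
        assert abs(dev.d_u) <= 1.0 and abs(dev.d_d) <= 1.0


class TestPermutationPvalue:
    def test_exhaustive_enumeration_single_gene_universe_four(self):
        n, n_perm = 4, 40_000
        ranked = make_ranked(n)
        # exact null: the single up gene lands on each rank with probability 1/4
        null_exact = []
        for r in range(1, 5):
            dev = en.signed_deviations(ranked, [f"g{r}"], [])
            null_exact.append(en.combined_statistic(dev.d_u, 1, dev.d_d, 0))
        for r in range(1, 5):
            gs = GeneSet(f"s{r}", "t", (f"g{r}",))
            p_mc = en.permutation_pvalue(ranked, gs, n_perm=n_perm, seed=3)
            dev = en.signed_deviations(ranked, [f"g{r}"], [])
            obs = en.combined_statistic(dev.d_u, 1, dev.d_d, 0)
            p_exact = np.mean([d >= obs - 1e-12 for d in null_exact])
            se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
            assert abs(p_mc - p_exact) <= 3 * se + 1e-9

    def test_below_median_statistic_has_large_p(self):
        n = 30
        ranked = make_ranked(n)
        # up-regulatees at the very bottom: strongly anti-enriched
        gs = GeneSet("anti", "t", tuple(f"g{r}" for r in range(n - 3, n + 1)))
        p = en.permutation_pvalue(ranked, gs, n_perm=4000, seed=1)
        assert p > 0.5

    def test_oversized_set_rejected(self, ranked10):
        gs = GeneSet("big", "t", tuple(f"x{i}" for i in range(20)))
        with pytest.raises(ValueError):
            en.null_statistics(10, 15, 0, 10, np.random.default_rng(0))

    def test_null_p_values_uniform(self):
        """Type-I calibration: random sets on a random profile reject at ~alpha."""
        rng = np.random.default_rng(23)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        ranked = en.rank_transform(pd.Series(rng.normal(size=n), index=genes))
        null = en.null_statistics(n, 3, 2, 20_000, np.random.default_rng(5))
        rejections = 0
        trials = 400
        for _ in range(trials):
            members = rng.choice(genes, 5, replace=False)
            gs = GeneSet("s", "t", tuple(members[:3]), tuple(members[3:]))
            p = en.permutation_pvalue(ranked, gs, n_perm=20_000, null=null)
            rejections += p <= 0.05
        rate = rejections / trials
        assert abs(rate - 0.05) < 0.03


class TestEnrichmentScores:
    def test_no_down_group_neutral_c_right(self, ranked10):
        c_left, c_right = en.enrichment_scores(ranked10, ["g1", "g2"], [])
        assert c_right == 1.0
        assert c_left == pytest.approx(1.0 / 0.2)  # F=1 at x*=0.2

    def test_top_five_of_hundred(self):
        ranked = make_ranked(100)
        c_left, _ = en.enrichment_scores(ranked, [f"g{i}" for i in range(1, 6)], [])
        assert c_left == pytest.approx(20.0)

    def test_uniformly_scattered_regulatees_score_near_one(self):
        rng = np.random.default_rng(3)
        n = 400
        ranked = make_ranked(n)
        scores = []
        for _ in range(200):
            members = [f"g{r}" for r in 1 + rng.choice(n, 10, replace=False)]
            c_left, _ = en.enrichment_scores(ranked, members, [])
            scores.append(c_left)
        assert 0.8 < np.mean(scores) < 1.3


class TestLeadingEdge:
    def test_step_enumeration_example(self, ranked10):
        edge_up, _ = en.leading_edge(ranked10, ["g1", "g2", "g8"], [])
        assert set(edge_up) == {"g1", "g2"}

    def test_all_top_ranked_group_is_whole_edge(self, ranked10):
        up = ["g1", "g2", "g3"]
        edge_up, _ = en.leading_edge(ranked10, up, [])
        assert set(edge_up) == set(up)

    def test_down_edge_collects_bottom_members(self, ranked10):
        _, edge_down = en.leading_edge(ranked10, [], ["g9", "g10"])
        assert set(edge_down) == {"g9", "g10"}

    def test_edge_subset_of_regulatees_random(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            ranked = make_ranked(n)
            k = int(rng.integers(1, min(6, n)))
            members = [f"g{r}" for r in 1 + rng.choice(n, k, replace=False)]
            split = int(rng.integers(0, k + 1))
            up, down = members[:split], members[split:]
            edge_up, edge_down = en.leading_edge(ranked, up, down)
            assert set(edge_up) <= set(up) and set(edge_down) <= set(down)

    def test_edges_match_brute_force_argmax(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            n = int(rng.integers(3, 13))
            k = int(rng.integers(1, n + 1))
            ranks = 1 + rng.choice(n, size=k, replace=False)
            ranked = make_ranked(n)
            members = [f"g{r}" for r in ranks]
            edge_up, _ = en.leading_edge(ranked, members, [])
            _, r_star = brute_force_deviation(ranks, n)
            expected = {f"g{r}" for r in ranks if r <= r_star}
            assert set(edge_up) == expected


class TestScreenCollection:
    def test_planted_sets_recovered(self, strong_study):
        from regks import preprocess, diffexpr

        normed, _ = preprocess.normalize_to_common_percentile(strong_study.matrix)
        table = diffexpr.ratio_profile(
            normed.intensity,
            strong_study.design,
            "noHS",
            "HS",
            "hippocampus",
            probe_map=strong_study.probe_map,
            times=[12],
        )
        profile = table.set_index("gene")["log2_ratio"]
        results = en.screen_collection(
            profile, strong_study.collection, n_perm=4000, seed=2
        )
        truth = strong_study.set_truth
        enriched = set(truth.loc[truth.enriched, "name"])
        selected = {r.name for r in results if r.selected}
        assert len(selected & enriched) >= 18
        false = len(selected - enriched)
        assert false <= 0.25 * max(len(selected), 1)

    def test_all_null_collection_selects_nothing(self):
        rng = np.random.default_rng(31)
        n = 500
        genes = [f"g{i}" for i in range(n)]
        profile = pd.Series(rng.normal(size=n), index=genes)
        sets = []
        for i in range(60):
            members = rng.choice(genes, 12, replace=False)
            sets.append(GeneSet(f"s{i}", "null_coll", tuple(members[:8]), tuple(members[8:])))
        results = en.screen_collection(
            profile, GeneSetCollection(sets), n_perm=2000, seed=4
        )
        assert sum(r.selected for r in results) <= 2

    def test_out_of_universe_set_skipped_with_warning(self, ranked10):
        coll = GeneSetCollection(
            [
                GeneSet("in", "c", ("g1", "g2")),
                GeneSet("out", "c", ("zz1", "zz2")),
            ]
        )
        with pytest.warns(UserWarning, match="skipped"):
            results = en.screen_collection(ranked10, coll, n_perm=200, seed=0)
        assert [r.name for r in results] == ["in"]


class TestKsPlotData:
    def test_step_coordinates_monotone(self, ranked10):
        table = en.ks_plot_data(ranked10, ["g2", "g5"], ["g8"])
        for curve in ("up", "down"):
            sub = table[table.curve == curve]
            assert (np.diff(sub.x) >= -1e-12).all()
            assert (np.diff(sub.y) >= -1e-12).all()
            assert sub.y.iloc[0] == 0.0 and sub.y.iloc[-1] == 1.0

    def test_band_coverage_near_nominal(self):
        rng = np.random.default_rng(8)
        n, k = 500, 12
        ranked = make_ranked(n)
        d_crit = float(__import__("scipy.stats", fromlist=["kstwo"]).kstwo.ppf(0.95, k))
        inside = 0
        trials = 600
        for _ in range(trials):
            ranks = np.sort(1 + rng.choice(n, k, replace=False))
            i = np.arange(1, k + 1)
            sup = max(np.max(i / k - ranks / n), np.max(ranks / n - (i - 1) / k))
            inside += sup <= d_crit
        coverage = inside / trials
        assert 0.92 <= coverage <= 0.995

    def test_enriched_set_exits_band_upward(self):
        ranked = make_ranked(100)
        top10 = [f"g{i}" for i in range(1, 11)]
        table = en.ks_plot_data(ranked, top10, [])
        up = table[table.curve == "up"]
        d_crit = table.loc[table.curve == "band_upper", "y"].iloc[0]
        assert ((up.y - up.x) > d_crit).any()

    def test_bad_confidence_rejected(self, ranked10):
        with pytest.raises(ValueError, match="confidence"):
            en.ks_plot_data(ranked10, ["g1"], [], confidence=1.5)
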