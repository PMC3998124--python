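import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_ols
from metaregulon import (
    ClassifierConfig,
    SiteHit,
    category_distribution,
    classify_prototypical,
    cumulative_counts,
    fit_cumulative,
    make_profile,
    normalized_cog_counts,
    profile_cogs,
)
from metaregulon.genes import SiteGeneLink

CFG = ClassifierConfig()

ONE_PER_BIN = [12.5, 13.5, 14.5, 15.5, 16.5, 17.5, 18.5, 19.5]


def _link(cog, score, category="L"):
    hit = SiteHit("c1", 0, 16, "+", score, "A" * 16)
    return SiteGeneLink(hit, f"gene_{cog}_{score}", -50.0, True,
                        cog_id=cog, cog_category=category)


class TestCumulativeCounts:
    def test_one_score_per_bin(self):
        assert cumulative_counts(ONE_PER_BIN, CFG).tolist() == [
            8, 7, 6, 5, 4, 3, 2, 1, 0
        ]

    def test_empty_scores_give_zeros(self):
        assert cumulative_counts([], CFG).tolist() == [0] * 9

    def test_counts_are_strictly_above_threshold(self):
        # a score exactly at a bin boundary is not counted at that bin
        assert cumulative_counts([16.0], CFG).tolist() == [
            1, 1, 1, 1, 0, 0, 0, 0, 0
        ]

    def test_normal_sample_matches_recount_oracle(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(16, 3, size=200).tolist()
        counts = cumulative_counts(scores, CFG)
        for t, c in zip(range(12, 21), counts):
            assert c == sum(1 for s in scores if s > t)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 30), max_size=60))
    def test_monotone_non_increasing(self, scores):
        counts = cumulative_counts(scores, CFG)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFitCumulative:
    def test_exactly_linear_counts(self):
        slope, intercept, r2 = fit_cumulative([8, 7, 6, 5, 4, 3, 2, 1, 0], CFG)
        assert slope == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_counts_get_zero_r2(self):
        slope, intercept, r2 = fit_cumulative([5] * 9, CFG)
        assert (slope, intercept, r2) == (0.0, 5.0, 0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(37)
        counts = cumulative_counts(rng.normal(16, 3, size=150), CFG)
        slope, intercept, r2 = fit_cumulative(counts, CFG)
        o_slope, o_intercept, o_r2 = oracle_ols(
            list(range(12, 21)), counts.tolist()
        )
        assert slope == pytest.approx(o_slope, abs=1e-9)
        assert intercept == pytest.approx(o_intercept, abs=1e-9)
        assert r2 == pytest.approx(o_r2, abs=1e-9)


class TestClassifyPrototypical:
    def test_linear_but_too_few_sites(self):
        # perfectly linear cumulative counts, but only 8 sites in range
        profile = make_profile("COGx", ONE_PER_BIN, CFG)
        assert profile.r2 == pytest.approx(1.0)
        assert profile.n_in_range == 8
        assert profile.prototypical is False

    def test_all_scores_above_range(self):
        profile = make_profile("COGx", [21.0] * 20, CFG)
        assert profile.n_in_range == 0
        assert profile.prototypical is False

    def test_clause_conjunction_evaluated_independently(self):
        scores = np.linspace(12.4, 18.9, 12).tolist()
        profile = make_profile("COGx", scores, CFG)
        # recompute the three clauses by hand
        in_range = sum(1 for s in scores if 12 <= s <= 20)
        counts = [sum(1 for s in scores if s > t) for t in range(12, 21)]
        _, _, r2 = oracle_ols(list(range(12, 21)), counts)
        expected = r2 > 0.85 and max(scores) > 16 and in_range >= 10
        assert profile.prototypical is expected
        assert classify_prototypical(profile, CFG) is expected

    def test_invariant_to_score_order(self):
        rng = np.random.default_rng(41)
        scores = rng.normal(16, 3, size=40).tolist()
        shuffled = list(scores)
        rng.shuffle(shuffled)
        a = make_profile("COGx", scores, CFG)
        b = make_profile("COGx", shuffled, CFG)
        assert a.cum_counts == b.cum_counts
        assert a.r2 == pytest.approx(b.r2)
        assert a.prototypical == b.prototypical

    def test_normal_scores_yield_linear_cumulative(self):
        # scores around the motif information content make the central
        # range of the cumulative distribution close to linear
        rng = np.random.default_rng(43)
        for n in (200, 500):
            scores = rng.normal(16, 3, size=n)
            _, _, r2 = fit_cumulative(cumulative_counts(scores, CFG), CFG)
            assert r2 > 0.95


class TestCategoryDistribution:
    def test_single_category_is_always_one(self):
        links = [_link("COG1", s, "L") for s in (10, 14, 18)]
        table = category_distribution(links, [8, 12, 16])
        assert np.allclose(table.loc["L"], 1.0)

    def test_high_scoring_categories_enrich_with_threshold(self):
        links = [
            _link(f"COG{i}", 17 + 0.1 * i, "LTK"[i % 3]) for i in range(30)
        ] + [
            _link(f"COGb{i}", 9 + 0.05 * i, "CFGJ"[i % 4]) for i in range(60)
        ]
        table = category_distribution(links, [8, 12, 16])
        ltk = table.loc[["L", "T", "K"]].sum()
        assert ltk[8] <= ltk[12] <= ltk[16]
        assert ltk[16] == pytest.approx(1.0)
        # fractions over categorised links sum to 1 at each threshold
        assert np.allclose(table.sum(), 1.0)

    def test_empty_links_give_empty_table(self):
        assert category_distribution([], [8, 16]).empty

    def test_reference_column_joined(self):
        import pandas as pd

        links = [_link("COG1", 15, "L"), _link("COG2", 15, "K")]
        ref = pd.Series({"L": 3.0, "K": 1.0})
        table = category_distribution(links, [10], reference=ref)
        assert table.loc["L", "reference"] == pytest.approx(0.75)


class TestNormalizedCogCounts:
    def test_reference_cog_is_unity(self):
        links = [_link("COG1974", 15)] * 4 + [_link("COG0468", 15)] * 2
        ratios = normalized_cog_counts(links)
        assert ratios["COG1974"] == pytest.approx(1.0)
        assert ratios["COG0468"] == pytest.approx(0.5)

    def test_missing_reference_raises_with_name(self):
        with pytest.raises(ValueError, match="COG1974"):
            normalized_cog_counts([_link("COG0468", 15)])

    def test_fixture_ratios_equal_manifest_ratios(self):
        rng = np.random.default_rng(47)
        manifest = {"COG1974": 8, "COG0001": 4, "COG0002": 6, "COG0003": 2}
        links = []
        for cog, n in manifest.items():
            links += [_link(cog, 14.0)] * n
        rng.shuffle(links)
        ratios = normalized_cog_counts(links)
        for cog, n in manifest.items():
            assert ratios[cog] == pytest.approx(n / manifest["COG1974"])


class TestProfileCogs:
    def test_links_without_cog_excluded(self):
        links = [_link("COG1", 15), _link("", 15)]
        profiles = profile_cogs(links, CFG)
        assert set(profiles) == {"COG1"}


class TestR2CutoffDiagnostic:
    def test_ranking_and_running_totals(self):
        from metaregulon import make_profile, r2_cutoff_diagnostic

        rng = np.random.default_rng(53)
        profiles = {}
        for i, sd in enumerate((2.5, 3.0, 3.5, 6.0)):
            cog = f"COG{i}"
            profiles[cog] = make_profile(
                cog, rng.normal(16, sd, size=40).tolist(), CFG
            )
        known = {"COG0", "COG1"}
        table = r2_cutoff_diagnostic(profiles, known, CFG)
        # ranked by decreasing r2, running totals consistent
        assert (table["r2"].diff().dropna() <= 1e-12).all()
        assert table["n_known_at_cutoff"].iloc[-1] == sum(
            table["known"]
        )
        assert (
            table["n_known_at_cutoff"] + table["n_novel_at_cutoff"]
            == np.arange(1, len(table) + 1)
        ).all()

    def test_ineligible_cogs_excluded(self):
        from metaregulon import make_profile, r2_cutoff_diagnostic

        sparse = make_profile("COGs", [13.0, 17.0], CFG)  # < 10 in range
        table = r2_cutoff_diagnostic({"COGs": sparse}, set(), CFG)
        assert table.empty
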