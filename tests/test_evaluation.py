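"""Criteria-support statistics: proportions, tables, rates, exact Wilcoxon."""

import random

import numpy as np
import pytest
from scipy import stats

from clinsearch.errors import ClinSearchError, ConfigurationError, DegenerateInputError
from clinsearch.evaluation import (
    SUPPORT_LEVELS,
    CriterionRecord,
    SupportScoreMap,
    automation_rates,
    canonical_combo,
    involvement_count,
    load_fixture,
    mean_support_scores,
    single_vs_combined,
    tabulate_sources,
    tabulate_support,
    wald_ci,
    wilcoxon_signed_rank_exact,
)


@pytest.fixture(scope="module")
def records():
    return load_fixture("criteria_records")


def make_record(i, support="full", ctype="inclusion", sources=("P",), trial="CT1"):
    return CriterionRecord(
        id=f"R{i}", trial_id=trial, criterion_type=ctype, support=support,
        sources=frozenset(sources),
    )


class TestWaldCI:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (6, 36, (4.5, 28.8)),
            (3, 36, (0.0, 17.4)),   # lower bound truncated at zero
            (0, 10, (0.0, 0.0)),    # degenerate zero-width interval
            (5, 59, (1.4, 15.6)),
            (19, 59, (20.3, 44.1)),
            (21, 95, (13.8, 30.4)),
        ],
    )
    def test_reference_intervals(self, k, n, expected):
        assert wald_ci(k, n) == expected

    def test_zero_n_is_domain_error(self):
        with pytest.raises(DegenerateInputError):
            wald_ci(0, 0)

    def test_symmetry_under_complement(self):
        rng = random.Random(0)
        for _ in range(50):
            n = rng.randint(1, 200)
            k = rng.randint(0, n)
            lo, hi = wald_ci(k, n)
            lo2, hi2 = wald_ci(n - k, n)
            assert abs((100 - hi2) - lo) < 0.11 and abs((100 - lo2) - hi) < 0.11


class TestTables:
    def test_empty_records_zero_table(self):
        df = tabulate_support([])
        assert (df[("total", "n")].drop("total") == 0).all()

    def test_fixture_reproduces_reference_counts(self, records):
        sup = tabulate_support(records)
        t1 = load_fixture("table1_counts")
        for level in SUPPORT_LEVELS:
            assert sup.loc[level, ("inclusion", "n")] == t1.loc[level, "inclusion"]
            assert sup.loc[level, ("exclusion", "n")] == t1.loc[level, "exclusion"]
        assert sup.loc["total", ("inclusion", "n")] == 36
        assert sup.loc["total", ("exclusion", "n")] == 59
        assert sup.loc["total", ("total", "n")] == 95

    def test_fixture_reproduces_all_ci_cells(self, records):
        sup = tabulate_support(records)
        expected = {
            ("full", "inclusion"): (4.5, 28.8),
            ("full", "exclusion"): (1.4, 15.6),
            ("accurate", "inclusion"): (0.0, 17.4),
            ("accurate", "exclusion"): (14.3, 36.5),
            ("broad", "inclusion"): (4.5, 28.8),
            ("broad", "exclusion"): (20.3, 44.1),
            ("inaccurate", "inclusion"): (0.8, 21.4),
            ("inaccurate", "exclusion"): (2.5, 17.9),
            ("none", "inclusion"): (0.0, 17.4),
            ("none", "exclusion"): (3.6, 20.1),
            ("not_applicable", "inclusion"): (23.0, 54.8),
            ("not_applicable", "exclusion"): (3.6, 20.1),
        }
        for (level, ctype), ci in expected.items():
            assert sup.loc[level, (ctype, "ci")] == ci, (level, ctype)

    def test_source_matrix_matches_fixture_and_marginals(self, records):
        src = tabulate_sources(records)
        t2 = load_fixture("table2_matrix")
        for level in SUPPORT_LEVELS:
            for combo in t2.columns:
                want = t2.loc[level, combo]
                got = src.loc[level, combo] if combo in src.columns else 0
                assert got == want, (level, combo)
        # level marginals of the source matrix equal the support totals
        assert src.drop("total").sum(axis=1).tolist() == [11, 18, 25, 10, 10, 21]
        assert src.loc["total"].sum() == 95

    def test_random_records_match_hand_tally(self):
        rng = random.Random(3)
        recs = [
            make_record(
                i,
                support=rng.choice(SUPPORT_LEVELS),
                ctype=rng.choice(["inclusion", "exclusion"]),
                sources=rng.sample(["P", "S", "B", "D", "N", "I"], rng.randint(1, 3)),
            )
            for i in range(200)
        ]
        sup = tabulate_support(recs)
        src = tabulate_sources(recs)
        for level in SUPPORT_LEVELS:
            for ctype in ("inclusion", "exclusion"):
                tally = sum(1 for r in recs if r.support == level and r.criterion_type == ctype)
                assert sup.loc[level, (ctype, "n")] == tally
            combos = {}
            for r in recs:
                if r.support == level:
                    combos[canonical_combo(r.sources)] = combos.get(canonical_combo(r.sources), 0) + 1
            for combo, n in combos.items():
                assert src.loc[level, combo] == n


class TestRates:
    def test_involvement_counts(self, records):
        assert involvement_count(records, "N") == (37, pytest.approx(37 / 95))
        assert involvement_count(records, "D")[0] == 36
        assert involvement_count(records, "P")[0] == 7
        assert involvement_count(records, "S")[0] == 8

    def test_unknown_source_rejected(self, records):
        with pytest.raises(ConfigurationError):
            involvement_count(records, "Z")

    def test_single_vs_combined(self, records):
        assert single_vs_combined(records) == (47, 27, 23.40, 0.0)

    def test_single_vs_combined_all_singletons(self):
        recs = [make_record(i, support="broad", sources=("D",)) for i in range(9)]
        assert single_vs_combined(recs) == (9, 0, 0.0, 0.0)

    def test_automation_rates_fixture(self, records):
        r = automation_rates(records)
        assert r.n_scorable == 74
        assert r.full_automation == pytest.approx(29 / 74)
        assert r.prescreen == pytest.approx(54 / 74)
        assert r.contribution_incl_na["inclusion"] == pytest.approx(15 / 36)
        assert r.contribution_incl_na["exclusion"] == pytest.approx(39 / 59)
        assert r.prescreen_by_type["inclusion"] == pytest.approx(15 / 22)
        assert r.prescreen_by_type["exclusion"] == pytest.approx(39 / 52)

    def test_all_full_records_rate_one(self):
        recs = [make_record(i, support="full") for i in range(5)]
        r = automation_rates(recs)
        assert r.full_automation == 1.0 and r.prescreen == 1.0


class TestScores:
    def test_single_record_trial(self):
        recs = [make_record(0, support="broad", ctype="inclusion"),
                make_record(1, support="none", ctype="exclusion")]
        df = mean_support_scores(recs)
        assert df.loc["CT1", "inclusion"] == 60.0
        assert df.loc["CT1", "exclusion"] == 0.0

    def test_hand_mean_two_levels(self):
        recs = [make_record(0, support="full", ctype="inclusion"),
                make_record(1, support="broad", ctype="inclusion")]
        df = mean_support_scores(recs)
        assert df.loc["CT1", "inclusion"] == pytest.approx((100 + 60) / 2)

    def test_full_double_weighting(self):
        recs = [make_record(0, support="full", ctype="inclusion"),
                make_record(1, support="none", ctype="inclusion")]
        uniform = mean_support_scores(recs, SupportScoreMap(weighting="uniform"))
        double = mean_support_scores(recs, SupportScoreMap(weighting="full_double"))
        assert uniform.loc["CT1", "inclusion"] == pytest.approx(50.0)
        assert double.loc["CT1", "inclusion"] == pytest.approx(200 / 3)

    def test_not_applicable_excluded(self):
        recs = [make_record(0, support="full", ctype="inclusion"),
                make_record(1, support="not_applicable", ctype="inclusion", sources=("I",))]
        df = mean_support_scores(recs)
        assert df.loc["CT1", "inclusion"] == 100.0

    def test_fixture_inclusion_exceeds_exclusion_per_trial(self, records):
        df = mean_support_scores(records, SupportScoreMap(weighting="full_double"))
        assert len(df) == 5
        assert (df["inclusion"] > df["exclusion"]).all()


class TestWilcoxon:
    def test_five_all_positive_pairs(self):
        pairs = [(8.3, 0.0), (9.4, 0.0), (11.7, 0.0), (1.2, 0.0), (6.7, 0.0)]
        t, p = wilcoxon_signed_rank_exact(pairs)
        assert t == 15.0
        assert p == pytest.approx(0.0625)

    def test_single_positive_pair(self):
        t, p = wilcoxon_signed_rank_exact([(3.0, 1.0)])
        assert (t, p) == (1.0, 1.0)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank_exact([(1.0, 1.0), (2.0, 2.0)])

    def test_sign_flip_symmetry(self):
        rng = random.Random(7)
        diffs = [rng.uniform(-3, 3) for _ in range(8)]
        t1, p1 = wilcoxon_signed_rank_exact(diffs)
        t2, p2 = wilcoxon_signed_rank_exact([-d for d in diffs])
        n = len([d for d in diffs if d != 0])
        assert t1 + t2 == pytest.approx(n * (n + 1) / 2)
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            diffs = rng.normal(0.5, 1.0, size=9)
            diffs = diffs[diffs != 0]
            _, p = wilcoxon_signed_rank_exact(diffs)
            ref = stats.wilcoxon(diffs, alternative="two-sided", mode="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_envelope(self):
        # continuity-corrected normal approximation tracks the exact p
        # closely once n >= 15 (sanity envelope, not a gate on accuracy)
        rng = np.random.default_rng(10)
        for n in (15, 16, 18, 20):
            diffs = rng.normal(0.3, 1.0, size=n)
            _, p_exact = wilcoxon_signed_rank_exact(diffs)
            ref = stats.wilcoxon(diffs, alternative="two-sided", mode="approx", correction=True)
            assert abs(p_exact - ref.pvalue) < 0.02


class TestFixtures:
    def test_totals(self, records):
        assert len(records) == 95
        assert sum(1 for r in records if r.criterion_type == "inclusion") == 36
        assert sum(1 for r in records if r.criterion_type == "exclusion") == 59

    def test_not_applicable_source_is_I(self, records):
        for r in records:
            if r.support == "not_applicable":
                assert r.sources == {"I"}

    def test_trial_sizes_match_reported_splits(self, records):
        splits = {}
        for r in records:
            key = (r.trial_id, r.criterion_type)
            splits[key] = splits.get(key, 0) + 1
        got = sorted(
            (splits[(t, "inclusion")], splits[(t, "exclusion")])
            for t in sorted({r.trial_id for r in records})
        )
        assert got == sorted([(6, 16), (9, 13), (5, 4), (7, 13), (9, 13)])

    def test_unknown_fixture(self):
        with pytest.raises(ClinSearchError):
            load_fixture("nope")
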