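import numpy as np
import pandas as pd
import pytest

from nestquant.survival import (
    CategorizationRule,
    cox_fit,
    find_cutpoints,
    km_logrank,
    logrank_statistic,
    logrank_test,
    miller_siegmund_p,
    npi_category,
    npi_score,
    roc_auc,
    spearman_screen,
)
from nestquant.synthetic import CohortScenario, generate_cohort


def two_group_logrank_oracle(times, events, groups):
    """Textbook 2-group log-rank: U^2/V with hypergeometric sums."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    U = V = 0.0
    for t in np.unique(times[events == 1]):
        at = times >= t
        d = ((times == t) & (events == 1)).sum()
        n = at.sum()
        n1 = (at & (groups == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U * U / V


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        events = np.ones(8, int)
        groups = np.repeat([0, 1], 4)
        assert logrank_statistic(times, events, groups) == pytest.approx(0.0, abs=1e-9)

    def test_matches_handworked_two_group_oracle(self):
        # small worked table: group 1 fails early, group 0 late/censored
        times = np.array([2.0, 4, 5, 7, 9, 3, 6, 8, 10, 12])
        events = np.array([1, 1, 0, 1, 1, 1, 1, 0, 1, 1])
        groups = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        ours = logrank_statistic(times, events, groups)
        assert ours == pytest.approx(two_group_logrank_oracle(times, events, groups))

    def test_matches_lifelines_three_groups(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times = rng.exponential(10, 90)
        events = rng.integers(0, 2, 90)
        groups = rng.integers(0, 3, 90)
        ours = logrank_statistic(times, events, groups)
        ref = multivariate_logrank_test(times, groups, events).test_statistic
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_invariant_under_monotone_time_transform(self, rng):
        times = rng.exponential(10, 60) + 0.5
        events = rng.integers(0, 2, 60)
        groups = rng.integers(0, 2, 60)
        a = logrank_statistic(times, events, groups)
        b = logrank_statistic(times**2, events, groups)
        assert a == pytest.approx(b, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_statistic([1.0, 2.0], [1, 1], [0, 0])


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = km_logrank(
            np.array([0, 0, 0, 0, 1, 1, 1, 1]),
            np.array([1.0, 2, 3, 4, 1, 2, 3, 4]),
            np.ones(8, int),
        )
        curve = km.curves[0]
        s_at = dict(zip(curve["time"], curve["survival"]))
        assert s_at[2.0] == pytest.approx(0.5)  # S(2.5) = 0.5

    def test_curves_nonincreasing_and_start_at_one(self, rng):
        times = rng.exponential(10, 50) + 0.1
        events = rng.integers(0, 2, 50)
        groups = rng.integers(0, 2, 50)
        km = km_logrank(groups, times, events)
        for c in km.curves.values():
            s = c["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()

    def test_median_undefined_when_curve_stays_high(self):
        # one group entirely censored: S never reaches 0.5
        times = np.array([5.0, 6, 7, 8, 1, 1.5, 2, 2.5])
        events = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        groups = np.repeat([0, 1], 4)
        km = km_logrank(groups, times, events)
        assert np.isnan(km.medians[0])
        # 4 events: S(1)=0.75, S(1.5)=0.50 -> first time S <= 0.5 is 1.5
        assert km.medians[1] == pytest.approx(1.5)

    def test_two_identical_groups_null_pvalue(self):
        times = np.tile([1.0, 2, 3, 4, 5], 2)
        events = np.ones(10, int)
        groups = np.repeat([0, 1], 5)
        km = km_logrank(groups, times, events)
        assert km.statistic == pytest.approx(0.0, abs=1e-9)
        assert km.p_value == pytest.approx(1.0)


class TestCutpointSearch:
    def _gap_cohort(self):
        # low values fail early, high values (gap at 5) survive long
        values = np.r_[np.linspace(0, 2, 12), np.linspace(8, 10, 18)]
        times = np.r_[np.linspace(1, 6, 12), np.linspace(40, 90, 18)]
        events = np.r_[np.ones(12, int), np.zeros(18, int)]
        return values, times, events

    def test_cutpoint_lands_in_the_gap(self):
        values, times, events = self._gap_cohort()
        rule = find_cutpoints(values, times, events, min_group_frac=0.1)
        assert 2 < max(rule.cutpoints) < 8

    def test_equals_exhaustive_lifelines_oracle(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        n = 45
        values = rng.normal(size=n)
        times = rng.exponential(20, n) + 0.5
        events = rng.integers(0, 2, n)
        rule = find_cutpoints(values, times, events, min_group_frac=0.1)

        distinct = np.unique(values)
        mids = (distinct[:-1] + distinct[1:]) / 2
        best = (-np.inf, None)
        min_n = int(np.ceil(0.1 * n))
        for i in range(len(mids) - 1):
            for j in range(i + 1, len(mids)):
                g = np.where(values < mids[i], 1, np.where(values > mids[j], 3, 2))
                sizes = [(g == k).sum() for k in (1, 2, 3)]
                if min(sizes) < min_n:
                    continue
                stat = multivariate_logrank_test(times, g, events).test_statistic
                if stat > best[0]:
                    best = (stat, (mids[i], mids[j]))
        assert rule.statistic == pytest.approx(best[0], abs=1e-8)
        assert rule.cutpoints == pytest.approx(best[1])

    def test_shuffled_values_stay_inside_permutation_band(self, rng):
        values, times, events = self._gap_cohort()
        shuffled = rng.permutation(values)
        observed = find_cutpoints(shuffled, times, events).statistic
        null_stats = [
            find_cutpoints(rng.permutation(values), times, events).statistic
            for _ in range(30)
        ]
        assert observed <= np.quantile(null_stats, 0.97) * 1.5

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError, match="insufficient spread"):
            find_cutpoints(np.ones(20), np.arange(1, 21.0), np.ones(20, int))

    def test_categorize_maps_three_levels(self):
        rule = CategorizationRule("f", (1.0, 2.0))
        assert list(rule.categorize([0.5, 1.5, 2.5])) == [1, 2, 3]

    def test_corrected_p_exceeds_naive(self):
        values, times, events = self._gap_cohort()
        rule = find_cutpoints(values, times, events, with_corrected_p=True)
        assert rule.corrected_p >= rule.p_value

    def test_uncorrected_selection_inflates_type_one_error(self):
        """Maximally selected log-rank without correction rejects a true
        null far more often than the nominal 5% level."""
        rng = np.random.default_rng(42)
        n, reps, hits = 30, 40, 0
        for _ in range(reps):
            values = rng.normal(size=n)
            times = rng.exponential(20, n) + 0.1
            events = rng.integers(0, 2, n)
            if events.sum() < 5:
                continue
            rule = find_cutpoints(values, times, events)
            hits += rule.p_value < 0.05
        assert hits / reps > 0.10


class TestCox:
    def test_hr_equals_exp_coefficient(self):
        cohort = generate_cohort(
            CohortScenario(n_patients=300, betas={"x": 0.5}, seed=1)
        )
        fit = cox_fit(cohort.patients, ["x"])
        row = fit.table.loc["x"]
        assert row["hazard_ratio"] == pytest.approx(np.exp(row["coefficient"]))

    def test_recovers_beta_at_n_1000(self):
        cohort = generate_cohort(
            CohortScenario(n_patients=1000, betas={"x": 0.5}, seed=7)
        )
        fit = cox_fit(cohort.patients, ["x"])
        assert 0.35 <= fit.table.loc["x", "coefficient"] <= 0.65

    def test_null_covariate_within_two_se(self):
        inside = 0
        for seed in range(40):
            cohort = generate_cohort(
                CohortScenario(n_patients=300, betas={"x": 0.0}, seed=seed)
            )
            fit = cox_fit(cohort.patients, ["x"])
            coef = fit.table.loc["x", "coefficient"]
            se = (
                np.log(fit.table.loc["x", "ci_upper"])
                - np.log(fit.table.loc["x", "ci_lower"])
            ) / (2 * 1.96)
            inside += abs(coef) < 2 * se
        assert inside / 40 >= 0.9

    def test_guards_on_events_and_constant_covariates(self):
        df = pd.DataFrame(
            {"time": np.arange(1.0, 21), "event": [1] * 5 + [0] * 15, "x": np.ones(20)}
        )
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["x"])
        df["event"] = 1
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])


class TestROC:
    def test_perfect_separation(self):
        auc, (lo, hi) = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0 and hi == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        outcome = rng.integers(0, 2, 2000)
        auc, _ = roc_auc(scores, outcome)
        assert abs(auc - 0.5) < 0.03

    def test_equals_pairwise_concordance_oracle(self, rng):
        scores = rng.normal(size=20)
        outcome = rng.integers(0, 2, 20)
        if outcome.sum() in (0, 20):
            outcome[0] = 1 - outcome[0]
        auc, _ = roc_auc(scores, outcome)
        pos = scores[outcome == 1]
        neg = scores[outcome == 0]
        conc = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestNPI:
    @pytest.mark.parametrize(
        "size,ln,grade,score,cat",
        [(2.0, 1, 2, 3.4, 2), (0.0, 1, 1, 2.0, 1), (5.0, 3, 3, 7.0, 3)],
    )
    def test_printed_formula_and_categories(self, size, ln, grade, score, cat):
        s = npi_score(size, ln, grade)
        assert s == pytest.approx(score)
        assert npi_category(s) == cat

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            npi_score(2.0, 4, 2)
        with pytest.raises(ValueError):
            npi_score(2.0, 1, 0)
        with pytest.raises(ValueError):
            npi_score(-1.0, 1, 1)


class TestSpearman:
    def test_perfect_and_reversed_rank_agreement(self):
        f = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [5.0, 4, 3, 2, 1]})
        rho, _ = spearman_screen(f, [1, 2, 3, 4, 5])
        assert rho.loc["a", "grade"] == pytest.approx(1.0)
        assert rho.loc["b", "grade"] == pytest.approx(-1.0)

    def test_equals_pearson_of_ranks(self, rng):
        from scipy import stats as sps

        x = rng.normal(size=10)
        y = rng.normal(size=10)
        f = pd.DataFrame({"x": x})
        rho, _ = spearman_screen(f, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        assert rho.loc["x", "grade"] == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_constant_vector_missing(self):
        f = pd.DataFrame({"a": [1.0, 1, 1, 1]})
        rho, _ = spearman_screen(f, [1, 2, 3, 4])
        assert np.isnan(rho.loc["a", "grade"])


def test_logrank_test_reports_df():
    times = np.array([1.0, 2, 3, 4, 5, 6])
    events = np.ones(6, int)
    groups = np.array([0, 1, 2, 0, 1, 2])
    stat, p, df = logrank_test(times, events, groups)
    assert df == 2 and 0 <= p <= 1
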