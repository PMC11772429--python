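from fractions import Fraction

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from tapse3d.outcomes import (
    CohortRecord,
    cox_fit,
    km_estimate,
    logrank_test,
    pearson_corr,
    roc_cutoff,
    roc_cutoff_from_values,
    screen_then_multivariate,
    stratify_rvef_itapse,
)
from tapse3d.synthetic import CohortSimConfig, simulate_cohort


def make_records(times, events, covariates=None, groups=None):
    n = len(times)
    covariates = covariates or {}
    groups = groups or {}
    return [
        CohortRecord(
            f"p{i}", float(times[i]), int(events[i]),
            {k: float(v[i]) for k, v in covariates.items()},
            {k: bool(v[i]) for k, v in groups.items()},
        )
        for i in range(n)
    ]


# The classic 21-patient remission-duration arm used for hand-worked
# product-limit examples: times in weeks, '+' = censored.
REMISSION_TIMES = [6, 6, 6, 6, 7, 9, 10, 10, 11, 13, 16, 17, 19, 20, 22, 23, 25, 32, 32, 34, 35]
REMISSION_EVENTS = [1, 1, 1, 0, 1, 0, 1, 0, 0, 1, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0]


def hand_product_limit(times, events):
    """Independent oracle: exact product-limit steps in rational arithmetic."""
    order = np.lexsort((1 - np.asarray(events), times))
    t = np.asarray(times)[order]
    e = np.asarray(events)[order]
    at_risk = len(t)
    surv = {}
    s = Fraction(1)
    for u in sorted(set(t)):
        d = int(np.sum((t == u) & (e == 1)))
        n_u = int(np.sum(t >= u))
        if d:
            s *= Fraction(n_u - d, n_u)
        surv[u] = s
        at_risk = n_u
    return surv


class TestKaplanMeier:
    def test_hand_worked_remission_fixture(self):
        records = make_records(REMISSION_TIMES, REMISSION_EVENTS)
        est = km_estimate(records)["all"]
        expected = hand_product_limit(REMISSION_TIMES, REMISSION_EVENTS)
        for t, s in expected.items():
            assert est.survival_at(t) == pytest.approx(float(s), abs=1e-12)
        # spot-check the first two steps against the textbook fractions
        assert est.survival_at(6) == pytest.approx(float(Fraction(18, 21)), abs=1e-12)
        assert est.survival_at(7) == pytest.approx(float(Fraction(18, 21) * Fraction(16, 17)), abs=1e-12)

    def test_all_censored_gives_unit_survival(self):
        est = km_estimate(make_records([10, 20, 30], [0, 0, 0]))["all"]
        assert np.all(est.survival == 1.0)
        assert est.event_rate_1yr == 0.0

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(100, 50)
        est = km_estimate(make_records(times, np.ones(50)))["all"]
        for t in times:
            assert est.survival_at(t) == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_one_year_rate_read_from_curve(self):
        times = [100, 200, 300, 400, 500]
        events = [1, 1, 0, 1, 0]
        est = km_estimate(make_records(times, events))["all"]
        assert est.event_rate_1yr == pytest.approx(1.0 - est.survival_at(365.0))

    def test_empty_group_rejected(self):
        records = make_records([10, 20], [1, 1], groups={"g": [True, True]})
        with pytest.raises(ValueError):
            km_estimate(records, "g")


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [5, 8, 12, 20, 30, 44]
        events = [1, 0, 1, 1, 0, 1]
        records = make_records(times + times, events + events,
                               groups={"g": [True] * 6 + [False] * 6})
        stat, p = logrank_test(records, "g")
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(100, 40)
        events = rng.integers(0, 2, 40)
        flags = rng.random(40) < 0.5
        records = make_records(times, events, groups={"g": flags})
        swapped = make_records(times, events, groups={"g": ~flags})
        assert logrank_test(records, "g")[0] == pytest.approx(logrank_test(swapped, "g")[0], rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_strongly_separated_hazards_detected(self, seed):
        rng = np.random.default_rng(seed)
        t_a = rng.exponential(1000, 200)  # HR 0.1
        t_b = rng.exponential(100, 200)
        times = np.concatenate([t_a, t_b])
        times = np.minimum(times, 500.0)
        events = (np.concatenate([t_a, t_b]) <= 500.0).astype(int)
        records = make_records(times, events, groups={"g": [True] * 200 + [False] * 200})
        _, p = logrank_test(records, "g")
        assert p < 1e-3

    def test_one_group_empty_rejected(self):
        records = make_records([1, 2], [1, 1], groups={"g": [True, True]})
        with pytest.raises(ValueError):
            logrank_test(records, "g")


class TestCox:
    def test_group_hr_recovery(self):
        cfg = CohortSimConfig(n_patients=800, seed=10, dropout_fraction=0.0)
        records, truth = simulate_cohort(cfg)
        fit = cox_fit(records, ["effect_preserved"])
        entry = fit.entries["effect_preserved"]
        assert entry.ci_lower < truth["hr"] < entry.ci_upper
        assert entry.hr == pytest.approx(truth["hr"], rel=0.5)
        assert entry.hr == pytest.approx(np.exp(entry.coef), rel=1e-12)

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(25):
            cfg = CohortSimConfig(n_patients=300, seed=seed, log_hr=0.0)
            records, _ = simulate_cohort(cfg)
            entry = cox_fit(records, ["effect_preserved"]).entries["effect_preserved"]
            covered += entry.ci_lower <= 1.0 <= entry.ci_upper
        assert covered >= 20  # ~95% nominal; allows Monte-Carlo slack

    def test_noise_covariate_leaves_estimate_stable(self):
        cfg = CohortSimConfig(n_patients=600, seed=3, dropout_fraction=0.0)
        records, _ = simulate_cohort(cfg)
        rng = np.random.default_rng(99)
        for r in records:
            r.covariates["noise"] = float(rng.normal())
        uni = cox_fit(records, ["effect_preserved"]).entries["effect_preserved"]
        multi = cox_fit(records, ["effect_preserved", "noise"]).entries["effect_preserved"]
        assert multi.coef == pytest.approx(uni.coef, abs=0.1)

    def test_zero_events_rejected(self):
        records = make_records([10, 20, 30], [0, 0, 0], covariates={"x": [1, 2, 3]})
        with pytest.raises(ValueError, match="zero events"):
            cox_fit(records, ["x"])

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        records = make_records(rng.exponential(100, 50), np.ones(50),
                               covariates={"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(records, ["a", "b"])


class TestScreen:
    def _records_with_strong_covariate(self, seed, n=400):
        cfg = CohortSimConfig(n_patients=n, seed=seed, effect_threshold=None,
                              log_hr=-0.4, dropout_fraction=0.0)
        records, _ = simulate_cohort(cfg)
        return records

    def test_strong_covariate_survives_screen(self):
        hits = 0
        for seed in range(10):
            records = self._records_with_strong_covariate(seed)
            out = screen_then_multivariate(records, ["itapse_posterior", "tapse_tte"], anchor="lvef")
            hits += "itapse_posterior" in out.retained
        assert hits >= 9

    def test_degenerate_threshold_retains_everything(self):
        records = self._records_with_strong_covariate(0, n=200)
        out = screen_then_multivariate(records, ["itapse_posterior", "lvef", "rvef"], screen_p=1.0)
        assert set(out.retained) == {"itapse_posterior", "lvef", "rvef"}

    def test_pairwise_models_anchor_on_lvef(self):
        records = self._records_with_strong_covariate(0)
        out = screen_then_multivariate(
            records, ["lvef", "itapse_posterior", "itapse_volume"], screen_p=1.0, anchor="lvef"
        )
        model_covs = [m.covariates for m in out.multivariate]
        assert ["lvef", "itapse_posterior"] in model_covs
        assert ["lvef", "itapse_volume"] in model_covs

    def test_deterministic_given_fixed_records(self):
        records = self._records_with_strong_covariate(1, n=200)
        a = screen_then_multivariate(records, ["itapse_posterior", "lvef"]).as_dict()
        b = screen_then_multivariate(records, ["itapse_posterior", "lvef"]).as_dict()
        assert a == b

    def test_nothing_retained_warns_and_returns_empty(self):
        rng = np.random.default_rng(7)
        records = make_records(rng.exponential(300, 120), rng.integers(0, 2, 120),
                               covariates={"x": rng.normal(size=120)})
        with pytest.warns(UserWarning):
            out = screen_then_multivariate(records, ["x"], screen_p=1e-6)
        assert out.retained == [] and out.multivariate == []


def brute_force_roc(x, y):
    """Exhaustive all-thresholds oracle for AUC and Youden cutoff."""
    uniq = np.unique(x)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    pos, neg = x[y == 1], x[y == 0]
    rows = []
    for t in mids:
        sens_hi = np.mean(pos >= t)
        spec_hi = np.mean(neg < t)
        rows.append((t, sens_hi, spec_hi))
    auc_hi = roc_auc_score(y, x)
    if auc_hi >= 0.5:
        table = [(t, s, sp) for t, s, sp in rows]
        auc = auc_hi
    else:
        table = [(t, 1 - s, 1 - sp) for t, s, sp in rows]
        auc = 1 - auc_hi
    best = max(table, key=lambda r: (round(r[1] + r[2], 12), round(r[2], 12), -r[0]))
    return auc, best[0]


class TestRocCutoff:
    def test_perfect_separation(self):
        x = np.array([1.0, 2, 3, 10, 11, 12])
        y = np.array([1, 1, 1, 0, 0, 0])
        res = roc_cutoff_from_values(x, y)
        assert res.auc == pytest.approx(1.0)
        assert 3.0 < res.cutoff < 10.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.direction == "low_positive"

    def test_null_covariate_auc_near_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        y = rng.integers(0, 2, 1000)
        res = roc_cutoff_from_values(x, y)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        x = np.round(rng.normal(size=n), 2)  # rounding forces ties
        y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * x))).astype(int)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        res = roc_cutoff_from_values(x, y)
        auc_oracle, cutoff_oracle = brute_force_roc(x, y)
        assert res.auc == pytest.approx(auc_oracle, abs=1e-10)
        assert res.cutoff == pytest.approx(cutoff_oracle, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_cutoff_from_values(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_records_interface(self):
        records = make_records([100, 200, 300, 400], [1, 1, 0, 0],
                               covariates={"itapse_posterior": [2.0, 3.0, 7.0, 8.0]})
        res = roc_cutoff(records, "itapse_posterior")
        assert res.direction == "low_positive"
        assert 3.0 < res.cutoff < 7.0


class TestStratification:
    def test_three_groups_with_boundary_rules(self):
        records = make_records(
            [100] * 6, [0] * 6,
            covariates={
                "rvef": [50, 40, 50, 40, 45, 50],
                "itapse_posterior": [6, 6, 3, 3, 6, 4.5],
            },
        )
        labels = stratify_rvef_itapse(records)
        # (50,6)->1, (40,6)->2, (50,3)->2, (40,3)->3,
        # rvef exactly 45 counts preserved -> 1; itapse exactly 4.5 counts reduced -> 2
        assert labels.tolist() == [1, 2, 2, 3, 1, 2]

    def test_missing_covariate_rejected(self):
        records = make_records([10], [0], covariates={"rvef": [50]})
        with pytest.raises(KeyError, match="itapse_posterior"):
            stratify_rvef_itapse(records)


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r, _ = pearson_corr(x, y)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_null_correlation_small(self):
        rng = np.random.default_rng(8)
        small = sum(
            abs(pearson_corr(rng.normal(size=1000), rng.normal(size=1000))[0]) < 0.1
            for _ in range(20)
        )
        assert small >= 19

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
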