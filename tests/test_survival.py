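"""Survival machinery: rates, KM, log-rank, Cox vs grid oracle, matching."""

import numpy as np
import pandas as pd
import pytest

from csvdstrat import (
    CoxModelSpec,
    CoxMortalityModel,
    age_match_controls,
    cox_fit,
    km_curve,
    logrank,
    person_year_rates,
    ph_check,
)
from csvdstrat.survival import round_half_away
from conftest import make_cohort, make_subject, make_survival_frame


class TestPersonYearRates:
    def test_rates_on_toy_groups(self):
        records = (
            [make_subject(followup=2.0, died=1), make_subject(followup=3.0)]
            + [make_subject(wmh_ratio=0.002, followup=4.0, died=1)]
        )
        cohort = make_cohort(records)
        phen = pd.DataFrame(
            {"subject_id": cohort["subject_id"], "csvd_type": ["control", "control", "type1"]}
        )
        rates = person_year_rates(cohort, phen, "csvd_type").set_index("group")
        assert rates.loc["control", "events"] == 1
        assert rates.loc["control", "person_years"] == pytest.approx(5.0)
        assert rates.loc["control", "rate_per_100py"] == pytest.approx(20.0)
        assert rates.loc["type1", "rate_per_100py"] == pytest.approx(25.0)

    def test_zero_events_rate_is_zero(self):
        cohort = make_cohort([make_subject(followup=3.0)])
        phen = pd.DataFrame({"subject_id": cohort["subject_id"], "csvd_type": ["control"]})
        rates = person_year_rates(cohort, phen, "csvd_type")
        assert rates["rate_per_100py"].iloc[0] == 0.0

    @pytest.mark.parametrize(
        "events, py, printed",
        [(18, 1925.0, 0.9), (7, 215.0, 3.3), (21, 544.0, 3.9)],
    )
    def test_display_rounding_matches_printed_convention(self, events, py, printed):
        assert round_half_away(100.0 * events / py, 1) == printed

    def test_unknown_grouping(self, fixture_cohort, fixture_results):
        with pytest.raises(ValueError):
            person_year_rates(fixture_cohort, fixture_results[0], "nope")

    def test_event_partitions_agree(self, fixture_cohort, fixture_results):
        # the same deaths are partitioned by type and by score
        results, _ = fixture_results
        by_type = person_year_rates(fixture_cohort, results, "csvd_type")
        by_score = person_year_rates(fixture_cohort, results, "csvd_score")
        assert by_type["events"].sum() == by_score["events"].sum() == 62
        assert by_type["person_years"].sum() == pytest.approx(by_score["person_years"].sum())


class TestKaplanMeier:
    def test_no_deaths_survival_is_one(self):
        curve = km_curve([1.0, 2.0, 3.0], [False, False, False])
        assert np.allclose(curve.survival, 1.0)

    def test_closed_form_no_censoring(self):
        curve = km_curve([1.0, 2.0, 3.0], [True, True, True])
        lookup = dict(zip(curve.times, curve.survival))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_monotone_in_unit_interval(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(2.0, size=120)
        e = rng.random(120) < 0.6
        curve = km_curve(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_agrees_with_analytic_exponential(self):
        # 200 exponential subjects, no censoring: KM ~ exp(-lambda t)
        rng = np.random.default_rng(11)
        lam = 0.5
        t = rng.exponential(1 / lam, size=200)
        curve = km_curve(t, np.ones(200, dtype=bool))
        inner = (curve.times > np.quantile(t, 0.05)) & (curve.times < np.quantile(t, 0.9))
        # Greenwood-free bound: pointwise deviation well within 4/sqrt(n)
        dev = np.abs(curve.survival[inner] - np.exp(-lam * curve.times[inner]))
        assert dev.max() < 4 / np.sqrt(200)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            km_curve([], [])
        with pytest.raises(ValueError):
            km_curve([0.0, 1.0], [True, True])


def test_km_plot_writes_file(tmp_path):
    from csvdstrat.survival import plot_km_curves

    curve = km_curve([1.0, 2.0, 3.0], [True, False, True], group="demo")
    out = tmp_path / "km.png"
    plot_km_curves([curve], str(out))
    assert out.stat().st_size > 0


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([1.0, 2.0, 3.0], [True, True, False])
        stat, df, p = logrank([g, g])
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_group_sum(self):
        # A dies at 1, 2; B dies at 3, 4; no censoring.
        # O_A = 2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9 = 17/36
        # chi2 = (2 - 5/6)^2 / (17/36) = 2.882...
        stat, df, _ = logrank([([1.0, 2.0], [True, True]), ([3.0, 4.0], [True, True])])
        expected = (2 - 5 / 6) ** 2 / (17 / 36)
        assert stat == pytest.approx(expected, rel=1e-6)

    def test_power_under_strong_effect(self):
        # true HR 3 at n = 500/group: essentially always detected
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(10.0, 500).clip(max=8.0)
            t1 = rng.exponential(10.0 / 3.0, 500).clip(max=8.0)
            e0, e1 = t0 < 8.0, t1 < 8.0
            _, _, p = logrank([(t0, e0), (t1, e1)])
            detected += p < 0.05
        assert detected >= 19

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            logrank([([1.0], [True]), ([], [])])


# ---------------------------------------------------------------------------
# Independent Cox oracle: grid search over the partial likelihood
# ---------------------------------------------------------------------------

def partial_loglik(beta, times, events, x, ties):
    """Brute-force Cox partial log-likelihood for one covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(times[events]):
        dead = events & (times == t)
        at_risk = times >= t
        d = int(dead.sum())
        s = x[dead].sum()
        ll += beta * s
        risk_sum = np.exp(beta * x[at_risk]).sum()
        dead_sum = np.exp(beta * x[dead]).sum()
        if ties == "breslow":
            ll -= d * np.log(risk_sum)
        else:  # efron
            for j in range(d):
                ll -= np.log(risk_sum - (j / d) * dead_sum)
    return ll


def grid_argmax(times, events, x, ties, lo=-4.0, hi=4.0, step=1e-3):
    grid = np.arange(lo, hi + step, step)
    vals = [partial_loglik(b, times, events, x, ties) for b in grid]
    return grid[int(np.argmax(vals))]


SMALL_INSTANCES = [
    # times, events, x  (<= 8 subjects; includes tied event times)
    ([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 1, 0, 1, 0], [1, 1, 0, 1, 0, 0]),
    ([2.0, 2.0, 3.0, 3.0, 5.0, 7.0, 8.0], [1, 1, 1, 0, 1, 1, 0], [1, 0, 1, 1, 0, 0, 1]),
    ([1.0, 1.0, 1.0, 2.0, 2.0, 4.0, 4.0, 6.0], [1, 1, 0, 1, 1, 1, 0, 1], [1, 0, 1, 1, 0, 0, 1, 0]),
]


class TestCoxModel:
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    @pytest.mark.parametrize("instance", SMALL_INSTANCES)
    def test_matches_grid_search_oracle(self, ties, instance):
        times, events, x = instance
        frame = make_survival_frame(times, events, x)
        model = CoxMortalityModel(
            exposure="x", reference_level=0, covariates=(), ties_method=ties
        ).fit(frame)
        beta_hat = model.summary_.loc["x[1]", "coef"]
        beta_grid = grid_argmax(times, events, x, ties)
        assert beta_hat == pytest.approx(beta_grid, abs=2e-3)

    def test_ties_methods_differ_with_ties(self):
        times, events, x = SMALL_INSTANCES[2]
        frame = make_survival_frame(times, events, x)
        b = {
            ties: CoxMortalityModel(
                exposure="x", reference_level=0, covariates=(), ties_method=ties
            )
            .fit(frame)
            .summary_.loc["x[1]", "coef"]
            for ties in ("efron", "breslow")
        }
        assert b["efron"] != pytest.approx(b["breslow"], abs=1e-6)

    def test_identical_groups_hr_one(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(4.0, 60).clip(max=8.0)
        e = (t < 8.0).astype(int)
        frame = make_survival_frame(
            np.concatenate([t, t]), np.concatenate([e, e]), [0] * 60 + [1] * 60
        )
        model = CoxMortalityModel(exposure="x", reference_level=0, covariates=()).fit(frame)
        row = model.summary_.loc["x[1]"]
        assert row["hazard_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert row["ci95_low"] < 1.0 < row["ci95_high"]

    def test_hr_ci_relations(self, fixture_cohort, fixture_results):
        model = cox_fit(fixture_cohort, fixture_results[0])
        s = model.summary_
        assert np.allclose(s["hazard_ratio"], np.exp(s["coef"]))
        assert np.allclose(s["ci95_low"], np.exp(s["coef"] - 1.96 * s["se"]))
        assert (s["ci95_low"] <= s["hazard_ratio"]).all()
        assert (s["hazard_ratio"] <= s["ci95_high"]).all()
        assert model.n_ == 735 and model.events_ == 62

    def test_no_events_raises(self):
        frame = make_survival_frame([1.0, 2.0], [0, 0], [0, 1])
        with pytest.raises(ValueError, match="events"):
            CoxMortalityModel(exposure="x", reference_level=0, covariates=()).fit(frame)

    def test_zero_event_level_warns(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(3.0, 40).clip(max=6.0)
        e = (t < 6.0).astype(int)
        t2 = np.full(4, 6.0)
        frame = make_survival_frame(
            np.concatenate([t, t2]), np.concatenate([e, np.zeros(4, int)]),
            [0] * 40 + [1] * 4,
        )
        with pytest.warns(UserWarning, match="zero events"):
            CoxMortalityModel(exposure="x", reference_level=0, covariates=()).fit(frame)

    def test_followup_covariate_warns(self, fixture_cohort, fixture_results):
        # follow-up time is the outcome timescale: the flag warns, and the
        # partial likelihood may legitimately diverge on such a covariate
        spec = CoxModelSpec(include_followup_covariate=True, covariates=("age", "sex"))
        with pytest.warns(UserWarning, match="degenerate"):
            try:
                cox_fit(fixture_cohort, fixture_results[0], spec)
            except RuntimeError:
                pass


class TestPHCheck:
    def test_single_group_errors(self):
        frame = make_survival_frame([1.0, 2.0, 3.0], [1, 1, 0], [1, 1, 1])
        with pytest.raises(ValueError):
            ph_check(frame, None, CoxModelSpec(exposure="x", reference_level=1, covariates=()))

    def test_proportional_data_not_rejected(self):
        rng = np.random.default_rng(42)
        n = 300
        x = np.repeat([0, 1], n // 2)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.7 * x))).clip(max=8.0)
        e = (t < 8.0).astype(int)
        p = ph_check(
            make_survival_frame(t, e, x),
            None,
            CoxModelSpec(exposure="x", reference_level=0, covariates=()),
        )
        assert p > 0.05

    def test_detects_time_increasing_hazard_ratio(self):
        # group 1 hazard rises ~t^2 relative to group 0 (Weibull shape 3)
        rng = np.random.default_rng(0)
        n = 500
        t0 = rng.exponential(8.0, n).clip(max=8.0)
        t1 = (rng.exponential(1.0, n) * 6.0**3) ** (1 / 3)
        t1 = t1.clip(max=8.0)
        t = np.concatenate([t0, t1])
        e = (t < 8.0).astype(int)
        x = np.repeat([0, 1], n)
        p = ph_check(
            make_survival_frame(t, e, x),
            None,
            CoxModelSpec(exposure="x", reference_level=0, covariates=()),
        )
        assert p < 0.05


class TestAgeMatching:
    def _frames(self, control_ages, exposed_ages):
        controls = make_cohort([make_subject(age=a) for a in control_ages])
        exposed = make_cohort([make_subject(age=a) for a in exposed_ages])
        exposed["subject_id"] = "e" + exposed["subject_id"]
        return controls, exposed

    def test_identical_age_lists_pair_perfectly(self):
        ages = [60.0, 65.0, 70.0, 75.0]
        controls, exposed = self._frames(ages, ages)
        matched, table = age_match_controls(controls, exposed, seed=1)
        assert len(matched) == 4
        assert table["age_diff"].abs().max() == pytest.approx(0.0)

    def test_caliper_leaves_unmatchable_exposed_unmatched(self):
        controls, exposed = self._frames([58.0, 69.0, 71.0], [70.0, 70.0, 70.0])
        matched, table = age_match_controls(controls, exposed, seed=2, caliper=2.0)
        assert sorted(matched["age_years"]) == [69.0, 71.0]
        assert table["control_id"].isna().sum() == 1

    def test_all_pairs_within_caliper(self):
        rng = np.random.default_rng(9)
        controls, exposed = self._frames(
            rng.uniform(50, 90, 200), rng.uniform(55, 85, 40)
        )
        _, table = age_match_controls(controls, exposed, seed=3, caliper=2.0)
        diffs = table["age_diff"].dropna()
        assert (diffs.abs() <= 2.0).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        controls, exposed = self._frames(rng.uniform(50, 90, 50), rng.uniform(55, 85, 20))
        m1, t1 = age_match_controls(controls, exposed, seed=5)
        m2, t2 = age_match_controls(controls, exposed, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_empty_input_raises(self):
        controls, exposed = self._frames([60.0], [61.0])
        with pytest.raises(ValueError):
            age_match_controls(controls.iloc[:0], exposed, seed=0)
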