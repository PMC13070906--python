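"""Survival estimators: hand oracles, brute-force checks, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tnsalvage as tn
from tnsalvage.errors import ConvergenceError
from tnsalvage.survival import epoch_split, km_median

from conftest import within_3se

# hand example: censor at 1, events at 2 and 3
HAND_TIMES = [1.0, 2.0, 3.0]
HAND_EVENTS = [0, 1, 1]


def _km_oracle(times, events):
    """Exhaustive risk-set recomputation of the product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    s = 1.0
    for u in sorted(set(times[events == 1])):
        r = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        s *= 1 - d / r
        out.append((u, s))
    return out


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = tn.km_estimate(HAND_TIMES, HAND_EVENTS)
        assert tn.survival_at(curve, 2.0)[0] == pytest.approx(0.5)
        assert tn.survival_at(curve, 3.0)[0] == pytest.approx(0.0)
        assert tn.survival_at(curve, 2.5)[0] == pytest.approx(0.5)

    def test_all_censored_flat_curve(self):
        curve = tn.km_estimate([1.0, 2.0], [0, 0])
        assert curve.event_times.size == 0
        assert tn.survival_at(curve, 5.0)[0] == 1.0

    @pytest.mark.parametrize("times,events,err", [
        ([], [], "empty"),
        ([-1.0], [1], "positive"),
    ])
    def test_input_errors(self, times, events, err):
        with pytest.raises(ValueError, match=err):
            tn.km_estimate(times, events)

    def test_survival_at_conventions(self):
        curve = tn.km_estimate(HAND_TIMES, HAND_EVENTS)
        assert tn.survival_at(curve, 0.0) == (1.0, 1.0, 1.0)
        assert tn.survival_at(curve, 99.0)[0] == pytest.approx(0.0)
        with pytest.raises(ValueError):
            tn.survival_at(curve, -0.5)

    @given(st.lists(st.tuples(st.floats(0.1, 10.0), st.booleans()),
                    min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_oracle(self, rows):
        times = [round(t, 1) for t, _ in rows]  # rounding forces ties
        events = [int(e) for _, e in rows]
        if sum(events) == 0:
            return
        curve = tn.km_estimate(times, events)
        for u, s in _km_oracle(times, events):
            assert tn.survival_at(curve, u)[0] == pytest.approx(s, abs=1e-12)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(2.0, 300).round(1) + 0.1
        e = rng.integers(0, 2, 300)
        curve = tn.km_estimate(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for u in curve.event_times:
            assert tn.survival_at(curve, u)[0] == pytest.approx(
                float(kmf.predict(u)), abs=1e-10)


class TestMedian:
    def test_not_reached_signal(self):
        curve = tn.km_estimate([1.0, 2.0, 3.0], [1, 0, 0])
        res = km_median(curve)
        assert not res.reached and res.median is None

    def test_hand_median_definition(self):
        res = km_median(tn.km_estimate(HAND_TIMES, HAND_EVENTS))
        assert res.median == 2.0  # first time S <= 0.5

    def test_exponential_sample_recovers_median(self, rng):
        rate = math.log(2.0) / 3.21
        t = rng.exponential(1.0 / rate, 5000)
        res = km_median(tn.km_estimate(t, np.ones_like(t)))
        assert abs(res.median - 3.21) <= 0.15
        assert res.ci_low < 3.21 < res.ci_high

    def test_study_cohort_median(self, km_curve):
        res = km_median(km_curve)
        assert abs(res.median - 3.21) <= 0.15


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        res = tn.log_rank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_event_hand_formula(self):
        # risk sets: group0 n=2, group1 n=2; one event in group1 at t=1
        t = [1.0, 2.0, 1.0, 2.0]
        e = [0, 0, 1, 0]
        g = [0, 0, 1, 1]
        res = tn.log_rank(t, e, g)
        # O-E = 1 - 2/4 = 0.5 ; V = 1*(2/4)*(2/4)*(3/3) = 0.25
        assert res.statistic == pytest.approx(0.5 ** 2 / 0.25)

    def test_power_under_strong_effect(self, rng):
        n = 5000
        g = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.2 * 2.15 ** g))
        c = rng.uniform(1, 6, n)
        res = tn.log_rank(np.minimum(t, c), (t <= c).astype(int), g)
        assert res.p_value < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            tn.log_rank([1.0, 2.0], [1, 1], [0, 0])


def _brute_force_partial_loglik(beta, times, events, x):
    """Independent Efron partial likelihood by direct risk-set enumeration."""
    ll = 0.0
    for u in sorted(set(t for t, e in zip(times, events) if e == 1)):
        D = [i for i, (t, e) in enumerate(zip(times, events)) if t == u and e == 1]
        R = [i for i, t in enumerate(times) if t >= u]
        d = len(D)
        sr = sum(math.exp(beta * x[i]) for i in R)
        sd = sum(math.exp(beta * x[i]) for i in D)
        ll += sum(beta * x[i] for i in D)
        for l in range(d):
            ll -= math.log(sr - l / d * sd)
    return ll


class TestCox:
    def test_grid_search_oracle_tiny_dataset(self):
        times = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 1, 1, 0, 1, 1]
        x = [1.0, 1.0, 0.0, 1.0, 0.0, 0.0]
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [_brute_force_partial_loglik(b, times, events, x) for b in grid]
        b_star = grid[int(np.argmax(lls))]
        res = tn.cox_fit(times, events, np.array(x)[:, None])
        assert abs(res.terms[0].coef - b_star) < 1e-4
        assert res.log_likelihood >= res.null_log_likelihood
        assert res.max_score < 1e-6

    def test_mirror_symmetry_gives_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 1, 1, 1, 1]
        x = [0, 0, 0, 1, 1, 1]
        res = tn.cox_fit(times, events, np.array(x, float)[:, None])
        assert res.terms[0].coef == pytest.approx(0.0, abs=1e-8)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 400
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.7 * x1 - 0.3 * x2))
        c = rng.uniform(0.3, 3.0, n)
        time_, ev = np.minimum(t, c), (t <= c).astype(int)
        ours = tn.cox_fit(time_, ev, np.column_stack([x1, x2]))
        df = pd.DataFrame({"T": time_, "E": ev, "x1": x1, "x2": x2})
        ref = lifelines.CoxPHFitter().fit(df, "T", "E")
        for j, name in enumerate(["x1", "x2"]):
            assert ours.terms[j].coef == pytest.approx(ref.params_[name], abs=1e-5)
            assert ours.terms[j].se == pytest.approx(
                ref.standard_errors_[name], abs=1e-5)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tn.cox_fit([1.0, 2.0, 3.0], [1, 1, 1], np.ones((3, 1)))

    def test_separation_signalled(self):
        # covariate perfectly ordered with event times: monotone likelihood
        times = [1.0, 2.0, 3.0, 4.0]
        x = [1.0, 1.0, 0.0, 0.0]
        with pytest.raises(ConvergenceError):
            tn.cox_fit(times, [1, 1, 1, 1], np.array(x)[:, None])

    def test_time_rescaling_invariance(self, rng):
        n = 150
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(0.5 * x)).round(2) + 0.01
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        a = tn.cox_fit(t, e, x[:, None])
        b = tn.cox_fit(t * 37.0, e, x[:, None])
        assert a.terms[0].coef == pytest.approx(b.terms[0].coef, abs=1e-8)
        lr_a = tn.log_rank(t, e, x)
        lr_b = tn.log_rank(t * 37.0, e, x)
        assert lr_a.statistic == pytest.approx(lr_b.statistic, abs=1e-10)

    def test_wald_ci_coverage(self, rng):
        """95% CI for a true log-HR covers the truth in 95% ± 4% of fits."""
        beta = math.log(2.0)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.integers(0, 2, 500).astype(float)
            t = rng.exponential(1 / (0.3 * np.exp(beta * x)))
            c = rng.uniform(0.5, 5.0, 500)
            res = tn.cox_fit(np.minimum(t, c), (t <= c).astype(int), x[:, None])
            term = res.terms[0]
            if term.coef - 1.96 * term.se <= beta <= term.coef + 1.96 * term.se:
                hits += 1
        assert 0.91 <= hits / reps <= 0.99


class TestEpochSplit:
    def test_hand_split(self):
        df = pd.DataFrame({"time_to_recurrence": [3.0], "event": [1], "x": [1]})
        ep = epoch_split(df, 2.0)
        assert len(ep) == 2
        early = ep[ep["epoch"] == "early"].iloc[0]
        late = ep[ep["epoch"] == "late"].iloc[0]
        assert (early["entry"], early["stop"], early["event"]) == (0.0, 2.0, 0)
        assert (late["entry"], late["stop"], late["event"]) == (2.0, 3.0, 1)

    def test_short_followup_single_episode(self):
        df = pd.DataFrame({"time_to_recurrence": [1.5], "event": [1], "x": [0]})
        ep = epoch_split(df, 2.0)
        assert len(ep) == 1
        assert ep.iloc[0]["event"] == 1

    @given(st.lists(st.tuples(st.floats(0.1, 8.0), st.booleans()),
                    min_size=1, max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_event_conservation(self, rows):
        df = pd.DataFrame({
            "time_to_recurrence": [t for t, _ in rows],
            "event": [int(e) for _, e in rows],
            "x": np.zeros(len(rows)),
        })
        ep = epoch_split(df, 2.0)
        assert ep["event"].sum() == df["event"].sum()

    def test_cutpoint_beyond_followup_equals_plain_cox(self, rng):
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(0.6 * x))
        e = np.ones(n, dtype=int)
        df = pd.DataFrame({"time_to_recurrence": t, "event": e, "x": x})
        plain = tn.cox_fit(t, e, x[:, None])
        split = tn.epoch_cox(df, cutpoint=float(t.max() + 1.0),
                             covariate_epoch_map={"x": "early"})
        assert split.terms[0].coef == pytest.approx(plain.terms[0].coef, abs=1e-8)

    def test_study_cohort_epoch_hrs(self, epoch_cox_result):
        """Early hypertension and late V1 hazard ratios are recovered."""
        htn = epoch_cox_result.term("hypertension", "early")
        v1 = epoch_cox_result.term("v1_involved", "late")
        assert within_3se(htn.coef, math.log(2.15), htn.se)
        assert within_3se(v1.coef, math.log(3.02), v1.se)


class TestPearson:
    def test_perfect_negative(self):
        r, _ = tn.pearson_corr([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_hand_formula(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 7.0]
        # hand: cov=5/2? compute directly from definition
        xm, ym = np.mean(x), np.mean(y)
        expect = (sum((a - xm) * (b - ym) for a, b in zip(x, y))
                  / math.sqrt(sum((a - xm) ** 2 for a in x)
                              * sum((b - ym) ** 2 for b in y)))
        r, _ = tn.pearson_corr(x, y)
        assert r == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tn.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
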