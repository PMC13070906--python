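"""Markov cost-utility engine: identities, traces, calibration, PSA oracle."""

import dataclasses
import itertools
import math

import numpy as np
import pytest

import tnsalvage as tn
from tnsalvage.errors import CalibrationError
from tnsalvage.markov import (
    FIVE_YEAR_REINTERVENTION,
    STATES,
    TABLE_TARGETS,
    Fixed,
    MarkovSpec,
    TwoPoint,
    calibrated_inputs,
    cumulative_probability,
    default_psa_distributions,
    one_way_sa,
)


@pytest.fixture(scope="module")
def inputs():
    return calibrated_inputs()


@pytest.fixture(scope="module")
def traces(inputs):
    return {arm: tn.run_cohort_trace(tn.build_arm_spec(arm, inputs))
            for arm in ("PBC", "GKRS")}


class TestProbRate:
    def test_zero_probability_zero_rate(self):
        assert tn.prob_to_rate(0.0) == 0.0

    def test_half_probability_log_two(self):
        assert tn.prob_to_rate(0.5, 1.0) == pytest.approx(math.log(2.0))

    @pytest.mark.parametrize("p", np.arange(0.1, 0.95, 0.1))
    def test_roundtrip_identity(self, p):
        assert tn.rate_to_prob(tn.prob_to_rate(p, 2.5), 2.5) == pytest.approx(
            p, abs=1e-12)

    def test_probability_one_rejected(self):
        with pytest.raises(ValueError):
            tn.prob_to_rate(1.0)


class TestTransitionCalibration:
    def test_closed_form_annual_reintervention(self):
        cal = tn.calibrate_transitions(0.321, [(1, 0.821)], "PBC")
        assert cal["p_reintervention"] == pytest.approx(1 - 0.679 ** 0.2, abs=1e-15)

    def test_zero_target_zero_probability(self):
        cal = tn.calibrate_transitions(0.0, [(1, 0.821)], "PBC")
        assert cal["p_reintervention"] == 0.0

    @pytest.mark.parametrize("arm", ["PBC", "GKRS"])
    def test_five_cycle_cumulative_roundtrip(self, arm):
        target = FIVE_YEAR_REINTERVENTION[arm]
        cal = tn.calibrate_transitions(target, [(1, 0.821)], arm)
        assert abs(cumulative_probability(cal["p_reintervention"], 5) - target) < 1e-9

    def test_rfs_occupancy_matches_targets(self):
        targets = [(1, 0.821), (2, 0.684), (5, 0.452)]
        cal = tn.calibrate_transitions(0.321, targets, "PBC")
        rfs = np.cumprod(1 - cal["p_recurrence"])
        for k, s in targets:
            assert rfs[k - 1] == pytest.approx(s, abs=1e-9)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(CalibrationError):
            tn.calibrate_transitions(0.3, [(1, 0.5), (2, 0.9)], "PBC")


def _two_state_spec(p_death, horizon, hcc=False, discount=0.0):
    P = np.zeros((horizon, 4, 4))
    for k in range(horizon):
        P[k, 0] = [1 - p_death, 0, 0, p_death]
        P[k, 1] = [0, 1 - p_death, 0, p_death]
        P[k, 2] = [0, 0, 1 - p_death, p_death]
        P[k, 3] = [0, 0, 0, 1]
    return MarkovSpec(
        arm="PBC", transition=P,
        state_costs=np.zeros(4), utilities=np.array([1.0, 1.0, 1.0, 0.0]),
        horizon=horizon, half_cycle_correction=hcc,
        discount_rate_qalys=discount,
    )


class TestTrace:
    def test_full_health_ten_years(self):
        tr = tn.run_cohort_trace(_two_state_spec(0.0, 10))
        assert tr.discounted_qaly == pytest.approx(10.0)

    def test_hand_enumerated_half_cohort_dying(self):
        # occupancy sequence (1, 0.5, 0.25); end-of-cycle rewards: 0.5 + 0.25
        tr = tn.run_cohort_trace(_two_state_spec(0.5, 2, hcc=False))
        assert tr.discounted_qaly == pytest.approx(0.75)
        assert np.allclose(tr.occupancy[:, 0], [1.0, 0.5, 0.25])

    def test_half_cycle_correction_trapezoid(self):
        tr = tn.run_cohort_trace(_two_state_spec(0.5, 2, hcc=True))
        assert tr.discounted_qaly == pytest.approx(0.75 + 1.5 / 4)

    def test_occupancy_conserved_and_dead_monotone(self, traces):
        for tr in traces.values():
            assert np.allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-10)
            dead = tr.occupancy[:, STATES.index("Dead")]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_discounting_inequality(self):
        undisc = tn.run_cohort_trace(_two_state_spec(0.1, 10, discount=0.0))
        disc = tn.run_cohort_trace(_two_state_spec(0.1, 10, discount=0.03))
        assert disc.discounted_qaly < undisc.discounted_qaly
        assert disc.undiscounted_qaly == pytest.approx(undisc.discounted_qaly)

    def test_linearity_in_costs_exact(self, inputs):
        spec = tn.build_arm_spec("PBC", inputs)
        doubled = dataclasses.replace(
            spec,
            state_costs=spec.state_costs * 2,
            event_costs={k: v * 2 for k, v in spec.event_costs.items()},
            initial_cost=spec.initial_cost * 2,
        )
        a, b = tn.run_cohort_trace(spec), tn.run_cohort_trace(doubled)
        assert b.discounted_cost == pytest.approx(2 * a.discounted_cost, rel=1e-14)
        assert b.discounted_qaly == pytest.approx(a.discounted_qaly, rel=1e-14)

    def test_invalid_matrix_names_row(self):
        spec = _two_state_spec(0.0, 2)
        spec.transition[1, 1, 1] = 0.7
        with pytest.raises(Exception, match="Recurred"):
            tn.run_cohort_trace(spec)


class TestValueCalibration:
    def test_qaly_above_life_years_rejected_with_feasible_max(self):
        spec = dataclasses.replace(_two_state_spec(0.1, 10),
                                   state_costs=np.full(4, 100.0))
        with pytest.raises(CalibrationError, match="feasible maximum"):
            tn.calibrate_values(spec, target_cost=1000.0, target_qaly=10.0)

    @pytest.mark.parametrize("arm", ["PBC", "GKRS"])
    def test_printed_targets_reproduced(self, traces, arm):
        cost_t, qaly_t = TABLE_TARGETS[arm]
        tr = traces[arm]
        assert abs(tr.discounted_cost - cost_t) <= 0.005 * cost_t
        assert abs(tr.discounted_qaly - qaly_t) <= 0.005 * qaly_t


class TestCompareArms:
    def test_printed_table_dominance(self, traces):
        ce = tn.compare_arms(traces["PBC"], traces["GKRS"])
        assert ce.delta_cost == pytest.approx(-1845.0, abs=1.0)
        assert ce.delta_qaly == pytest.approx(0.8, abs=0.005)
        assert ce.status == "dominant"
        assert ce.icer is None

    def test_identical_arms_equivalent(self, traces):
        ce = tn.compare_arms(traces["PBC"], traces["PBC"])
        assert ce.status == "equivalent"
        assert ce.icer is None
        assert ce.delta_cost == 0.0

    def test_tradeoff_icer_arithmetic(self, traces):
        a = dataclasses.replace(traces["PBC"], discounted_cost=11000.0,
                                discounted_qaly=9.5)
        b = dataclasses.replace(traces["GKRS"], discounted_cost=10000.0,
                                discounted_qaly=9.0)
        ce = tn.compare_arms(a, b)
        assert ce.status == "tradeoff"
        assert ce.icer == pytest.approx(2000.0)

    def test_mismatched_horizons_rejected(self, traces):
        other = dataclasses.replace(traces["GKRS"], horizon=5)
        with pytest.raises(ValueError):
            tn.compare_arms(traces["PBC"], other)


class TestSensitivity:
    def test_zero_width_ranges_reproduce_base(self, inputs):
        table = one_way_sa(inputs, {
            "p_death": (inputs.p_death, inputs.p_death),
            "reintervention_cost": (4000.0, 4000.0),
        })
        assert np.allclose(table["nmb_low"], table.attrs["nmb_base"])
        assert np.allclose(table["nmb_high"], table.attrs["nmb_base"])

    def test_cost_parameter_leaves_delta_qaly(self, inputs):
        table = one_way_sa(inputs, {"reintervention_cost": (2000.0, 8000.0)})
        base = tn.compare_arms(
            tn.run_cohort_trace(tn.build_arm_spec("PBC", inputs)),
            tn.run_cohort_trace(tn.build_arm_spec("GKRS", inputs)))
        assert table["delta_qaly_low"].iloc[0] == pytest.approx(base.delta_qaly)
        assert table["delta_qaly_high"].iloc[0] == pytest.approx(base.delta_qaly)

    def test_bound_consistent_with_direct_rerun(self, inputs):
        table = one_way_sa(inputs, {"p_death": (0.0, 0.01)}, wtp=30_000.0)
        mod = dataclasses.replace(inputs, p_death=0.01)
        tr = {a: tn.run_cohort_trace(tn.build_arm_spec(a, mod))
              for a in ("PBC", "GKRS")}
        nmb = 30_000.0 * (tr["PBC"].discounted_qaly - tr["GKRS"].discounted_qaly) \
            - (tr["PBC"].discounted_cost - tr["GKRS"].discounted_cost)
        assert table["nmb_high"].iloc[0] == pytest.approx(nmb)

    def test_range_excluding_base_rejected(self, inputs):
        with pytest.raises(ValueError):
            one_way_sa(inputs, {"p_death": (0.05, 0.1)})


class TestPSA:
    def test_degenerate_dominant_ceac_is_one(self, inputs):
        dists = {"p_death": Fixed(inputs.p_death)}
        res = tn.psa(inputs, dists, seed=1)
        assert res.method == "exact"
        assert np.allclose(res.ceac["prob_pbc_optimal"], 1.0)

    def test_two_point_enumeration_oracle(self, inputs):
        """Exact PSA equals a by-hand enumeration of the 2^k support."""
        dists = {
            "five_year_reint_gkrs": TwoPoint(0.40, 0.60),
            "cost_scale_gkrs": TwoPoint(0.5, 1.5),
            "p_death": TwoPoint(0.0, 0.01),
        }
        wtp = [0.0, 20_000.0, 50_000.0]
        res = tn.psa(inputs, dists, seed=3, wtp_grid=wtp)
        assert res.method == "exact"
        # independent enumeration
        names = list(dists)
        expect = {w: 0.0 for w in wtp}
        for combo in itertools.product(*[(d.low, d.high) for d in dists.values()]):
            mod = dataclasses.replace(inputs, **dict(zip(names, combo)))
            tr = {a: tn.run_cohort_trace(tn.build_arm_spec(a, mod))
                  for a in ("PBC", "GKRS")}
            for w in wtp:
                nmb = w * (tr["PBC"].discounted_qaly - tr["GKRS"].discounted_qaly) \
                    - (tr["PBC"].discounted_cost - tr["GKRS"].discounted_cost)
                if nmb > 0:
                    expect[w] += 1 / 8
        for i, w in enumerate(wtp):
            assert res.ceac["prob_pbc_optimal"].iloc[i] == pytest.approx(expect[w])

    def test_monte_carlo_reproducible_and_bounded(self, inputs):
        a = tn.psa(inputs, default_psa_distributions(inputs), n_draws=100, seed=9)
        b = tn.psa(inputs, default_psa_distributions(inputs), n_draws=100, seed=9)
        assert a.method == "monte-carlo"
        assert a.ceac.equals(b.ceac)
        assert ((a.ceac["prob_pbc_optimal"] >= 0)
                & (a.ceac["prob_pbc_optimal"] <= 1)).all()
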