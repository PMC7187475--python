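"""Discounting conventions, arm accumulation, ICER logic."""

import math

import numpy as np
import pytest

from cariescea import model_core as mc
from cariescea.cohort_engine import CohortTrace, run_cohort
from cariescea.economics import (
    ArmResult,
    accumulate_arm,
    compute_icer,
    cycle_discount_factors,
    discount_factor,
)


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate,time,expected",
        [
            (0.05, 0.0, 1.0),
            (0.0, 37.2, 1.0),
            (0.05, 1.0, 1 / 1.05),
            (0.05, 1.5, 1 / 1.05),  # constant within the model year
            (0.05, 2.0, 1 / 1.05**2),
        ],
    )
    def test_annual_step_factor(self, rate, time, expected):
        assert discount_factor(rate, time) == pytest.approx(expected, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1.0)

    def test_timing_conventions_relate_by_one_year(self):
        start = cycle_discount_factors(0.05, 140, 0.5, "year_start")
        end = cycle_discount_factors(0.05, 140, 0.5, "year_end")
        np.testing.assert_allclose(end, start / 1.05, atol=1e-15)
        assert np.all(cycle_discount_factors(0.0, 140, 0.5, "year_end") == 1.0)


def _full_health_trace(n_cycles=140):
    occ = np.zeros((n_cycles + 1, mc.N_STATES))
    occ[:, 0] = 1.0
    return CohortTrace(occupancy=occ, entries=np.zeros_like(occ))


class TestAccumulateArm:
    def test_full_health_undiscounted_qaly_is_horizon(self, core):
        params = core.params.with_(discount_rate=0.0)
        arm = accumulate_arm(_full_health_trace(), core.states, params)
        assert arm.qaly == pytest.approx(70.0, abs=1e-9)
        assert arm.dmft == 0.0
        assert arm.total_cost == 0.0

    def test_single_filling_entry_costs_unit_cost_per_molar(self, core):
        params = core.params.with_(discount_rate=0.0)
        trace = _full_health_trace()
        trace.entries[1, mc.state_index("Filling")] = 1.0
        arm = accumulate_arm(trace, core.states, params)
        assert arm.treatment_cost == pytest.approx(203 * 8)

    def test_toy_model_matches_spreadsheet_arithmetic(self, core):
        """Four cycles of a three-state chain, recomputed cell by cell the
        way a spreadsheet lays out a Markov CEA, at 5%/yr."""
        # states: NoDisease (u=1), DentineDecay (u=0.24, flagged),
        # Filling (u=0.77, cost 203, flagged)
        m = np.array(
            [
                [0.8, 0.15, 0.05],
                [0.0, 0.60, 0.40],
                [0.0, 0.00, 1.00],
            ]
        )
        init = [1.0, 0.0, 0.0]
        trace = run_cohort(m, init, n_cycles=4)
        states = [core.states[i] for i in (0, 2, 3)]  # ND, DentineDecay, Filling
        params = core.params
        arm = accumulate_arm(trace, states, params, arm_label="toy")

        # independent spreadsheet-style recomputation
        cost = qaly = dmft = 0.0
        occ = [1.0, 0.0, 0.0]
        for k in range(4):
            t = k * 0.5
            df = (1.05) ** (-(math.floor(t) + 1))  # year-end convention
            qaly += (occ[0] * 1.0 + occ[1] * 0.24 + occ[2] * 0.77) * 0.5 * df
            dmft += (occ[1] + occ[2]) * 0.5 * df
            nxt = [
                occ[0] * m[0][0],
                occ[0] * m[0][1] + occ[1] * m[1][1],
                occ[0] * m[0][2] + occ[1] * m[1][2] + occ[2],
            ]
            entering_filling = occ[0] * m[0][2] + occ[1] * m[1][2]
            cost += entering_filling * 203 * 8 * df
            occ = nxt
        assert arm.treatment_cost == pytest.approx(cost, abs=1e-9)
        assert arm.qaly == pytest.approx(qaly, abs=1e-9)
        assert arm.dmft == pytest.approx(dmft, abs=1e-9)

    def test_discounted_totals_decrease_in_rate(self, core, suite_results):
        """0% >= 3.5% >= 5% totals for the same underlying trace."""
        by_rate = {
            r.config.discount_rate: r for r in suite_results
            if r.config.label in ("base_case", "discount_0pct", "discount_3.5pct")
        }
        for attr in ("total_cost", "dmft", "qaly"):
            v0 = getattr(by_rate[0.0].comparator, attr)
            v35 = getattr(by_rate[0.035].comparator, attr)
            v5 = getattr(by_rate[0.05].comparator, attr)
            assert v0 >= v35 >= v5

    def test_intervention_cost_stops_at_death(self, core):
        params = core.params.with_(discount_rate=0.0)
        occ = np.zeros((141, mc.N_STATES))
        occ[:, mc.DEATH_STATE] = 1.0  # everyone dead from baseline
        trace = CohortTrace(occupancy=occ, entries=np.zeros_like(occ))
        arm = accumulate_arm(
            trace, core.states, params, include_intervention_cost=True
        )
        assert arm.intervention_cost == 0.0


class TestComputeIcer:
    def _arm(self, cost, dmft, qaly, label="x"):
        return ArmResult(
            arm_label=label, total_cost=cost, treatment_cost=cost,
            intervention_cost=0.0, dmft=dmft, qaly=qaly, discount_rate=0.05,
        )

    def test_base_case_worked_example(self):
        base = self._arm(2303, 15.52, 14.74)
        interv = self._arm(3600, 13.99, 15.44)
        per_dmft = compute_icer(base, interv, "prevented_dmft", 28033)
        per_qaly = compute_icer(base, interv, "qaly_gained", 28033)
        assert per_dmft.icer == pytest.approx(849, rel=0.01)
        assert per_qaly.icer == pytest.approx(1851, rel=0.01)
        assert per_dmft.quadrant == per_qaly.quadrant == "NE"
        assert per_qaly.verdict == "cost_effective"

    def test_identical_arms_undefined(self):
        a = self._arm(100, 5, 5)
        res = compute_icer(a, a, "qaly_gained", 28033)
        assert res.undefined and math.isnan(res.icer)
        assert res.verdict == "undefined"

    def test_antisymmetric_under_arm_swap(self):
        a = self._arm(2303, 15.52, 14.74)
        b = self._arm(3600, 13.99, 15.44)
        fwd = compute_icer(a, b, "qaly_gained", 28033)
        rev = compute_icer(b, a, "qaly_gained", 28033)
        assert rev.icer == pytest.approx(fwd.icer)
        assert (fwd.quadrant, rev.quadrant) == ("NE", "SW")

    def test_dominance_verdicts(self):
        base = self._arm(1000, 10, 10)
        cheaper_better = self._arm(500, 8, 11)
        dearer_worse = self._arm(2000, 12, 9)
        assert compute_icer(base, cheaper_better, "qaly_gained").verdict == "dominant"
        assert compute_icer(base, dearer_worse, "qaly_gained").verdict == "dominated"

    def test_ne_threshold_verdict(self):
        base = self._arm(0, 10, 10)
        pricey = self._arm(1_000_000, 10, 11)
        res = compute_icer(base, pricey, "qaly_gained", 28033)
        assert res.verdict == "not_cost_effective"
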