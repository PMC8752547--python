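"""Discounting, intervention costing, cohort totals and incremental outcomes."""

import dataclasses

import numpy as np
import pytest

from padem import (
    arm_totals,
    discount_factor,
    discount_sum,
    expected_dose_outcome,
    incremental,
    user_testing_cost,
)
from padem.params import CohortSpec


class TestDiscounting:
    def test_zero_rate_gives_unit_factors(self):
        assert all(discount_factor(t, 0.0) == 1.0 for t in range(1, 11))

    def test_year_one_discounted_once(self):
        assert discount_factor(1, 0.035) == pytest.approx(1 / 1.035)

    def test_five_year_sum(self):
        assert discount_sum(5, 0.035) == pytest.approx(4.5151, abs=5e-5)

    def test_year_zero_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0, 0.035)


class TestUserTestingCost:
    def test_closed_form_at_means(self, base_config, ev_draw):
        # interviews 1387.2 + transcription 1428.0 + analysis 2346.5
        # + revisions 590.4 + training 562 + equipment 4 = 6318.1
        cost = user_testing_cost(
            ev_draw, base_config.shared.user_testing, base_config.shared.staff_rates
        )
        assert float(cost) == pytest.approx(6318.1, rel=0.001)

    def test_zero_durations_leave_fixed_costs(self, base_config, ev_draw):
        import copy

        d = copy.deepcopy(ev_draw)
        d.ut_interview_minutes = np.zeros(4)
        d.ut_analysis_minutes = np.zeros(4)
        d.ut_revision_minutes = np.zeros(3)
        cost = user_testing_cost(
            d, base_config.shared.user_testing, base_config.shared.staff_rates
        )
        assert float(cost) == pytest.approx(566.0)

    def test_single_hour_interview_arithmetic(self, base_config, ev_draw):
        # 60 min x (65+37)/60 staff + 60 x 1.75 transcription + 566 fixed = 773
        import copy

        d = copy.deepcopy(ev_draw)
        d.ut_interview_minutes = np.array([60.0, 0.0, 0.0, 0.0])
        d.ut_analysis_minutes = np.zeros(4)
        d.ut_revision_minutes = np.zeros(3)
        spec = dataclasses.replace(base_config.shared.user_testing, n_pilot=1)
        cost = user_testing_cost(d, spec, base_config.shared.staff_rates)
        assert float(cost) == pytest.approx(773.0)


class TestArmTotals:
    def test_identity_scaling_single_dose_year(self, base_config, ev_draw):
        out = expected_dose_outcome(ev_draw, "current")
        cohort = CohortSpec(doses_per_year=1, horizon_years=1, discount_rate=0.0)
        res = arm_totals(out, ev_draw.current.admin_minutes, cohort, 37.0)
        assert float(res.total_pades) == pytest.approx(float(out.p_pade))
        expected_cost = float(ev_draw.current.admin_minutes) / 60 * 37 + float(
            out.expected_error_cost
        )
        assert float(res.health_system_cost) == pytest.approx(expected_cost)
        assert float(res.total_qaly_decrement) == pytest.approx(
            float(out.expected_qaly_decrement)
        )

    def test_base_cohort_expected_value_totals(self, base_config, ev_draw):
        # 20,000 dose-years x 0.0605 pADE/dose ~ 1210 events;
        # discounted QALY decrement ~ 238
        out = expected_dose_outcome(ev_draw, "current")
        res = arm_totals(out, ev_draw.current.admin_minutes, base_config.cohort, 37.0)
        assert float(res.total_pades) == pytest.approx(1210, abs=5)
        assert float(res.total_qaly_decrement) == pytest.approx(238, abs=2)
        assert float(res.moderate_severe_pades) <= float(res.total_pades)

    def test_doubling_doses_doubles_dose_driven_outputs(self, base_config, ev_draw):
        out = expected_dose_outcome(ev_draw, "user_tested")
        c1 = base_config.cohort
        c2 = dataclasses.replace(c1, doses_per_year=2 * c1.doses_per_year)
        r1 = arm_totals(out, ev_draw.user.admin_minutes, c1, 37.0, user_testing_cost=6318.0)
        r2 = arm_totals(out, ev_draw.user.admin_minutes, c2, 37.0, user_testing_cost=6318.0)
        assert float(r2.total_pades) == pytest.approx(2 * float(r1.total_pades))
        assert float(r2.total_qaly_decrement) == pytest.approx(
            2 * float(r1.total_qaly_decrement)
        )
        # user-testing cost is one-off: cost doubles only in its dose-driven part
        assert float(r2.health_system_cost) == pytest.approx(
            2 * (float(r1.health_system_cost) - 6318.0) + 6318.0
        )


class TestIncremental:
    def _results(self, base_config, ev_draw):
        out_c = expected_dose_outcome(ev_draw, "current")
        out_u = expected_dose_outcome(ev_draw, "user_tested")
        ut = user_testing_cost(
            ev_draw, base_config.shared.user_testing, base_config.shared.staff_rates
        )
        res_c = arm_totals(out_c, ev_draw.current.admin_minutes, base_config.cohort, 37.0)
        res_u = arm_totals(
            out_u, ev_draw.user.admin_minutes, base_config.cohort, 37.0, user_testing_cost=ut
        )
        return res_c, res_u

    def test_identical_arms_give_zero_deltas(self, base_config, ev_draw):
        res_c, _ = self._results(base_config, ev_draw)
        inc = incremental(res_c, res_c, 20000.0)
        assert float(inc.delta_pades) == 0.0
        assert float(inc.nmb_at_wtp) == 0.0

    def test_zero_wtp_nmb_equals_ics(self, base_config, ev_draw):
        res_c, res_u = self._results(base_config, ev_draw)
        inc = incremental(res_c, res_u, 0.0)
        assert float(inc.nmb_at_wtp) == float(inc.incremental_cost_saving)

    def test_nmb_identity_exact(self, base_config, ev_draw):
        res_c, res_u = self._results(base_config, ev_draw)
        inc = incremental(res_c, res_u, 20000.0)
        assert float(inc.nmb_at_wtp) == pytest.approx(
            20000.0 * float(inc.delta_qaly_decrement)
            + float(inc.incremental_cost_saving),
            rel=1e-15,
        )
        # printed-scale sanity: deltas land near the published means
        assert float(inc.incremental_cost_saving) == pytest.approx(241_000, rel=0.02)
        assert float(inc.delta_qaly_decrement) == pytest.approx(145.6, rel=0.02)

    def test_mismatched_cohorts_rejected(self, base_config, ev_draw):
        res_c, res_u = self._results(base_config, ev_draw)
        other = dataclasses.replace(res_u, cohort=CohortSpec(doses_per_year=1))
        with pytest.raises(ValueError):
            incremental(res_c, other, 20000.0)
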