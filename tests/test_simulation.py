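"""Tests of the integrator and the scan experiment families."""

import numpy as np
import pytest

from folfiri_tme.cohort import cluster_initial_conditions
from folfiri_tme.dosing import Regimen
from folfiri_tme.model import BaselineParams, StateVector, zero_treatment_params
from folfiri_tme.simulation import (DEFAULT_EVAL_DAYS, combination_scan,
                                    dose_scan, parameter_scan, simulate,
                                    start_time_scan)

END_OF_COURSE = 169.0


class TestSimulate:
    def test_zero_dose_holds_equilibrium_one_year(self, baseline):
        traj = simulate(StateVector.ones(), baseline, horizon=365.0,
                        eval_days=[365.0])
        assert np.max(np.abs(traj.eval_days[365.0][:14] - 1.0)) < 1e-6

    def test_median_regimen_reduces_cancer(self, median_trajectory):
        assert median_trajectory.cancer_at(END_OF_COURSE) < \
            median_trajectory.cancer_at(0.0)

    def test_treatment_effect_for_all_cluster_ics(self, derived):
        """Cancer at end of course is below the untreated value for every
        cluster's smallest-tumor initial conditions."""
        base, treat, scal = derived
        for cluster in (1, 2, 3, 4, 5):
            init = cluster_initial_conditions(cluster)
            treated = simulate(init, base, treat, Regimen(), scal,
                               horizon=END_OF_COURSE, eval_days=[END_OF_COURSE])
            untreated = simulate(init, base, horizon=END_OF_COURSE,
                                 eval_days=[END_OF_COURSE])
            assert treated.eval_days[END_OF_COURSE][7] < \
                untreated.eval_days[END_OF_COURSE][7]

    def test_drugs_clear_between_cycles(self, treatment, scaling):
        """With cell interactions off, each drug decays below 1e-6 of its
        peak before the next cycle starts."""
        zeros = {name: 0.0 for name in BaselineParams.names()}
        zeros["C0"] = 1.0
        base = BaselineParams.from_dict(zeros)
        tp = zero_treatment_params().replace(
            delta_5fu=treatment.delta_5fu, delta_LV=treatment.delta_LV,
            delta_Ir=treatment.delta_Ir)
        traj = simulate(np.zeros(17), base, tp, Regimen(n_cycles=1), scaling,
                        horizon=14.0, grid_step=0.01)
        for i in (14, 15, 16):
            series = traj.y[i]
            assert series[-1] < 1e-6 * series.max()

    def test_negativity_within_solver_tolerance(self, median_trajectory):
        assert median_trajectory.y.min() >= -10.0 * 1e-10

    def test_tolerance_robustness_at_end_of_course(self, derived,
                                                   median_trajectory):
        base, treat, scal = derived
        tighter = simulate(StateVector.ones(), base, treat, Regimen(), scal,
                           horizon=200.0, eval_days=[END_OF_COURSE],
                           rtol=5e-9, atol=5e-11)
        c_ref = median_trajectory.cancer_at(END_OF_COURSE)
        c_tight = tighter.eval_days[END_OF_COURSE][7]
        assert abs(c_tight - c_ref) / c_ref < 1e-4

    def test_cancer_recurs_to_steady_state(self, median_trajectory):
        """After the course ends the cancer regrows toward its untreated
        steady state."""
        c169 = median_trajectory.cancer_at(169.0)
        c365 = median_trajectory.cancer_at(365.0)
        c3285 = median_trajectory.cancer_at(3285.0)
        assert c169 < c365 < c3285
        assert c3285 == pytest.approx(1.0, abs=1e-3)

    def test_eval_day_outside_horizon_rejected(self, baseline):
        with pytest.raises(ValueError):
            simulate(StateVector.ones(), baseline, horizon=10.0, eval_days=[20.0])


@pytest.fixture(scope="module")
def scan(derived):
    base, treat, scal = derived
    return combination_scan(StateVector.ones(), base, treat, Regimen(),
                            scal, horizon=END_OF_COURSE,
                            eval_days=[END_OF_COURSE])


@pytest.fixture(scope="module")
def start_scan(derived):
    base, treat, scal = derived
    init = cluster_initial_conditions(3)
    return start_time_scan(init, base, treat, Regimen(), scal,
                           start_years=(1, 7))


@pytest.fixture(scope="module")
def lv_scan(derived):
    base, treat, scal = derived
    return parameter_scan("delta_CLV5fu", base, treat,
                          [0.1, 1.0, 5.0], Regimen(), scal,
                          eval_days=DEFAULT_EVAL_DAYS)


class TestCombinationScan:
    def test_leucovorin_adds_cancer_kill(self, scan):
        c_fu = scan.trajectories["5FU"].cancer_at(END_OF_COURSE)
        c_fulv = scan.trajectories["5FU+LV"].cancer_at(END_OF_COURSE)
        assert c_fulv < c_fu

    def test_irinotecan_depletes_tregs(self, scan):
        tr_fu = scan.trajectories["5FU"].state_at(END_OF_COURSE)[3]
        tr_fuir = scan.trajectories["5FU+Ir"].state_at(END_OF_COURSE)[3]
        assert tr_fuir < tr_fu

    def test_triple_combination_is_strongest(self, scan):
        summary = scan.summary().set_index("combination")["cancer"]
        assert summary["5FU+LV+Ir"] < min(summary["5FU"], summary["5FU+LV"],
                                          summary["5FU+Ir"])

    def test_zero_lv_dose_arm_identical_to_fu_only(self, derived):
        base, treat, scal = derived
        reg = Regimen(dose_lv=0.0, dose_ir=0.0)
        a = simulate(StateVector.ones(), base, treat, reg, scal,
                     horizon=30.0, eval_days=[30.0])
        b = simulate(StateVector.ones(), base, treat,
                     Regimen(dose_ir=0.0).with_doses(dose_lv=0.0), scal,
                     horizon=30.0, eval_days=[30.0])
        np.testing.assert_array_equal(a.eval_days[30.0], b.eval_days[30.0])

    def test_leucovorin_null_without_fu(self, derived):
        """With zero 5-FU dose, cell/cytokine dynamics ignore leucovorin."""
        base, treat, scal = derived
        lv_only = simulate(StateVector.ones(), base, treat,
                           Regimen(dose_5fu=0.0, dose_ir=0.0), scal,
                           horizon=60.0, eval_days=[60.0])
        none = simulate(StateVector.ones(), base, treat, None, None,
                        horizon=60.0, eval_days=[60.0])
        np.testing.assert_allclose(lv_only.eval_days[60.0][:14],
                                   none.eval_days[60.0][:14], atol=1e-7)
        assert lv_only.series("LV").max() > 1.0  # the drug itself was present


class TestStartTimeScan:
    def test_late_start_is_closer_to_equilibrium(self, start_scan):
        d1 = np.abs(start_scan.trajectories[1].state_at(365.0)[:14] - 1.0).max()
        d7 = np.abs(start_scan.trajectories[7].state_at(7 * 365.0)[:14] - 1.0).max()
        assert d7 <= d1
        assert d7 < 1e-3

    def test_identical_start_reproduces_trajectory(self, derived):
        base, treat, scal = derived
        init = cluster_initial_conditions(2)
        a = start_time_scan(init, base, treat, Regimen(), scal,
                            start_years=(1,), horizon=600.0)
        b = start_time_scan(init, base, treat, Regimen(), scal,
                            start_years=(1,), horizon=600.0)
        np.testing.assert_array_equal(a.trajectories[1].y, b.trajectories[1].y)

    def test_start_delay_shifts_response_from_equilibrium(self, derived):
        """Starting later from an equilibrated state time-shifts the
        treatment response."""
        base, treat, scal = derived
        trajs = start_time_scan(StateVector.ones(), base, treat, Regimen(),
                                scal, start_years=(5, 7)).trajectories
        for offset in (100.0, 400.0):
            s5 = trajs[5].state_at(5 * 365.0 + offset)
            s7 = trajs[7].state_at(7 * 365.0 + offset)
            np.testing.assert_allclose(s5, s7, atol=1e-6)


class TestDoseScan:
    def test_multiplier_one_is_bitwise_reference(self, derived):
        base, treat, scal = derived
        reg = Regimen()
        scan = dose_scan(reg, base, treat, StateVector.ones(), [1.0], "FU",
                         scal, horizon=60.0, eval_days=[60.0])
        ref = simulate(StateVector.ones(), base, treat, reg, scal,
                       horizon=60.0, eval_days=[60.0])
        np.testing.assert_array_equal(scan.trajectories[1.0].y, ref.y)

    def test_cancer_nonincreasing_in_fu_dose(self, derived):
        base, treat, scal = derived
        scan = dose_scan(Regimen(), base, treat, StateVector.ones(),
                         [0.1, 0.5, 1.0, 2.0, 5.0, 10.0], "FU", scal,
                         horizon=END_OF_COURSE, eval_days=[END_OF_COURSE])
        cs = [scan.trajectories[m].cancer_at(END_OF_COURSE)
              for m in scan.axis]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(cs, cs[1:]))

    def test_zero_lv_multiplier_equals_fu_ir_arm(self, derived):
        base, treat, scal = derived
        reg = Regimen(dose_ir=0.0)
        scan = dose_scan(reg, base, treat, StateVector.ones(), [0.0], "LV",
                         scal, horizon=50.0, eval_days=[50.0])
        arm = simulate(StateVector.ones(), base, treat,
                       reg.with_doses(dose_lv=0.0), scal,
                       horizon=50.0, eval_days=[50.0])
        np.testing.assert_array_equal(scan.trajectories[0.0].y, arm.y)


class TestParameterScan:
    def test_cancer_at_169d_decreases_with_lv_synergy(self, lv_scan):
        cs = [lv_scan.trajectories[m].cancer_at(169.0) for m in lv_scan.axis]
        assert cs[0] > cs[1] > cs[2]

    def test_minimum_cancer_at_169_days(self, lv_scan):
        for m in lv_scan.axis:
            traj = lv_scan.trajectories[m]
            values = {d: traj.cancer_at(d) for d in DEFAULT_EVAL_DAYS}
            assert min(values, key=values.get) == 169.0

    def test_macrophage_shielding_is_weaker_knob(self, derived, lv_scan):
        base, treat, scal = derived
        m_scan = parameter_scan("delta_5fuM", base, treat, [0.1, 5.0],
                                Regimen(), scal, eval_days=[169.0],
                                horizon=169.0)

        def rel_range(scan):
            cs = [scan.trajectories[m].cancer_at(169.0) for m in scan.axis]
            return abs(cs[-1] - cs[0]) / max(cs)

        lv_lo = lv_scan.trajectories[0.1].cancer_at(169.0)
        lv_hi = lv_scan.trajectories[5.0].cancer_at(169.0)
        lv_range = abs(lv_hi - lv_lo) / max(lv_lo, lv_hi)
        assert rel_range(m_scan) < lv_range

    def test_unknown_parameter_lists_valid_names(self, derived):
        base, treat, scal = derived
        with pytest.raises(ValueError, match="delta_CLV5fu"):
            parameter_scan("not_a_param", base, treat, [1.0], Regimen(), scal)
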