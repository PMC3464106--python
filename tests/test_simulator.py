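"""Integration engine, Euler cross-validation oracle and condition presets."""

import numpy as np
import pytest

from conjphage import (
    ExperimentCondition,
    KineticParameters,
    PopulationState,
    Trajectory,
    euler_oracle,
    integrate,
    trajectory_deviation,
)
from conjphage.simulate import preset_condition, preset_variants


class TestIntegrate:
    def test_pure_donor_exhausts_resource_budget(self, params, cond1_donor_traj):
        """Final density approaches the resource budget r0/e (below K here)."""
        budget = min(params.K, 100.0 / params.e + 1e6)
        final = cond1_donor_traj.total_cells()[-1]
        assert final == pytest.approx(budget, rel=0.05)

    def test_empty_culture_stays_empty(self, params):
        cond = ExperimentCondition("CUSTOM", PopulationState(r=100.0),
                                   duration=200.0, sampling_interval=20.0)
        traj = integrate(cond, params)
        assert np.all(traj.y[:, 1:] == 0.0)
        assert np.allclose(traj.column("r"), 100.0)

    def test_cond2b_infection_overwhelms_donors(self, params):
        """At ~30 phage per donor the whole population is infected early."""
        traj = integrate(preset_condition("COND2B", 0), params,
                         system="infection_only")
        s = traj.state_at(300.0)
        assert s.n_D < 1.0  # essentially extinct
        assert s.n_I > 0.9 * traj.total_cells()[traj.times.searchsorted(300.0)]

    def test_states_nonnegative_and_grid_reported(self, cond3_traj):
        assert np.all(cond3_traj.y >= 0.0)
        assert cond3_traj.times[0] == 0.0
        assert cond3_traj.times[-1] == 700.0
        assert np.all(np.diff(cond3_traj.times) == 20.0)

    def test_unknown_system_rejected(self, params):
        with pytest.raises(ValueError):
            integrate(preset_condition("COND1", 0), params, system="stochastic")

    def test_reduced_system_requires_zero_eliminated_compartments(self, params):
        with pytest.raises(ValueError):
            integrate(preset_condition("COND3", 1), params,
                      system="conjugation_only")

    def test_sampling_grid_does_not_change_solution(self, params):
        """Doubling the reporting interval must not move the shared states."""
        c1 = preset_condition("COND1", 1)
        c2 = preset_condition("COND1", 1)
        c2.sampling_interval = 40.0
        t1 = integrate(c1, params)
        t2 = integrate(c2, params)
        shared = np.isin(t1.times, t2.times)
        assert np.allclose(t1.y[shared], t2.y, rtol=1e-6, atol=1e-2)


class TestEulerOracle:
    def test_agrees_with_adaptive_solver(self, params, cond1_donor_traj):
        eo = euler_oracle(preset_condition("COND1", 0), params,
                          system="conjugation_only", dt=0.01)
        assert trajectory_deviation(eo, cond1_donor_traj) < 1e-3

    def test_convergence_with_step_refinement(self, params, cond2c_traj):
        cond = preset_condition("COND2C", 0)
        dev = [trajectory_deviation(
            euler_oracle(cond, params, "infection_only", dt=dt), cond2c_traj)
            for dt in (0.08, 0.02)]
        assert dev[1] < dev[0] / 2  # first-order convergence

    def test_zero_cells_identical_to_adaptive(self, params):
        cond = ExperimentCondition("CUSTOM", PopulationState(r=100.0),
                                   duration=100.0, sampling_interval=20.0)
        assert trajectory_deviation(euler_oracle(cond, params, dt=1.0),
                                    integrate(cond, params)) == 0.0

    def test_preserves_linear_invariants_exactly(self):
        """Euler steps preserve the growth-free conservation sums exactly."""
        p = KineticParameters(psi_max=0.0, lambda_T=0.0, lambda_X=0.0)
        cond = ExperimentCondition("CUSTOM",
                                   PopulationState(r=100.0, n_D=5e5, n_R=5e5),
                                   duration=100.0, sampling_interval=20.0)
        traj = euler_oracle(cond, p, system="conjugation_only", dt=0.1)
        dx = traj.column("n_D") + traj.column("n_X")
        rt = traj.column("n_R") + traj.column("n_T")
        # preserved to rounding error (the update moves equal and opposite
        # fluxes between the paired compartments)
        assert np.allclose(dx, dx[0], rtol=1e-12)
        assert np.allclose(rt, rt[0], rtol=1e-12)

    def test_rejects_bad_dt(self, params):
        with pytest.raises(ValueError):
            euler_oracle(preset_condition("COND1", 0), params, dt=0.0)


class TestPresets:
    def test_presets_are_pure_functions(self):
        for label in ("COND1", "COND2A", "COND2B", "COND2C", "COND3"):
            for v in range(preset_variants(label)):
                a, b = preset_condition(label, v), preset_condition(label, v)
                assert a.to_dict() == b.to_dict()

    def test_cond1_one_to_one_split(self):
        c = preset_condition("COND1", "1:1")
        assert c.initial_state.n_D == c.initial_state.n_R == 5e5
        assert c.initial_state.r == 100.0
        assert c.initial_state.n_P == 0.0

    def test_cond1_ratio_series_totals(self):
        for v, ratio in enumerate((0, 1, 10, 100, 1000)):
            s = preset_condition("COND1", v).initial_state
            assert s.n_D + s.n_R == pytest.approx(1e6)
            if ratio:
                assert s.n_R / s.n_D == pytest.approx(ratio)

    def test_cond2a_phage_inoculum(self):
        # 5 uL of a 1e11/mL stock into 50 mL
        s = preset_condition("COND2A", 0).initial_state
        assert s.n_P == pytest.approx(1e7)
        assert s.n_D == pytest.approx(3e7)

    def test_cond2b_dilution_series(self):
        for v in range(5):
            s = preset_condition("COND2B", v).initial_state
            assert s.n_D == pytest.approx(3e6)
            assert s.n_P == pytest.approx(1e8 * 10.0 ** (-v))

    def test_cond2c_preserves_saturated_ratio(self, params):
        s = preset_condition("COND2C", 0).initial_state
        assert s.n_P / s.n_I == pytest.approx(params.K_P / params.K)
        assert s.n_D == 0.0

    def test_cond3_is_cond1_plus_phage(self):
        c1 = preset_condition("COND1", 2).initial_state
        c3 = preset_condition("COND3", 2).initial_state
        assert (c3.n_D, c3.n_R) == (c1.n_D, c1.n_R)
        assert c3.n_P == 1e7

    def test_unknown_label_and_variant(self):
        with pytest.raises(ValueError):
            preset_condition("COND9")
        with pytest.raises(ValueError):
            preset_condition("COND2A", 7)
        with pytest.raises(ValueError):
            preset_condition("COND1", "2:1")


class TestTrajectory:
    def test_tsv_round_trip(self, tmp_path, cond1_donor_traj):
        path = tmp_path / "traj.tsv"
        cond1_donor_traj.write_tsv(path)
        back = Trajectory.read_tsv(path)
        assert np.allclose(back.y, cond1_donor_traj.y)
        assert np.array_equal(back.times, cond1_donor_traj.times)

    def test_cond1_row_count(self, cond1_donor_traj):
        assert cond1_donor_traj.times.size == 36  # 0..700 at 20-min sampling

    def test_state_lookup(self, cond1_donor_traj):
        s = cond1_donor_traj.state_at(0.0)
        assert s.n_D == 1e6
        with pytest.raises(KeyError):
            cond1_donor_traj.state_at(13.0)
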