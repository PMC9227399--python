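"""RK4 integration, the washout event, and the closed-form ZA oracle."""

import numpy as np
import pytest

import zaipp
from conftest import rand_za
from zaipp.simulator import (
    DEFAULT_STEP,
    IntegrationError,
    Trajectory,
    apply_medium_replacement,
    integrate_rk4,
    simulate_experiment,
    za_subsystem_closed_form,
)


class TestGenericRK4:
    def test_exponential_decay_against_closed_form(self):
        a = 0.011
        out = integrate_rk4(lambda t, y: -a * y, [25.0], [0.0, 24.0], step=0.01)
        assert out[-1, 0] == pytest.approx(25.0 * np.exp(-a * 24.0), rel=1e-9)

    def test_zero_rhs_is_constant(self):
        out = integrate_rk4(lambda t, y: 0.0 * y, [3.0, 4.0], np.linspace(0, 10, 11), step=0.07)
        assert np.all(out == [3.0, 4.0])

    def test_fourth_order_convergence(self):
        a, y0, T = 0.9, 25.0, 10.0
        exact = y0 * np.exp(-a * T)
        errs = []
        for h in (0.02, 0.01):
            out = integrate_rk4(lambda t, y: -a * y, [y0], [0.0, T], step=h)
            errs.append(abs(out[-1, 0] - exact))
        ratio = errs[0] / errs[1]
        assert 12.0 < ratio < 20.0  # halving the step cuts the error ~2^4

    def test_nonfinite_state_reports_failure_time(self):
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(IntegrationError) as err:
                integrate_rk4(lambda t, y: y**3, [5.0], [0.0, 2.0, 50.0], step=0.5)
        assert err.value.time <= 50.0

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            integrate_rk4(lambda t, y: -y, [1.0], [0.0, 0.0], step=0.1)
        with pytest.raises(ValueError):
            integrate_rk4(lambda t, y: -y, [1.0], [0.0, 1.0], step=-0.1)


class TestClosedFormOracle:
    def test_triangular_case_formula(self):
        # kYZ = kXZ = 0 decouples Y; Z is an integral of Y
        za = zaipp.ZAKineticParams(kZY=0.3, kXY=0.1, kYZ=0.0, rhoZY=10.0, kXZ=0.0)
        Y0, t = 25.0, 7.0
        lam = za.kZY + za.kXY
        Y, Z = za_subsystem_closed_form(za, Y0, t)
        assert Y == pytest.approx(Y0 * np.exp(-lam * t), rel=1e-12)
        assert Z == pytest.approx(Y0 * za.rhoZY * za.kZY * (1 - np.exp(-lam * t)) / lam, rel=1e-12)

    def test_initial_condition(self):
        za = zaipp.ZAKineticParams(0.1, 0.2, 0.3, 5.0, 0.4)
        assert np.allclose(za_subsystem_closed_form(za, 25.0, 0.0), [25.0, 0.0])

    def test_rk4_agrees_on_fixture_parameters(self, m1_continuous):
        za, ag, design = m1_continuous
        traj = simulate_experiment(1, za, ag, design, step=0.01, dense=False)
        exact = za_subsystem_closed_form(za, design.Y0, 24.0)
        assert np.allclose(traj.state_at(24.0)[:2], exact, rtol=1e-6)


class TestMediumReplacement:
    def test_washout_to_zero(self, m1_pulse):
        za, _, design = m1_pulse
        post = apply_medium_replacement([18.3, 4.4, 7.0], za, design)
        assert post[0] == 0.0
        assert post[1] == 4.4 and post[2] == 7.0  # intracellular pool untouched

    def test_identity_when_residue_equals_pre(self, m1_pulse):
        _, _, design = m1_pulse
        za = zaipp.ZAKineticParams(0.6, 0.03, 18.0, 14.9, 0.0, Ystar_plus=18.3)
        post = apply_medium_replacement([18.3, 4.4, 7.0], za, design)
        assert np.allclose(post, [18.3, 4.4, 7.0])

    def test_usage_error_in_continuous_mode(self, m1_continuous):
        za, _, design = m1_continuous
        with pytest.raises(ValueError):
            apply_medium_replacement([1.0, 0.0, 0.0], za, design)


class TestSimulateExperiment:
    def test_continuous_ipp_accumulation_published(self, m1_continuous):
        za, ag, design = m1_continuous
        traj = simulate_experiment(1, za, ag, design)
        assert traj.state_at(24.0)[2] == pytest.approx(1460.0, rel=0.05)
        assert traj.state_at(48.0)[2] / ag.G0 == pytest.approx(130.0, rel=0.05)

    def test_no_drug_means_steady_state(self, m1_continuous, m2_continuous):
        for mid, (za, ag, design) in ((1, m1_continuous), (2, m2_continuous)):
            from dataclasses import replace

            d0 = replace(design, Y0=0.0)
            traj = simulate_experiment(mid, za, ag, d0, step=0.05)
            assert np.max(np.abs(traj.G - ag.G0)) <= 1e-9
            assert np.max(traj.Z) <= 1e-12

    def test_event_exactness_and_z_continuity(self, m1_pulse):
        za, ag, design = m1_pulse
        traj = simulate_experiment(1, za, ag, design)
        assert traj.state_at(design.t_star)[0] == 0.0  # Y jumps exactly to Y*+
        pre = traj.pre_event_state
        assert pre is not None and pre[0] > 0.0
        assert traj.state_at(design.t_star)[1] == pre[1]  # Z continuous across t*

    def test_refinement_stability_continuous(self, m1_continuous):
        za, ag, design = m1_continuous
        a = simulate_experiment(1, za, ag, design, step=DEFAULT_STEP, dense=False)
        b = simulate_experiment(1, za, ag, design, step=DEFAULT_STEP / 2, dense=False)
        sa = np.array([a.state_at(t) for t in design.sample_times if t > 0])
        sb = np.array([b.state_at(t) for t in design.sample_times if t > 0])
        assert np.allclose(sa, sb, rtol=1e-7, atol=1e-10)

    def test_refinement_stability_pulse(self, m1_pulse):
        # the pulse estimate kYZ = 18.06 /h makes the pre-washout transient
        # fast relative to the default step, so the bound is looser here
        za, ag, design = m1_pulse
        a = simulate_experiment(1, za, ag, design, step=DEFAULT_STEP, dense=False)
        b = simulate_experiment(1, za, ag, design, step=DEFAULT_STEP / 2, dense=False)
        sa = np.array([a.state_at(t) for t in design.sample_times if t > 0])
        sb = np.array([b.state_at(t) for t in design.sample_times if t > 0])
        assert np.allclose(sa, sb, rtol=1e-5, atol=1e-10)

    def test_pulse_never_exceeds_continuous_exposure(self, m1_pulse):
        from dataclasses import replace

        za, ag, design = m1_pulse
        pulse = simulate_experiment(1, za, ag, design)
        cont_design = replace(design, mode="continuous", t_star=None)
        cont = simulate_experiment(1, za, ag, cont_design)
        after = pulse.times >= design.t_star
        assert np.all(pulse.Z[after] <= cont.Z[after] + 1e-9)

    def test_enzyme_conservation_is_exact(self, m2_pulse):
        za, ag, design = m2_pulse
        traj = simulate_experiment(2, za, ag, design)
        assert np.all(traj.U + traj.B == 100.0)
        assert np.all(traj.B <= 100.0)

    def test_jitted_path_matches_generic_rk4(self, m2_continuous):
        za, ag, design = m2_continuous
        traj = simulate_experiment(2, za, ag, design, step=0.05, dense=False)

        def rhs(t, y):
            return zaipp.model2_rhs(np.maximum(y, 0.0), za, ag)

        grid = np.array([0.0] + [t for t in design.sample_times])
        ref = integrate_rk4(rhs, [design.Y0, 0.0, ag.G0, 0.0], grid, step=0.05)
        got = np.array([traj.state_at(t) for t in grid])
        assert np.allclose(got, ref, rtol=1e-12, atol=1e-12)

    def test_nonnegativity_on_random_parameters(self, m1_continuous):
        _, ag, design = m1_continuous
        rng = np.random.default_rng(11)
        for _ in range(25):
            za = rand_za(rng)
            traj = simulate_experiment(1, za, ag, design, step=0.01, dense=False)
            assert np.min(traj.states) >= 0.0


class TestTrajectoryContainer:
    def test_frame_round_trip(self, tmp_path, m2_continuous):
        za, ag, design = m2_continuous
        traj = simulate_experiment(2, za, ag, design, step=0.1, dense=False)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time_h,Y_uM,Z_pmol_per_mgprot,G_pmol_per_mgprot,B_pct,U_pct"

    def test_lookup_off_grid_fails(self, m1_continuous):
        za, ag, design = m1_continuous
        traj = simulate_experiment(1, za, ag, design, dense=False)
        with pytest.raises(KeyError):
            traj.state_at(2.5)

    def test_times_must_start_at_zero(self, m1_continuous):
        _, _, design = m1_continuous
        with pytest.raises(ValueError):
            Trajectory(np.array([1.0, 2.0]), np.zeros((2, 3)), 1, design)
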