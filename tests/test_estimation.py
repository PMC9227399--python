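"""Loss definition, simplex machinery, and parameter recovery behaviour."""

import numpy as np
import pandas as pd
import pytest

import zaipp
from conftest import fitspec_fixing, truth_dict
from zaipp.estimation import (
    PENALTY,
    FitSpec,
    _run_simplex,
    default_fitspec,
    fit,
    load_fitspec_file,
    loss,
    residuals,
)
from zaipp.synthetic import ObservationSet, generate_observations


def _truth_theta(spec, truth):
    return {n: truth[n] for n in spec.free_names}


class TestResidualsAndLoss:
    def test_noiseless_self_consistency(self, m1_continuous, noiseless_m1c_obs):
        za, ag, _ = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kZY", "rhoZY"), truth)
        r = residuals(_truth_theta(spec, truth), noiseless_m1c_obs, spec)
        assert np.max(np.abs(r)) < 1e-9
        assert loss(_truth_theta(spec, truth), noiseless_m1c_obs, spec) < 1e-18

    def test_single_observation_definition(self, m1_continuous):
        # shift one Z observation by +2 from the model value: residual (2), J = 4
        za, ag, design = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kZY",), truth)
        traj = zaipp.simulate_experiment(1, za, ag, design, dense=False)
        z_sim = traj.state_at(6.0)[1]
        obs = ObservationSet(
            pd.DataFrame({"time_h": [6.0], "Z_obs": [z_sim + 2.0], "G_obs": [np.nan]}), design
        )
        r = residuals(_truth_theta(spec, truth), obs, spec)
        assert r.shape == (1,)
        assert r[0] == pytest.approx(2.0, abs=1e-9)
        assert loss(_truth_theta(spec, truth), obs, spec) == pytest.approx(4.0, rel=1e-9)

    def test_loss_matches_bruteforce_formula(self, m1_continuous):
        # independent re-evaluation of sum_t (Z-ZS)^2 + (G-GS)^2 row by row
        za, ag, design = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kZY", "kXG"), truth)
        obs = generate_observations(1, za, ag, design, seed=3)
        theta = {"kZY": truth["kZY"] * 1.1, "kXG": truth["kXG"] * 0.9}
        full = spec.full_params(theta)
        za_t, ag_t = zaipp.params_from_dict(1, full)
        traj = zaipp.simulate_experiment(1, za_t, ag_t, design, step=spec.step, dense=False)
        brute = 0.0
        for _, row in obs.data.iterrows():
            s = traj.state_at(row.time_h)
            brute += (row.Z_obs - s[1]) ** 2 + (row.G_obs - s[2]) ** 2
        assert loss(theta, obs, spec) == pytest.approx(brute, rel=1e-12)

    def test_quadratic_homogeneity_and_permutation(self, m1_continuous):
        za, ag, design = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kZY",), truth)
        obs = generate_observations(1, za, ag, design, seed=4)
        theta = {"kZY": truth["kZY"] * 1.3}
        r = residuals(theta, obs, spec)
        assert np.sum((3.0 * r) ** 2) == pytest.approx(9.0 * np.sum(r**2), rel=1e-12)
        shuffled = ObservationSet(
            obs.data.sample(frac=1.0, random_state=1), obs.design
        )
        assert loss(theta, shuffled, spec) == pytest.approx(loss(theta, obs, spec), rel=1e-12)

    def test_residual_ordering_z_then_g(self, m1_continuous):
        za, ag, design = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kZY",), truth)
        traj = zaipp.simulate_experiment(1, za, ag, design, dense=False)
        df = pd.DataFrame(
            {
                "time_h": [3.0, 6.0],
                "Z_obs": [traj.state_at(3.0)[1] + 1.0, np.nan],
                "G_obs": [np.nan, traj.state_at(6.0)[2] + 5.0],
            }
        )
        r = residuals(_truth_theta(spec, truth), ObservationSet(df, design), spec)
        assert r == pytest.approx([1.0, 5.0], abs=1e-9)

    def test_penalty_on_unsimulatable_parameters(self, m1_continuous, noiseless_m1c_obs):
        za, ag, _ = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kYZ",), truth)
        val = loss({"kYZ": 1e9}, noiseless_m1c_obs, spec)  # blows up RK4 at h=0.01
        assert np.isfinite(val) and val >= PENALTY


class TestSimplexDriver:
    def test_quadratic_minimum_recovered(self):
        target = np.array([1.7, -0.3])

        def f(x):
            d = x - target
            return float(d @ d) + 2.0

        x, fval, ok = _run_simplex(f, np.zeros(2), budget=2000, xatol=1e-10, fatol=1e-12, n_restarts=3)
        assert ok
        assert np.allclose(x, target, atol=1e-6)
        assert fval == pytest.approx(2.0, abs=1e-10)


class TestFit:
    def test_start_at_optimum_stays_there(self, m1_continuous, noiseless_m1c_obs):
        za, ag, _ = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kZY", "rhoZY"), truth, max_iter=600, n_restarts=1, step=0.05)
        spec = FitSpec(
            1, spec.free_names, spec.fixed,
            init={n: truth[n] for n in spec.free_names},
            max_iter=600, n_restarts=1, step=0.05,
        )
        res = fit(noiseless_m1c_obs, spec)
        assert res.loss_value < 1e-8
        assert res.theta_hat["kZY"] == pytest.approx(truth["kZY"], rel=1e-3)

    def test_fixed_parameters_bit_identical(self, m1_continuous, noiseless_m1c_obs):
        za, ag, _ = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kZY", "rhoZY"), truth, max_iter=400, n_restarts=0, step=0.05)
        res = fit(noiseless_m1c_obs, spec)
        for name, value in spec.fixed.items():
            assert res.theta_hat[name] == value  # exact, not approx

    def test_reproducibility(self, m1_continuous):
        za, ag, design = m1_continuous
        truth = truth_dict(za, ag)
        obs = generate_observations(1, za, ag, design, seed=12)
        spec = fitspec_fixing(1, ("kZY", "kXG"), truth, max_iter=400, n_restarts=1, step=0.05)
        a = fit(obs, spec)
        b = fit(obs, spec)
        assert a.theta_hat == b.theta_hat and a.loss_value == b.loss_value

    def test_noisy_recovery_plausible_spread(self, m1_pulse):
        """Median relative error of kZY over replicate noisy fits stays in the
        range the asymptotic analysis makes plausible (same order as the
        published ~19% CV; simulation-derived bound)."""
        za, ag, design = m1_pulse
        truth = truth_dict(za, ag)
        free = ("kZY", "rhoZY", "kXGZ", "lambdaGZ")
        errs = []
        for seed in range(8):
            obs = generate_observations(1, za, ag, design, seed=seed)
            spec = fitspec_fixing(
                1, free, truth, max_iter=6000, n_restarts=2, step=0.02, normalize=True
            )
            res = fit(obs, spec)
            errs.append(abs(res.theta_hat["kZY"] - truth["kZY"]) / truth["kZY"])
        assert np.median(errs) < 0.30

    def test_empty_observations_rejected(self, m1_continuous):
        import pandas as pd

        za, ag, design = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kZY",), truth)
        empty = ObservationSet.__new__(ObservationSet)
        object.__setattr__(empty, "data", pd.DataFrame(columns=["time_h", "Z_obs", "G_obs"]))
        object.__setattr__(empty, "design", design)
        with pytest.raises(ValueError):
            fit(empty, spec)


class TestFitSpec:
    def test_validation(self, m1_continuous):
        za, ag, _ = m1_continuous
        truth = truth_dict(za, ag)
        with pytest.raises(ValueError, match="both free and fixed"):
            FitSpec(1, ("kZY",), dict(truth), {"kZY": 0.01})
        with pytest.raises(ValueError, match="cover"):
            FitSpec(1, ("kZY",), {}, {"kZY": 0.01})
        with pytest.raises(ValueError, match="init"):
            fixed = {n: truth[n] for n in truth if n not in ("kZY", "rhoZY")}
            FitSpec(1, ("kZY", "rhoZY"), fixed, {"kZY": 0.01})

    def test_default_fitspec_pins_paper_zeros(self, m1_pulse):
        za, ag, _ = m1_pulse
        truth = truth_dict(za, ag)
        spec = default_fitspec(1, "pulse", init={n: v or 0.1 for n, v in truth.items()})
        assert spec.fixed == {"kXZ": 0.0, "Ystar_plus": 0.0, "kXG": 0.0}
        spec_c = default_fitspec(1, "continuous", init={n: v or 0.1 for n, v in truth.items()})
        assert "kXG" in spec_c.free_names

    def test_toml_round_trip(self, tmp_path, m1_continuous):
        za, ag, _ = m1_continuous
        truth = truth_dict(za, ag)
        spec = fitspec_fixing(1, ("kZY", "rhoZY"), truth, normalize=True, max_iter=123)
        lines = ["model = 1", f"free = {list(spec.free_names)!r}".replace("'", '"'), "[init]"]
        lines += [f"{k} = {v}" for k, v in spec.init.items()]
        lines += ["[fixed]"] + [f"{k} = {v}" for k, v in spec.fixed.items()]
        lines += ["[controls]", "normalize = true", "max_iter = 123"]
        p = tmp_path / "spec.toml"
        p.write_text("\n".join(lines) + "\n")
        loaded = load_fitspec_file(p)
        assert loaded == spec
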