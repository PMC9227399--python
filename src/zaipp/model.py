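"""Model/Results front end tying estimation and identifiability together.

`KineticFitModel` is constructed from an observation set (the data) plus a
fit specification (what to estimate); `fit()` returns a
`KineticFitResults` carrying the estimates, their asymptotic
uncertainties, diagnostics and a `summary()` table, with simulation and
plotting hanging off the results object::

    za, ag, design = zaipp.scenario_truth("model1_continuous")
    obs = zaipp.generate_observations(1, za, ag, design, seed=7)
    spec = zaipp.default_fitspec(1, design.mode, init=...)
    res = zaipp.KineticFitModel(obs, spec).fit()
    print(res.summary())
    res.simulate().to_csv("fitted_trajectory.csv")
"""

from __future__ import annotations

from functools import cached_property

import numpy as np
import pandas as pd

from . import __about__
from .estimation import FitResult, FitSpec, fit as _fit, residuals
from .identifiability import IdentifiabilityReport, analyze_fit
from .kinetics import ExperimentDesign, derived_rates, params_from_dict
from .simulator import DEFAULT_STEP, Trajectory, simulate_experiment
from .synthetic import ObservationSet

__all__ = ["KineticFitModel", "KineticFitResults"]


class KineticFitModel:
    """One of the two ZA/IPP kinetic models bound to an observation set."""

    def __init__(self, observations: ObservationSet, spec: FitSpec):
        self.observations = observations
        self.spec = spec
        self.model_id = spec.model_id

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, design: ExperimentDesign, spec: FitSpec, provenance: str = ""
    ) -> "KineticFitModel":
        """Build from a (time_h, Z_obs, G_obs) DataFrame and a design."""
        return cls(ObservationSet(data, design, provenance=provenance), spec)

    def loglike_surface(self, theta) -> float:  # pragma: no cover - convenience
        from .estimation import loss

        return loss(theta, self.observations, self.spec)

    def fit(self) -> "KineticFitResults":
        """Estimate the free parameters by Nelder–Mead least squares."""
        return KineticFitResults(self, _fit(self.observations, self.spec))


class KineticFitResults:
    """Estimates, uncertainties and diagnostics from a kinetic-model fit."""

    def __init__(self, model: KineticFitModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result
        self.spec = fit_result.spec

    # -- estimates -----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Free-parameter estimates, in specification order."""
        return pd.Series(
            {n: self.fit_result.theta_hat[n] for n in self.spec.free_names}, name="estimate"
        )

    @property
    def theta_hat(self) -> dict[str, float]:
        """All model parameters (free estimates merged with fixed values)."""
        return dict(self.fit_result.theta_hat)

    @property
    def loss_value(self) -> float:
        return self.fit_result.loss_value

    @property
    def nobs(self) -> int:
        return self.fit_result.n_obs

    @property
    def df_resid(self) -> int:
        return self.fit_result.n_obs - self.fit_result.n_free

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @cached_property
    def derived(self) -> pd.Series:
        """The derived antigen rates (kG, kXGtot) at the estimate."""
        _, ag = params_from_dict(self.spec.model_id, self.fit_result.theta_hat)
        kG, kXGtot = derived_rates(ag)
        return pd.Series({"kG": kG, "kXGtot": kXGtot}, name="derived")

    # -- uncertainty ---------------------------------------------------
    @cached_property
    def identifiability(self) -> IdentifiabilityReport:
        return analyze_fit(self.fit_result, self.model.observations)

    @property
    def bse(self) -> pd.Series:
        """Asymptotic standard deviations of the free parameters."""
        return self.identifiability.table["SD"].rename("SD")

    @property
    def cv_percent(self) -> pd.Series:
        return self.identifiability.table["CV_pct"].rename("CV_pct")

    def conf_int(self) -> pd.DataFrame:
        """Normal 95 % confidence limits (LLC, ULC) per free parameter."""
        return self.identifiability.table[["LLC", "ULC"]]

    @property
    def corr_params(self) -> pd.DataFrame:
        return self.identifiability.correlation_matrix

    # -- diagnostics ---------------------------------------------------
    @cached_property
    def resid(self) -> np.ndarray:
        """Residual vector at the estimate (Z block then G block)."""
        theta = {n: self.fit_result.theta_hat[n] for n in self.spec.free_names}
        return residuals(theta, self.model.observations, self.spec)

    def simulate(self, design: ExperimentDesign | None = None, step: float = DEFAULT_STEP) -> Trajectory:
        """Forward-simulate the fitted model (dense grid for plotting)."""
        za, ag = params_from_dict(self.spec.model_id, self.fit_result.theta_hat)
        return simulate_experiment(
            self.spec.model_id, za, ag, design or self.model.observations.design, step=step
        )

    def plot_fit(self, ax=None):
        """Overlay the fitted trajectory on the observations."""
        import matplotlib.pyplot as plt

        traj = self.simulate()
        obs = self.model.observations.data
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(traj.times, traj.Z, color="tab:blue", label="Z fit")
        ax.plot(traj.times, traj.G, color="tab:green", label="G fit")
        ax.plot(obs["time_h"], obs["Z_obs"], "*", color="tab:blue", label="Z obs")
        ax.plot(obs["time_h"], obs["G_obs"], "o", mfc="none", color="tab:green", label="G obs")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("pmol/mgprot")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Human-readable fit summary: estimates, SD/CV%, 95 % limits."""
        ident = self.identifiability
        head = [
            f"zaipp {__about__.__version__} — Model {self.spec.model_id} "
            f"({self.model.observations.design.mode.value} protocol)",
            f"observations: {self.nobs} scalar values, free parameters: {self.fit_result.n_free}",
            f"loss J(theta_hat) = {self.loss_value:.6g}   s2 = {ident.s2:.6g}   "
            f"converged: {self.converged}",
            "",
        ]
        body = ident.to_text().splitlines()[1:]
        derived = self.derived
        tail = [
            "",
            f"derived: kG = {derived.kG:.4g} pmol/mgprot/h, kXGtot = {derived.kXGtot:.4g} /h",
        ]
        return "\n".join(head + body + tail)
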