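"""Ordinary least squares fitting of the kinetic models by Nelder–Mead.

The loss is the plain (unweighted) sum of squared residuals over the paired
ZA/IPP observations,

    J(θ) = Σ_t (Z_obs(t) − Z_sim(t))² + (G_obs(t) − G_sim(t))²,

minimised over the free parameters with a derivative-free simplex search.
Because the simplex is unconstrained, strictly positive parameters are
optimised on the log scale and parameters started at zero through a
soft-plus floor; parameters the data cannot inform (e.g. the within-cell
degradation rate kXZ, or the post-washout residue Y*+) are fixed at zero in
the default specifications rather than estimated.

An optional per-variable normalisation divides each variable's residuals by
that variable's observation SD.  The unnormalised loss is the default, but
it lets the IPP residuals (scale ~10³ pmol/mgprot in continuous dosing)
dominate the ZA residuals (~10²), so the normalised variant is the better
choice for recovery experiments on continuous-dosing data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .kinetics import param_names, params_from_dict
from .simulator import DEFAULT_STEP, IntegrationError, simulate_experiment
from .synthetic import ObservationSet

__all__ = [
    "FitSpec",
    "FitResult",
    "residuals",
    "loss",
    "fit",
    "default_fitspec",
    "load_fitspec_file",
]

#: Penalty returned for parameter vectors whose simulation fails, so the
#: simplex can retreat instead of crashing.
PENALTY = 1.0e12

_SOFTPLUS_FLOOR = 1e-8


@dataclass(frozen=True)
class FitSpec:
    """What to estimate and how.

    ``free_names`` orders the estimated parameters; ``fixed`` pins the
    rest; ``init`` supplies a starting value for every free parameter
    (mandatory — there are no silent defaults).  ``max_iter`` bounds the
    total number of function evaluations across the simplex restarts.
    """

    model_id: int
    free_names: tuple[str, ...]
    fixed: dict[str, float]
    init: dict[str, float]
    max_iter: int | None = None
    # absolute simplex tolerances: xatol acts on the log/soft-plus search
    # scale (so ~1e-10 relative); fatol must stay above the float64 eps-floor
    # of the loss magnitude or convergence can never be flagged
    xatol: float = 1e-10
    fatol: float = 1e-8
    n_restarts: int = 3
    step: float = DEFAULT_STEP
    normalize: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "free_names", tuple(self.free_names))
        universe = set(param_names(self.model_id))
        free = set(self.free_names)
        fixed = set(self.fixed)
        if free & fixed:
            raise ValueError(f"parameters both free and fixed: {sorted(free & fixed)}")
        if free | fixed != universe:
            missing = sorted(universe - free - fixed)
            extra = sorted((free | fixed) - universe)
            raise ValueError(f"free+fixed must cover the model parameters (missing {missing}, unknown {extra})")
        if set(self.init) < free:
            raise ValueError(f"init must cover all free parameters (missing {sorted(free - set(self.init))})")
        if any(v < 0 for v in self.init.values()):
            raise ValueError("initial values must be non-negative")

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def full_params(self, theta: Mapping[str, float]) -> dict[str, float]:
        """Merge free values with the fixed map into a complete parameter set."""
        missing = set(self.free_names) - set(theta)
        if missing:
            raise ValueError(f"theta lacks values for {sorted(missing)}")
        out = dict(self.fixed)
        out.update({n: float(theta[n]) for n in self.free_names})
        return out


@dataclass(frozen=True)
class FitResult:
    """Estimate, loss and bookkeeping from one least-squares fit.

    ``theta_hat`` maps every model parameter (free and fixed) to its value;
    fixed parameters are carried through bit-identically.
    """

    theta_hat: dict[str, float]
    loss_value: float
    n_obs: int
    n_free: int
    converged: bool
    n_evals: int
    spec: FitSpec
    trace: tuple[float, ...] | None = None

    def free_values(self) -> np.ndarray:
        return np.array([self.theta_hat[n] for n in self.spec.free_names])

    def to_json(self, path=None) -> str:
        doc = {
            "model_id": self.spec.model_id,
            "theta_hat": self.theta_hat,
            "loss_value": self.loss_value,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "converged": self.converged,
            "n_evals": self.n_evals,
            "free_names": list(self.spec.free_names),
            "fixed": self.spec.fixed,
            "controls": {
                "max_iter": self.spec.max_iter,
                "xatol": self.spec.xatol,
                "fatol": self.spec.fatol,
                "n_restarts": self.spec.n_restarts,
                "step": self.spec.step,
                "normalize": self.spec.normalize,
            },
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _simulate_at_obs(theta_full: dict[str, float], obs: ObservationSet, spec: FitSpec):
    za, ag = params_from_dict(spec.model_id, theta_full)
    design = obs.design.with_samples(tuple(np.unique(obs.times[obs.times > 0])))
    traj = simulate_experiment(spec.model_id, za, ag, design, step=spec.step, dense=False)
    sim = np.array([traj.state_at(t) for t in obs.times])
    return sim[:, 1], sim[:, 2]  # Z, G


def residuals(theta: Mapping[str, float], obs: ObservationSet, spec: FitSpec) -> np.ndarray:
    """Stacked residual vector: all Z residuals (ascending time), then all G.

    Missing observations contribute no entry.  Raises
    :class:`~zaipp.simulator.IntegrationError` if the trial parameters make
    the simulation fail; :func:`loss` converts that into a finite penalty.
    """
    full = spec.full_params(theta)
    Z_sim, G_sim = _simulate_at_obs(full, obs, spec)
    Z_obs = obs.data["Z_obs"].to_numpy(float)
    G_obs = obs.data["G_obs"].to_numpy(float)
    rz = (Z_obs - Z_sim)[~np.isnan(Z_obs)]
    rg = (G_obs - G_sim)[~np.isnan(G_obs)]
    return np.concatenate([rz, rg])


def _weights(obs: ObservationSet, spec: FitSpec) -> tuple[float, float]:
    if not spec.normalize:
        return 1.0, 1.0
    sZ = float(np.nanstd(obs.data["Z_obs"].to_numpy(float)))
    sG = float(np.nanstd(obs.data["G_obs"].to_numpy(float)))
    return (1.0 / sZ if sZ > 0 else 1.0), (1.0 / sG if sG > 0 else 1.0)


def loss(theta: Mapping[str, float], obs: ObservationSet, spec: FitSpec) -> float:
    """Sum-of-squares loss J(θ); finite penalty on simulation failure."""
    wZ, wG = _weights(obs, spec)
    try:
        full = spec.full_params(theta)
        Z_sim, G_sim = _simulate_at_obs(full, obs, spec)
    except (IntegrationError, FloatingPointError, OverflowError, ValueError):
        infeas = sum(max(0.0, -float(v)) for v in theta.values())
        return PENALTY + infeas
    Z_obs = obs.data["Z_obs"].to_numpy(float)
    G_obs = obs.data["G_obs"].to_numpy(float)
    rz = ((Z_obs - Z_sim)[~np.isnan(Z_obs)]) * wZ
    rg = ((G_obs - G_sim)[~np.isnan(G_obs)]) * wG
    val = float(rz @ rz + rg @ rg)
    return val if math.isfinite(val) else PENALTY


def _to_internal(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map non-negative parameter values to the unconstrained search scale.

    Positive values are optimised as logs; zeros through an inverse
    soft-plus at a small floor, which keeps the image non-negative while
    letting the simplex move freely.
    """
    is_log = values > 0
    x = np.empty_like(values)
    x[is_log] = np.log(values[is_log])
    floored = np.maximum(values[~is_log], _SOFTPLUS_FLOOR)
    x[~is_log] = np.log(np.expm1(floored))
    return x, is_log


def _from_internal(x: np.ndarray, is_log: np.ndarray) -> np.ndarray:
    v = np.empty_like(x)
    with np.errstate(over="ignore"):
        v[is_log] = np.exp(x[is_log])
        v[~is_log] = np.log1p(np.exp(x[~is_log]))
    return v


def _run_simplex(
    objective,
    x0: np.ndarray,
    *,
    budget: int,
    xatol: float,
    fatol: float,
    n_restarts: int,
) -> tuple[np.ndarray, float, bool]:
    """Restarted Nelder–Mead: each restart resumes from the best point found.

    ``budget`` bounds the total number of evaluations across all runs.
    Returns (best_x, best_f, last_run_converged); deterministic.
    """
    per_run = max(1, budget // (n_restarts + 1))
    best_x, best_f, converged = np.asarray(x0, float), float(objective(x0)), False
    x = best_x
    for _ in range(n_restarts + 1):
        res = minimize(
            objective,
            x,
            method="Nelder-Mead",
            options=dict(maxiter=per_run, maxfev=per_run, xatol=xatol, fatol=fatol, adaptive=True),
        )
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x.copy()
        converged = bool(res.success)
        x = best_x
    return best_x, best_f, converged


def fit(obs: ObservationSet, spec: FitSpec) -> FitResult:
    """Nelder–Mead least-squares estimation of the free parameters.

    The simplex is restarted ``spec.n_restarts`` times from the best point
    found so far to reduce stagnation; the result is deterministic given
    the observations, the starting values and the controls.
    """
    if obs.data.empty:
        raise ValueError("observation set is empty")
    free = spec.free_names
    x0_nat = np.array([spec.init[n] for n in free], dtype=float)
    x0, is_log = _to_internal(x0_nat)
    wrapped_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal wrapped_evals
        wrapped_evals += 1
        theta = dict(zip(free, _from_internal(x, is_log)))
        return loss(theta, obs, spec)

    total_budget = spec.max_iter if spec.max_iter is not None else 5000 * max(1, spec.n_free)
    best_x, best_f, converged = _run_simplex(
        objective, x0,
        budget=total_budget, xatol=spec.xatol, fatol=spec.fatol, n_restarts=spec.n_restarts,
    )
    theta_free = dict(zip(free, _from_internal(best_x, is_log)))
    theta_hat = spec.full_params(theta_free)
    return FitResult(
        theta_hat=theta_hat,
        loss_value=best_f,
        n_obs=obs.n_obs,
        n_free=spec.n_free,
        converged=converged,
        n_evals=wrapped_evals,
        spec=spec,
    )


def default_fitspec(
    model_id: int,
    mode: str,
    init: Mapping[str, float],
    **controls,
) -> FitSpec:
    """Standard fit specification for a model/protocol pair.

    Fixes the parameters the source analysis pins at zero — kXZ always,
    plus Y*+ and (for pulse protocols) the irreducible elimination kXG —
    and frees the rest.  ``init`` must cover the free parameters.
    """
    from .kinetics import ExperimentMode

    fixed: dict[str, float] = {"kXZ": 0.0, "Ystar_plus": 0.0}
    if ExperimentMode(mode) is ExperimentMode.PULSE:
        fixed["kXG"] = 0.0
    free = tuple(n for n in param_names(model_id) if n not in fixed)
    init = {n: float(init[n]) for n in free}
    return FitSpec(model_id=model_id, free_names=free, fixed=fixed, init=init, **controls)


def load_fitspec_file(path) -> FitSpec:
    """Load a fit specification from TOML.

    Layout: top-level ``model`` (1 or 2) and optional ``free`` list
    (defaults to every parameter present in ``[init]``), plus ``[init]``,
    ``[fixed]`` and optional ``[controls]`` tables::

        model = 1
        [init]
        kZY = 0.008
        ...
        [fixed]
        kXZ = 0.0
        [controls]
        normalize = true
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    model_id = int(doc["model"])
    init = {k: float(v) for k, v in doc.get("init", {}).items()}
    fixed = {k: float(v) for k, v in doc.get("fixed", {}).items()}
    free = tuple(doc.get("free", list(init)))
    controls = dict(doc.get("controls", {}))
    return FitSpec(model_id=model_id, free_names=free, fixed=fixed, init=init, **controls)
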