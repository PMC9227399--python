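"""Fixed-step RK4 simulation of the ZA/IPP models, with pulse washout.

The pulse experiment replaces the culture medium at ``t*`` (1 h in the
source experiments): the medium concentration Y jumps to ``Y*+`` while the
intracellular states are untouched.  The Dirac term of the medium equation
is realised as this instantaneous event between two integration phases —
no smoothing, no event detection, since the event time is known and forced
onto the integration grid.

The ZA subsystem (Y, Z) is linear between events; ``za_subsystem_closed_form``
provides the exact matrix-exponential solution used as an independent
oracle for the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

from . import _kernels
from .kinetics import (
    AgParams,
    ExperimentDesign,
    ExperimentMode,
    Model1AgParams,
    Model2AgParams,
    ZAKineticParams,
)

__all__ = [
    "DEFAULT_STEP",
    "DENSE_SPACING",
    "IntegrationError",
    "Trajectory",
    "integrate_rk4",
    "apply_medium_replacement",
    "simulate_experiment",
    "za_subsystem_closed_form",
]

#: Default RK4 step (h).  Small enough that the discretisation error is far
#: below measurement noise and the matrix-exponential oracle bound.
DEFAULT_STEP = 0.01

#: Spacing (h) of the dense output grid used for plotting.
DENSE_SPACING = 0.1

_NEG_TOL = 1e-12

_MODEL1_COLUMNS = ("Y_uM", "Z_pmol_per_mgprot", "G_pmol_per_mgprot")
_MODEL2_COLUMNS = _MODEL1_COLUMNS + ("B_pct", "U_pct")


class IntegrationError(RuntimeError):
    """Raised when the integration produces a non-finite or negative state.

    ``time`` carries the first grid time at which the failure was observed.
    """

    def __init__(self, message: str, time: float):
        super().__init__(f"{message} (t = {time:g} h)")
        self.time = time


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed model states on a recording grid.

    ``states`` holds one row per time: (Y, Z, G) for Model 1 and
    (Y, Z, G, B) for Model 2 (the algebraic U = 100 - B is derived on
    access).  For pulse designs the value stored at ``t_star`` is the
    post-washout state; the pre-washout state is kept separately in
    ``pre_event_state``.
    """

    times: np.ndarray
    states: np.ndarray
    model_id: int
    design: ExperimentDesign
    pre_event_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", x)
        if t.ndim != 1 or np.any(np.diff(t) <= 0) or (t.size and t[0] != 0.0):
            raise ValueError("times must be strictly increasing and start at 0")
        ncols = {1: 3, 2: 4}[self.model_id]
        if x.shape != (t.size, ncols):
            raise ValueError(f"states must have shape ({t.size}, {ncols})")

    @property
    def Y(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def Z(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def G(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def B(self) -> np.ndarray:
        if self.model_id != 2:
            raise AttributeError("B is only defined for Model 2")
        return self.states[:, 3]

    @property
    def U(self) -> np.ndarray:
        return _kernels.U0 - self.B

    def state_at(self, t: float) -> np.ndarray:
        """State at a recorded time ``t`` (exact grid lookup, no interpolation)."""
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=0.0, atol=1e-9))
        if idx.size == 0:
            raise KeyError(f"t = {t!r} h is not on the recording grid")
        return self.states[idx[0]]

    def at_sample_times(self) -> "Trajectory":
        """Restrict to the design's sample times (plus t=0 to keep the grid anchored)."""
        keep = np.isin(np.round(self.times, 9), np.round((0.0,) + self.design.sample_times, 9))
        return Trajectory(self.times[keep], self.states[keep], self.model_id, self.design, self.pre_event_state)

    def to_frame(self):
        import pandas as pd

        cols = _MODEL1_COLUMNS if self.model_id == 1 else _MODEL2_COLUMNS
        data = {"time_h": self.times}
        for j, c in enumerate(_MODEL1_COLUMNS):
            data[c] = self.states[:, j]
        if self.model_id == 2:
            data["B_pct"] = self.B
            data["U_pct"] = self.U
        return pd.DataFrame(data, columns=("time_h",) + cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        """Plot Y, Z and G against time on twin axes; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.Z, label="Z (intracellular ZA)", color="tab:blue")
        ax.plot(self.times, self.G, label="G (IPP)", color="tab:green")
        ax2 = ax.twinx()
        ax2.plot(self.times, self.Y, label="Y (medium ZA)", color="tab:orange", ls="--")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("pmol/mgprot")
        ax2.set_ylabel("μM")
        ax.legend(loc="upper left")
        return ax


def integrate_rk4(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    x0: Sequence[float],
    t_grid: Sequence[float],
    step: float,
) -> np.ndarray:
    """Classic fixed-step RK4 for an arbitrary right-hand side.

    Integrates from ``t_grid[0]`` and returns the state at every grid time
    (one row per time, including the initial one).  Within each inter-grid
    interval full steps of size ``step`` are taken and the final partial
    step is shortened so grid times are landed exactly.

    This generic path accepts any Python callable and is the reference
    implementation; ``simulate_experiment`` uses jitted kernels specialised
    to the two models and is tested to agree with it.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be non-empty and strictly increasing")
    y = np.asarray(x0, dtype=float).copy()
    out = np.empty((t_grid.size, y.size))
    out[0] = y
    t = t_grid[0]
    for k in range(1, t_grid.size):
        t1 = t_grid[k]
        while t < t1 - 1e-12:
            h = step if t + step <= t1 + 1e-12 else t1 - t
            k1 = rhs(t, y)
            k2 = rhs(t + 0.5 * h, y + 0.5 * h * np.asarray(k1))
            k3 = rhs(t + 0.5 * h, y + 0.5 * h * np.asarray(k2))
            k4 = rhs(t + h, y + h * np.asarray(k3))
            y = y + (h / 6.0) * (np.asarray(k1) + 2 * np.asarray(k2) + 2 * np.asarray(k3) + np.asarray(k4))
            t += h
        if not np.all(np.isfinite(y)):
            raise IntegrationError("non-finite state during integration", t1)
        out[k] = y
        t = t1
    return out


def apply_medium_replacement(
    state_pre: Sequence[float], za: ZAKineticParams, design: ExperimentDesign
) -> np.ndarray:
    """Instantaneous washout at t*: medium ZA jumps to Y*+, cells untouched."""
    if design.mode is not ExperimentMode.PULSE:
        raise ValueError("medium replacement is only defined for pulse experiments")
    state = np.asarray(state_pre, dtype=float).copy()
    state[0] = za.Ystar_plus
    return state


def _param_vector(model_id: int, za: ZAKineticParams, ag: AgParams) -> np.ndarray:
    if model_id == 1:
        if not isinstance(ag, Model1AgParams):
            raise TypeError("model_id=1 requires Model1AgParams")
        return np.array(
            [za.kZY, za.kXY, za.kYZ, za.rhoZY, za.kXZ, ag.kXG, ag.kXGZ, ag.lambdaGZ, ag.kG]
        )
    if model_id == 2:
        if not isinstance(ag, Model2AgParams):
            raise TypeError("model_id=2 requires Model2AgParams")
        return np.array(
            [za.kZY, za.kXY, za.kYZ, za.rhoZY, za.kXZ,
             ag.kXG, ag.kXGU, ag.lambdaUBG, ag.kBUZ, ag.kUBG, ag.kG]
        )
    raise ValueError(f"model_id must be 1 or 2, got {model_id!r}")


def _initial_state(model_id: int, design: ExperimentDesign, ag: AgParams) -> np.ndarray:
    y0 = [design.Y0, 0.0, ag.G0]
    if model_id == 2:
        y0.append(0.0)
    return np.array(y0)


def _check_states(times: np.ndarray, states: np.ndarray) -> None:
    bad = ~np.all(np.isfinite(states), axis=1)
    if np.any(bad):
        raise IntegrationError("non-finite state during integration", float(times[np.argmax(bad)]))
    neg = np.min(states, axis=1) < -_NEG_TOL
    if np.any(neg):
        t_bad = float(times[np.argmax(neg)])
        raise IntegrationError("state became negative beyond round-off tolerance", t_bad)


def _record_grid(design: ExperimentDesign, dense: bool) -> np.ndarray:
    nodes = {0.0, float(design.t_end)}
    nodes.update(design.sample_times)
    if design.mode is ExperimentMode.PULSE:
        nodes.add(float(design.t_star))
    if dense:
        nodes.update(np.arange(0.0, design.t_end, DENSE_SPACING))
    return np.unique(np.array(sorted(nodes)))


def simulate_experiment(
    model_id: int,
    za: ZAKineticParams,
    ag: AgParams,
    design: ExperimentDesign,
    step: float = DEFAULT_STEP,
    dense: bool = True,
) -> Trajectory:
    """Simulate one experiment and return the trajectory on the recording grid.

    The recording grid always contains t=0, the sample times, t_end and
    (for pulse designs) t*; with ``dense=True`` a 0.1 h plotting grid is
    added.  Pulse mode integrates to t*, applies the washout and continues;
    the stored state at t* is post-washout.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    p = _param_vector(model_id, za, ag)
    kernel = _kernels.integrate_model1 if model_id == 1 else _kernels.integrate_model2
    y0 = _initial_state(model_id, design, ag)
    grid = _record_grid(design, dense)

    pre_event = None
    if design.mode is ExperimentMode.PULSE:
        t_star = float(design.t_star)
        phase1 = grid[grid <= t_star + 1e-12]
        if not np.isclose(phase1[-1], t_star):
            raise RuntimeError("t_star missing from recording grid")
        s1 = kernel(p, y0, 0.0, phase1[1:], step) if phase1.size > 1 else np.empty((0, y0.size))
        s1 = np.vstack([y0, s1])
        _check_states(phase1, s1)
        pre_event = s1[-1].copy()
        y_post = apply_medium_replacement(pre_event, za, design)
        s1[-1] = y_post
        phase2 = grid[grid > t_star + 1e-12]
        s2 = kernel(p, y_post, t_star, phase2, step)
        _check_states(phase2, s2)
        states = np.vstack([s1, s2])
    else:
        states = kernel(p, y0, 0.0, grid[1:], step) if grid.size > 1 else np.empty((0, y0.size))
        states = np.vstack([y0, states])
        _check_states(grid, states)

    return Trajectory(grid, states, model_id, design, pre_event)


def za_subsystem_closed_form(
    za: ZAKineticParams, Y0: float, t: float | Sequence[float]
) -> np.ndarray:
    """Exact solution of the linear (Y, Z) subsystem via the matrix exponential.

    Valid between dosing events (the subsystem is autonomous and linear
    there).  Returns ``(Y, Z)`` at ``t``, or an array of shape (len(t), 2)
    for a sequence of times.  Handles repeated eigenvalues automatically
    (the matrix exponential is computed numerically, not by diagonalisation).
    """
    M = np.array(
        [
            [-(za.kZY + za.kXY), za.kYZ / za.rhoZY],
            [za.rhoZY * za.kZY, -(za.kXZ + za.kYZ)],
        ]
    )
    x0 = np.array([Y0, 0.0])
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.array([expm(M * tv) @ x0 for tv in ts])
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out
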