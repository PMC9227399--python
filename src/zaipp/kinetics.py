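"""State equations and parameter blocks for the two ZA/IPP kinetic models.

Both models share a linear two-compartment description of zoledronic acid
(ZA): ``Y`` is the ZA concentration in the culture medium (μM) and ``Z`` the
intracellular ZA concentration (pmol per mg of cellular protein).  The
antigen (isopentenyl pyrophosphate, IPP) concentration ``G`` is driven by a
constant production rate ``kG`` and an elimination rate that ZA suppresses:

Model 1 (3 ODEs)::

    dY/dt = -(kZY + kXY)·Y + (kYZ/ρZY)·Z
    dZ/dt = ρZY·kZY·Y - (kXZ + kYZ)·Z
    dG/dt = kG - [kXG + kXGZ·exp(-λGZ·Z)]·G

Model 2 (4 ODEs + 1 algebraic) replaces the phenomenological exponential by
explicit binding of ZA to farnesyl pyrophosphate synthase (FPPS), tracked as
bound/unbound enzyme percentages ``B`` and ``U = 100 - B``::

    dB/dt = kBUZ·Z·U - kUBG·exp(-λUBG·G)·B
    dG/dt = kG - (kXGU·U + kXG)·G

In both models the production rate is tied to an initial steady state,
``kG = kXGtot·G0``, with ``kXGtot = kXG + kXGZ`` (Model 1) or
``kXGtot = kXGU·U0 + kXG`` (Model 2); ``kG`` is always derived, never a free
parameter.

The back-transfer term in dY/dt is implemented as ``(kYZ/ρZY)·Z``: ρZY
(pmol/mgprot per μM) converts medium concentration to the intracellular
scale, so the cell→medium flux must divide by it to land back in μM/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence, Union

import numpy as np

__all__ = [
    "ExperimentMode",
    "ExperimentDesign",
    "ZAKineticParams",
    "Model1AgParams",
    "Model2AgParams",
    "model1_rhs",
    "model2_rhs",
    "derived_rates",
    "elimination_rate_limit",
    "MODEL1_PARAM_NAMES",
    "MODEL2_PARAM_NAMES",
    "param_names",
    "params_to_dict",
    "params_from_dict",
]

#: Full parameter-name universe per model: the ZA kinetic block followed by
#: the antigen block (kG and kXGtot are derived, never listed).
_ZA_NAMES = ("kZY", "kXY", "kYZ", "rhoZY", "kXZ", "Ystar_plus")
MODEL1_PARAM_NAMES = _ZA_NAMES + ("kXG", "kXGZ", "lambdaGZ", "G0")
MODEL2_PARAM_NAMES = _ZA_NAMES + ("kXG", "kXGU", "lambdaUBG", "kBUZ", "kUBG", "G0")


class ExperimentMode(str, Enum):
    """Dosing protocol: continuous exposure or a 1 h pulse with washout."""

    CONTINUOUS = "continuous"
    PULSE = "pulse"


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class ZAKineticParams:
    """Zoledronate kinetic parameters shared by both models.

    Attributes
    ----------
    kZY : float
        Medium → cell transfer rate (/h).
    kXY : float
        Medium ZA degradation rate (/h).
    kYZ : float
        Cell → medium transfer rate (/h).
    rhoZY : float
        Conversion factor from μM to pmol/mgprot (pmol/mgprot per μM).
    kXZ : float
        Within-cell ZA degradation rate (/h).
    Ystar_plus : float
        Medium ZA concentration (μM) immediately after the pulse washout;
        only meaningful for pulse experiments.
    """

    kZY: float
    kXY: float
    kYZ: float
    rhoZY: float
    kXZ: float = 0.0
    Ystar_plus: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kZY", "kXY", "kYZ", "kXZ", "Ystar_plus"):
            _check_nonneg(name, getattr(self, name))
        if self.rhoZY <= 0:
            raise ValueError(f"rhoZY must be positive, got {self.rhoZY!r}")


@dataclass(frozen=True)
class Model1AgParams:
    """Antigen (IPP) dynamics parameters for Model 1.

    ``kXG`` (/h) is the irreducible elimination rate that survives even at
    saturating intracellular ZA; ``kXGZ`` (/h) the suppressible part;
    ``lambdaGZ`` (per pmol/mgprot) the e-folding constant of suppression
    with Z; ``G0`` (pmol/mgprot) the initial antigen concentration.
    """

    kXG: float
    kXGZ: float
    lambdaGZ: float
    G0: float

    def __post_init__(self) -> None:
        for name in ("kXG", "kXGZ", "lambdaGZ", "G0"):
            _check_nonneg(name, getattr(self, name))

    @property
    def kXGtot(self) -> float:
        """Total baseline elimination rate kXG + kXGZ (/h)."""
        return self.kXG + self.kXGZ

    @property
    def kG(self) -> float:
        """Antigen production rate kXGtot·G0 (pmol/mgprot/h), fixed by the
        steady-state-at-t0 construction."""
        return self.kXGtot * self.G0


@dataclass(frozen=True)
class Model2AgParams:
    """Antigen and enzyme-binding parameters for Model 2.

    ``kXGU`` (/h per % unbound enzyme) scales antigen elimination with the
    unbound FPPS fraction; ``kBUZ`` (/h per pmol/mgprot) is the second-order
    bound-enzyme formation rate; ``kUBG`` (/h) the maximal dissociation
    rate, damped by exp(-λUBG·G); ``U0`` is fixed at 100 %.
    """

    kXG: float
    kXGU: float
    lambdaUBG: float
    kBUZ: float
    kUBG: float
    G0: float
    U0: float = 100.0

    def __post_init__(self) -> None:
        for name in ("kXG", "kXGU", "lambdaUBG", "kBUZ", "kUBG", "G0"):
            _check_nonneg(name, getattr(self, name))
        if self.U0 != 100.0:
            raise ValueError("U0 is fixed at 100 % in this formulation")

    @property
    def kXGtot(self) -> float:
        """Total baseline elimination rate kXGU·U0 + kXG (/h)."""
        return self.kXGU * self.U0 + self.kXG

    @property
    def kG(self) -> float:
        """Antigen production rate kXGtot·G0 (pmol/mgprot/h)."""
        return self.kXGtot * self.G0


AgParams = Union[Model1AgParams, Model2AgParams]


@dataclass(frozen=True)
class ExperimentDesign:
    """Dosing protocol and sampling grid for one in vitro experiment.

    ``t_star`` is the washout instant (h, pulse mode only) and ``Y0`` the
    initial medium ZA concentration (μM; 25 in the source experiments).
    """

    mode: ExperimentMode
    Y0: float
    t_end: float
    sample_times: tuple[float, ...]
    t_star: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ExperimentMode(self.mode))
        object.__setattr__(self, "sample_times", tuple(float(t) for t in self.sample_times))
        _check_nonneg("Y0", self.Y0)
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        ts = self.sample_times
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("sample_times must be strictly increasing")
        if ts and (ts[0] < 0 or ts[-1] > self.t_end):
            raise ValueError("sample_times must lie within [0, t_end]")
        if self.mode is ExperimentMode.PULSE:
            if self.t_star is None or not (0 < self.t_star < self.t_end):
                raise ValueError("pulse mode requires 0 < t_star < t_end")
        elif self.t_star is not None:
            raise ValueError("t_star is only meaningful in pulse mode")

    @property
    def chi_pulse(self) -> int:
        """Indicator distinguishing the experiment type (0 continuous, 1 pulse)."""
        return int(self.mode is ExperimentMode.PULSE)

    def with_samples(self, sample_times: Sequence[float]) -> "ExperimentDesign":
        return replace(self, sample_times=tuple(sample_times))


def _validate_state(state: Sequence[float], names: Sequence[str]) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (len(names),):
        raise ValueError(f"expected state of length {len(names)}, got shape {x.shape}")
    for name, v in zip(names, x):
        if v < 0:
            raise ValueError(f"state component {name} is negative ({v!r})")
    return x


def model1_rhs(state: Sequence[float], za: ZAKineticParams, ag: Model1AgParams) -> np.ndarray:
    """Smooth right-hand side d(Y, Z, G)/dt of Model 1.

    The pulse washout (Dirac term of the medium equation) is not part of
    this function; it is realised as a discrete event by the simulator.
    """
    Y, Z, G = _validate_state(state, ("Y", "Z", "G"))
    dY = -(za.kZY + za.kXY) * Y + (za.kYZ / za.rhoZY) * Z
    dZ = za.rhoZY * za.kZY * Y - (za.kXZ + za.kYZ) * Z
    dG = ag.kG - (ag.kXG + ag.kXGZ * math.exp(-ag.lambdaGZ * Z)) * G
    return np.array([dY, dZ, dG])


def model2_rhs(state: Sequence[float], za: ZAKineticParams, ag: Model2AgParams) -> np.ndarray:
    """Smooth right-hand side d(Y, Z, G, B)/dt of Model 2.

    The unbound enzyme percentage is eliminated algebraically,
    U = U0 - B, so the system is integrated as plain ODEs.
    """
    Y, Z, G, B = _validate_state(state, ("Y", "Z", "G", "B"))
    if B > ag.U0:
        raise ValueError(f"bound enzyme B={B!r} exceeds U0={ag.U0!r}")
    U = ag.U0 - B
    dY = -(za.kZY + za.kXY) * Y + (za.kYZ / za.rhoZY) * Z
    dZ = za.rhoZY * za.kZY * Y - (za.kXZ + za.kYZ) * Z
    dG = ag.kG - (ag.kXGU * U + ag.kXG) * G
    dB = ag.kBUZ * Z * U - ag.kUBG * math.exp(-ag.lambdaUBG * G) * B
    return np.array([dY, dZ, dG, dB])


def derived_rates(ag: AgParams) -> tuple[float, float]:
    """Return the derived pair (kG, kXGtot) for either antigen block."""
    return ag.kG, ag.kXGtot


def elimination_rate_limit(ag: Model1AgParams, Z: float) -> float:
    """Model 1 antigen elimination rate kXG + kXGZ·exp(-λGZ·Z) at a given
    intracellular ZA concentration Z.

    Non-increasing in Z: equals kXGtot at Z=0 and approaches the
    irreducible floor kXG as Z → ∞.
    """
    if Z < 0:
        raise ValueError("Z must be non-negative")
    return ag.kXG + ag.kXGZ * math.exp(-ag.lambdaGZ * Z)


def param_names(model_id: int) -> tuple[str, ...]:
    """Full (free + fixable) parameter-name universe for a model."""
    if model_id == 1:
        return MODEL1_PARAM_NAMES
    if model_id == 2:
        return MODEL2_PARAM_NAMES
    raise ValueError(f"model_id must be 1 or 2, got {model_id!r}")


def params_to_dict(za: ZAKineticParams, ag: AgParams) -> dict[str, float]:
    """Flatten parameter blocks into a name → value map (kG/kXGtot excluded)."""
    d = {n: getattr(za, n) for n in _ZA_NAMES}
    ag_names = MODEL1_PARAM_NAMES if isinstance(ag, Model1AgParams) else MODEL2_PARAM_NAMES
    d.update({n: getattr(ag, n) for n in ag_names[len(_ZA_NAMES):]})
    return d


def params_from_dict(model_id: int, values: dict[str, float]) -> tuple[ZAKineticParams, AgParams]:
    """Assemble (za, ag) blocks from a complete name → value map."""
    names = param_names(model_id)
    missing = sorted(set(names) - set(values))
    if missing:
        raise ValueError(f"missing parameter values for {missing}")
    za = ZAKineticParams(**{n: values[n] for n in _ZA_NAMES})
    ag_names = names[len(_ZA_NAMES):]
    ag_values = {n: values[n] for n in ag_names}
    ag: AgParams = Model1AgParams(**ag_values) if model_id == 1 else Model2AgParams(**ag_values)
    return za, ag
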