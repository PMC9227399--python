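"""Synthetic observation sets with the error structure the fit assumes.

The estimator assumes additive i.i.d. Gaussian measurement error on the
observed variables (intracellular ZA ``Z`` and IPP ``G``).  The generator
simulates the true trajectory for a scenario, samples it on a published
grid and adds independent N(0, σ²) noise per variable, truncating negative
draws to zero (concentrations) and recording how often truncation fired so
tests can require it to be negligible.

By default each variable gets its own σ, expressed as a fraction of that
variable's trajectory maximum (Z and G differ by an order of magnitude, so
a single pooled σ would drown the ZA data).  ``homoscedastic=True`` applies
one shared σ — the literal textbook assumption — computed from the larger
of the two maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import AgParams, ExperimentDesign, ZAKineticParams
from .simulator import DEFAULT_STEP, Trajectory, simulate_experiment

__all__ = ["DEFAULT_SIGMA_FRAC", "ObservationSet", "generate_observations"]

#: Default noise level: σ per variable as a fraction of its trajectory maximum.
DEFAULT_SIGMA_FRAC = 0.02


@dataclass(frozen=True)
class ObservationSet:
    """Sparse (time, Z_obs, G_obs) measurements for one experiment.

    ``data`` has columns ``time_h``, ``Z_obs``, ``G_obs``; missing values
    are NaN (at least one of the two must be present per row).  For
    generator output, ``sigma_Z``/``sigma_G`` record the noise SDs used and
    ``n_truncated`` how many negative draws were clipped to zero.
    """

    data: pd.DataFrame
    design: ExperimentDesign
    provenance: str = ""
    sigma_Z: float | None = None
    sigma_G: float | None = None
    n_truncated: int = 0

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in ("time_h", "Z_obs", "G_obs") if c not in df.columns]
        if missing:
            raise ValueError(f"observation table lacks columns {missing}")
        if df["time_h"].isna().any():
            raise ValueError("observation times must not be missing")
        t = df["time_h"].to_numpy(float)
        if np.any(t < 0) or np.any(t > self.design.t_end):
            raise ValueError("observation times must lie within [0, t_end]")
        if (df["Z_obs"].isna() & df["G_obs"].isna()).any():
            raise ValueError("each record needs at least one observed value")
        for c in ("Z_obs", "G_obs"):
            if (df[c].dropna() < 0).any():
                raise ValueError(f"{c} must be non-negative")
        object.__setattr__(self, "data", df)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(float)

    @property
    def n_obs(self) -> int:
        """Number of non-missing scalar observations (Z and G counted separately)."""
        return int(self.data[["Z_obs", "G_obs"]].notna().to_numpy().sum())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, design: ExperimentDesign, provenance: str | None = None) -> "ObservationSet":
        df = pd.read_csv(path)
        return cls(df, design, provenance=provenance or str(Path(path)))


def generate_observations(
    model_id: int,
    za: ZAKineticParams,
    ag: AgParams,
    design: ExperimentDesign,
    sigma_Z: float | None = None,
    sigma_G: float | None = None,
    seed: int = 0,
    sigma_frac: float = DEFAULT_SIGMA_FRAC,
    homoscedastic: bool = False,
    step: float = DEFAULT_STEP,
    provenance: str = "",
) -> ObservationSet:
    """Simulate the true trajectory and add Gaussian measurement noise.

    ``sigma_Z``/``sigma_G`` override the defaults; otherwise each is
    ``sigma_frac`` × the variable's maximum over the sampled trajectory
    (or, with ``homoscedastic=True``, one shared σ from the larger
    maximum).  Negative draws are truncated to 0 and counted.  The output
    is deterministic given ``seed``.
    """
    traj: Trajectory = simulate_experiment(model_id, za, ag, design, step=step, dense=False)
    samples = np.array([traj.state_at(t) for t in design.sample_times])
    Z_true, G_true = samples[:, 1], samples[:, 2]

    if sigma_Z is None or sigma_G is None:
        if homoscedastic:
            shared = sigma_frac * max(Z_true.max(), G_true.max())
            sZ = sG = shared
        else:
            sZ = sigma_frac * Z_true.max()
            sG = sigma_frac * G_true.max()
        sigma_Z = sZ if sigma_Z is None else sigma_Z
        sigma_G = sG if sigma_G is None else sigma_G
    if sigma_Z < 0 or sigma_G < 0:
        raise ValueError("noise SDs must be non-negative")

    rng = np.random.default_rng(seed)
    Z_obs = Z_true + rng.normal(0.0, 1.0, Z_true.size) * sigma_Z
    G_obs = G_true + rng.normal(0.0, 1.0, G_true.size) * sigma_G
    n_trunc = int((Z_obs < 0).sum() + (G_obs < 0).sum())
    Z_obs = np.maximum(Z_obs, 0.0)
    G_obs = np.maximum(G_obs, 0.0)

    df = pd.DataFrame(
        {"time_h": np.asarray(design.sample_times, float), "Z_obs": Z_obs, "G_obs": G_obs}
    )
    label = provenance or f"synthetic model{model_id} {design.mode.value} seed={seed}"
    return ObservationSet(
        df, design, provenance=label, sigma_Z=float(sigma_Z), sigma_G=float(sigma_G), n_truncated=n_trunc
    )
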