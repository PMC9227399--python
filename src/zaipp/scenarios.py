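"""Parameter scenarios and the published sampling grids.

A *scenario* bundles a ZA kinetic block, an antigen block and an experiment
design, encoded as TOML with ``[za]``, ``[ag]`` and ``[design]`` sections.
Four scenarios encoding the published point estimates for the two models ×
two dosing protocols ship with the package; arbitrary scenario files can be
loaded with :func:`load_scenario_file`.

The sampling grids reproduce the two source assays: continuous sampling at
{1, 3, 6, 12, 18, 24, 48} h, pulse sampling at {0, 1, 3, 6, 12, 18, 24, 48} h
(MCF7) or {0, 4, 8, 12, 24, 42} h (T47D), all starting from 25 μM medium ZA
with washout at 1 h in pulse mode.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

from .kinetics import (
    AgParams,
    ExperimentDesign,
    ExperimentMode,
    Model1AgParams,
    Model2AgParams,
    ZAKineticParams,
)

__all__ = [
    "SCENARIO_NAMES",
    "GRID_NAMES",
    "scenario_truth",
    "paper_sampling_grid",
    "load_scenario_file",
]

SCENARIO_NAMES = (
    "model1_continuous",
    "model1_pulse",
    "model2_continuous",
    "model2_pulse",
)

GRID_NAMES = ("raikkonen_continuous", "raikkonen_pulse", "benzaid_pulse")

_GRIDS = {
    "raikkonen_continuous": dict(
        mode=ExperimentMode.CONTINUOUS,
        sample_times=(1.0, 3.0, 6.0, 12.0, 18.0, 24.0, 48.0),
    ),
    "raikkonen_pulse": dict(
        mode=ExperimentMode.PULSE,
        sample_times=(0.0, 1.0, 3.0, 6.0, 12.0, 18.0, 24.0, 48.0),
    ),
    "benzaid_pulse": dict(
        mode=ExperimentMode.PULSE,
        sample_times=(0.0, 4.0, 8.0, 12.0, 24.0, 42.0),
    ),
}

_Y0 = 25.0
_T_STAR = 1.0


def paper_sampling_grid(name: str) -> ExperimentDesign:
    """Experiment design with the sampling grid of one of the source assays."""
    try:
        spec = _GRIDS[name]
    except KeyError:
        raise ValueError(f"unknown grid {name!r}; choose from {GRID_NAMES}") from None
    mode = spec["mode"]
    samples = spec["sample_times"]
    return ExperimentDesign(
        mode=mode,
        Y0=_Y0,
        t_end=samples[-1],
        sample_times=samples,
        t_star=_T_STAR if mode is ExperimentMode.PULSE else None,
    )


def _parse_scenario(doc: dict) -> tuple[ZAKineticParams, AgParams, ExperimentDesign]:
    try:
        za_doc = dict(doc["za"])
        ag_doc = dict(doc["ag"])
        de_doc = dict(doc["design"])
    except KeyError as e:
        raise ValueError(f"scenario file is missing the {e.args[0]!r} section") from None
    za = ZAKineticParams(**za_doc)
    model_id = int(ag_doc.pop("model"))
    if model_id == 1:
        ag: AgParams = Model1AgParams(**ag_doc)
    elif model_id == 2:
        ag = Model2AgParams(**ag_doc)
    else:
        raise ValueError(f"ag.model must be 1 or 2, got {model_id!r}")
    design = ExperimentDesign(**de_doc)
    return za, ag, design


def load_scenario_file(path) -> tuple[ZAKineticParams, AgParams, ExperimentDesign]:
    """Load (za, ag, design) from a TOML scenario file."""
    with open(Path(path), "rb") as fh:
        return _parse_scenario(tomllib.load(fh))


def scenario_truth(name: str) -> tuple[ZAKineticParams, AgParams, ExperimentDesign]:
    """The packaged scenario ``name``, exactly as published.

    Returns the parameter blocks and the matching experiment design (the
    MCF7 sampling grid; the T47D pulse grid is available separately through
    :func:`paper_sampling_grid`).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    ref = resources.files("zaipp").joinpath("data", f"{name}.toml")
    with ref.open("rb") as fh:
        return _parse_scenario(tomllib.load(fh))


def model_id_of(ag: AgParams) -> int:
    """1 or 2 depending on the antigen block type."""
    return 1 if isinstance(ag, Model1AgParams) else 2
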