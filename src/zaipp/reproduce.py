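"""Recompute every desk-scale published quantity and compare.

Each target re-derives one number from the packaged scenarios — derived-rate
arithmetic, forward simulation of the continuous experiment, or
identifiability arithmetic — and checks it against the published value at a
stated tolerance: ±1 % for pure arithmetic (the inputs are printed rounded),
±5 % for quantities propagated through 24–48 h of simulated dynamics, and
±0.1 absolute for the half-life-derived decay rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from .identifiability import confidence_limits, cv_percent
from .kinetics import derived_rates
from .scenarios import scenario_truth
from .simulator import DEFAULT_STEP, simulate_experiment

__all__ = ["ReproductionRow", "reproduce", "render_rows", "TARGET_IDS"]

TOL_ARITH = 0.01   # relative, printed-input rounding
TOL_SIM = 0.05     # relative, simulation targets
TOL_DECAY = 0.1    # absolute, half-life-derived rate


@dataclass(frozen=True)
class ReproductionRow:
    target_id: str
    description: str
    published_value: float
    computed_value: float
    tolerance: float
    relative: bool
    status: str  # pass | fail | info

    @property
    def error(self) -> float:
        if self.relative:
            return abs(self.computed_value - self.published_value) / abs(self.published_value)
        return abs(self.computed_value - self.published_value)


def _row(target_id: str, description: str, published: float, computed: float, tol: float, relative: bool = True) -> ReproductionRow:
    err = abs(computed - published) / abs(published) if relative else abs(computed - published)
    return ReproductionRow(target_id, description, published, computed, tol, relative, "pass" if err <= tol else "fail")


def _model1_continuous_G(t: float, step: float = DEFAULT_STEP) -> float:
    za, ag, design = scenario_truth("model1_continuous")
    traj = simulate_experiment(1, za, ag, design, step=step, dense=False)
    return float(traj.state_at(t)[2])


def _derived(scenario: str) -> tuple[float, float]:
    _, ag, _ = scenario_truth(scenario)
    return derived_rates(ag)


def _builders() -> dict[str, Callable[[], ReproductionRow]]:
    b: dict[str, Callable[[], ReproductionRow]] = {}

    def add(tid: str, fn: Callable[[], ReproductionRow]) -> None:
        b[tid] = fn

    # forward simulation, Model 1 continuous
    add("ipp_24h_continuous", lambda: _row(
        "ipp_24h_continuous", "Model 1 continuous: IPP G(24 h) [pmol/mgprot]",
        1460.0, _model1_continuous_G(24.0), TOL_SIM))
    add("ipp_fold_48h_continuous", lambda: _row(
        "ipp_fold_48h_continuous", "Model 1 continuous: fold increase G(48)/G(0)",
        130.0, _model1_continuous_G(48.0) / scenario_truth("model1_continuous")[1].G0, TOL_SIM))
    add("ipp_fold_24h_continuous", lambda: _row(
        "ipp_fold_24h_continuous", "Model 1 continuous: fold increase G(24)/G(0)",
        115.0, _model1_continuous_G(24.0) / scenario_truth("model1_continuous")[1].G0, TOL_SIM))

    # derived-rate arithmetic
    derived_targets = [
        ("kxgtot_model1_continuous", "model1_continuous", 1, 13.35),
        ("kg_model1_continuous", "model1_continuous", 0, 169.7),
        ("kxgtot_model1_pulse", "model1_pulse", 1, 2.391),
        ("kg_model1_pulse", "model1_pulse", 0, 6.466),
        ("kxgtot_model2_continuous", "model2_continuous", 1, 5.181),
        ("kg_model2_continuous", "model2_continuous", 0, 141.7),
        ("kxgtot_model2_pulse", "model2_pulse", 1, 22.44),
        ("kg_model2_pulse", "model2_pulse", 0, 22.18),
    ]
    for tid, scen, idx, pub in derived_targets:
        what = "kXGtot [/h]" if idx == 1 else "kG [pmol/mgprot/h]"
        add(tid, lambda tid=tid, scen=scen, idx=idx, pub=pub, what=what: _row(
            tid, f"{scen}: derived {what}", pub, _derived(scen)[idx], TOL_ARITH))

    # identifiability arithmetic
    add("decay_rate_from_halflife", lambda: _row(
        "decay_rate_from_halflife",
        "spontaneous IPP decay rate from a 20 h half-life [%/h]",
        3.5, 100.0 * math.log(2.0) / 20.0, TOL_DECAY, relative=False))
    add("rhozy_llc", lambda: _row(
        "rhozy_llc", "rhoZY 95% lower limit from estimate 25.46, SD 4.922",
        15.81, confidence_limits(25.46, 4.922)[0], TOL_ARITH))
    add("rhozy_ulc", lambda: _row(
        "rhozy_ulc", "rhoZY 95% upper limit from estimate 25.46, SD 4.922",
        35.11, confidence_limits(25.46, 4.922)[1], TOL_ARITH))
    add("kxg_model2_llc", lambda: _row(
        "kxg_model2_llc", "Model 2 kXG 95% lower limit from estimate 0.081, SD 0.051",
        -0.019, confidence_limits(0.081, 0.051)[0], TOL_ARITH))
    add("kxg_model2_ulc", lambda: _row(
        "kxg_model2_ulc", "Model 2 kXG 95% upper limit from estimate 0.081, SD 0.051",
        0.181, confidence_limits(0.081, 0.051)[1], TOL_ARITH))
    add("cv_rhozy", lambda: _row(
        "cv_rhozy", "rhoZY CV% from estimate 25.46, SD 4.922",
        19.30, cv_percent(25.46, 4.922), TOL_ARITH))
    add("cv_kxgu", lambda: _row(
        "cv_kxgu", "kXGU CV% from estimate 0.051, SD 0.525",
        1029.0, cv_percent(0.051, 0.525), TOL_ARITH))
    return b


TARGET_IDS: tuple[str, ...] = tuple(_builders().keys())


def reproduce(targets: Sequence[str] | None = None) -> list[ReproductionRow]:
    """Recompute the selected targets (all by default) and return the rows."""
    builders = _builders()
    if targets is None:
        targets = list(builders)
    unknown = sorted(set(targets) - set(builders))
    if unknown:
        raise ValueError(f"unknown reproduction targets: {unknown}")
    return [builders[t]() for t in targets]


def render_rows(rows: Sequence[ReproductionRow], fmt: str = "text") -> str:
    """Render reproduction rows as text, JSON or CSV."""
    if fmt == "json":
        import json

        return json.dumps(
            {
                r.target_id: {
                    "description": r.description,
                    "published_value": r.published_value,
                    "computed_value": r.computed_value,
                    "tolerance": r.tolerance,
                    "relative": r.relative,
                    "status": r.status,
                }
                for r in rows
            },
            indent=2,
        )
    if fmt == "csv":
        lines = ["target_id,published_value,computed_value,tolerance,relative,status"]
        for r in rows:
            lines.append(
                f"{r.target_id},{r.published_value:.6g},{r.computed_value:.6g},{r.tolerance},{int(r.relative)},{r.status}"
            )
        return "\n".join(lines)
    if fmt == "text":
        w = max((len(r.target_id) for r in rows), default=10)
        lines = [f"{'target':<{w}}  {'published':>10}  {'computed':>10}  {'tol':>7}  status"]
        for r in rows:
            tol = f"{r.tolerance:.0%}" if r.relative else f"±{r.tolerance}"
            lines.append(
                f"{r.target_id:<{w}}  {r.published_value:>10.4g}  {r.computed_value:>10.4g}  {tol:>7}  {r.status}"
            )
        return "\n".join(lines)
    raise ValueError(f"unknown format {fmt!r}")
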