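"""A-posteriori (practical) identifiability from the asymptotic covariance.

With i.i.d. Gaussian errors, the covariance of the least-squares estimate
is approximated by V = s²(JᵀJ)⁻¹ where J is the N×q Jacobian of the
residual vector at the optimum and s² = S(θ̂)/(N − q) the residual
variance.  Per-parameter standard deviations, percent coefficients of
variation and normal 95 % confidence limits (±1.96·SD) follow, together
with the parameter correlation matrix used to flag near-collinear pairs —
the screening by which poorly separable parameters are excluded from the
analysis.

N counts every non-missing scalar observation (Z and G separately); q
counts free parameters only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult, FitSpec, residuals
from .simulator import IntegrationError
from .synthetic import ObservationSet

__all__ = [
    "Z95",
    "IdentifiabilityReport",
    "residual_jacobian",
    "asymptotic_covariance",
    "confidence_limits",
    "cv_percent",
    "analyze_fit",
]

#: Normal 95 % confidence multiplier.
Z95 = 1.96

DEFAULT_REL_STEP = 1e-6
_STEP_FLOOR = 1e-8

#: Pairwise |correlation| above which a parameter pair is flagged as
#: practically non-separable.
CORRELATION_THRESHOLD = 0.99


class SingularJacobianError(np.linalg.LinAlgError):
    """JᵀJ is numerically singular; carries the most collinear parameter pair."""

    def __init__(self, pair: tuple[str, str]):
        super().__init__(
            f"J'J is singular: parameters {pair[0]} and {pair[1]} are not separable "
            "from these data; fix or remove one of them"
        )
        self.pair = pair


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Per-parameter uncertainty table plus the correlation structure.

    ``table`` has one row per free parameter with columns
    ``estimate, SD, CV_pct, LLC, ULC``; ``excluded`` lists (name, reason)
    pairs for parameters left out of the table (fixed at zero, derived, or
    flagged as highly correlated).
    """

    table: pd.DataFrame
    s2: float
    N: int
    q: int
    correlation_matrix: pd.DataFrame
    condition_number: float
    excluded: tuple[tuple[str, str], ...] = ()

    def flagged_pairs(self, threshold: float = CORRELATION_THRESHOLD) -> list[tuple[str, str, float]]:
        """Parameter pairs whose |correlation| exceeds ``threshold``."""
        c = self.correlation_matrix
        out = []
        for i, a in enumerate(c.index):
            for j, b in enumerate(c.columns):
                if j > i and abs(c.iloc[i, j]) > threshold:
                    out.append((a, b, float(c.iloc[i, j])))
        return out

    def to_json(self, path=None) -> str:
        import json

        doc = {
            "N": self.N,
            "q": self.q,
            "s2": self.s2,
            "condition_number": self.condition_number,
            "table": {
                name: {k: (None if not np.isfinite(v) else float(v)) for k, v in row.items()}
                for name, row in self.table.to_dict(orient="index").items()
            },
            "correlation_matrix": self.correlation_matrix.round(12).to_dict(orient="index"),
            "excluded": [list(e) for e in self.excluded],
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        """Render the report as an aligned text table."""
        lines = [f"N = {self.N}, q = {self.q}, s2 = {self.s2:.6g}"]
        lines.append(f"{'parameter':<12}{'estimate':>12}{'SD':>12}{'CV%':>10}{'LLC':>12}{'ULC':>12}")
        for name, row in self.table.iterrows():
            cv = f"{row.CV_pct:.4g}" if np.isfinite(row.CV_pct) else "n/a"
            lines.append(
                f"{name:<12}{row.estimate:>12.4g}{row.SD:>12.4g}{cv:>10}{row.LLC:>12.4g}{row.ULC:>12.4g}"
            )
        for name, reason in self.excluded:
            lines.append(f"{name:<12}  excluded ({reason})")
        return "\n".join(lines)


def residual_jacobian(
    theta_hat: dict[str, float],
    obs: ObservationSet,
    spec: FitSpec,
    rel_step: float = DEFAULT_REL_STEP,
) -> np.ndarray:
    """N×q Jacobian of the residual vector by central finite differences.

    Steps are relative on the natural parameter scale,
    h_i = rel_step·max(|θ_i|, floor); columns follow ``spec.free_names``.
    If a perturbed simulation fails the step is halved once before giving up.
    """
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    theta = {n: float(theta_hat[n]) for n in spec.free_names}
    return _fd_jacobian(lambda th: residuals(th, obs, spec), theta, spec.free_names, rel_step)


def _fd_jacobian(resid_fn, theta: dict[str, float], names: Sequence[str], rel_step: float) -> np.ndarray:
    """Central finite differences of an arbitrary residual function."""
    base = np.asarray(resid_fn(theta), float)
    J = np.empty((base.size, len(names)))
    for j, name in enumerate(names):
        h = rel_step * max(abs(theta[name]), _STEP_FLOOR)
        for attempt in range(2):
            up = dict(theta, **{name: theta[name] + h})
            dn = dict(theta, **{name: max(theta[name] - h, 0.0)})
            try:
                r_up = np.asarray(resid_fn(up), float)
                r_dn = np.asarray(resid_fn(dn), float)
                break
            except IntegrationError:
                if attempt == 1:
                    raise
                h *= 0.5
        denom = up[name] - dn[name]
        J[:, j] = (r_up - r_dn) / denom
    return J


def _correlation_from(V: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.clip(np.diag(V), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = V / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr


def asymptotic_covariance(
    Jmat: np.ndarray, loss_value: float, N: int, q: int
) -> tuple[np.ndarray, float]:
    """V = s²(JᵀJ)⁻¹ with s² = S(θ̂)/(N−q); returns (V, s²).

    Raises :class:`SingularJacobianError` naming the most collinear column
    pair when JᵀJ is numerically singular.
    """
    if N <= q:
        raise ValueError(f"need N > q for the residual variance (N={N}, q={q})")
    JtJ = Jmat.T @ Jmat
    s2 = float(loss_value) / (N - q)
    try:
        JtJ_inv = np.linalg.inv(JtJ)
        if not np.all(np.isfinite(JtJ_inv)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        corr = _correlation_from(np.linalg.pinv(JtJ))
        tri = np.abs(np.triu(corr, k=1))
        i, j = np.unravel_index(np.argmax(tri), tri.shape)
        raise SingularJacobianError((f"column {i}", f"column {j}")) from None
    return s2 * JtJ_inv, s2


def confidence_limits(estimate: float, SD: float) -> tuple[float, float]:
    """Normal 95 % limits: estimate ± 1.96·SD."""
    if SD < 0:
        raise ValueError("SD must be non-negative")
    return estimate - Z95 * SD, estimate + Z95 * SD


def cv_percent(estimate: float, SD: float) -> float:
    """Percent coefficient of variation, 100·SD/|estimate|.

    Undefined (NaN) for a zero estimate — such parameters are fixed rather
    than reported.
    """
    if SD < 0:
        raise ValueError("SD must be non-negative")
    if SD == 0.0:
        return 0.0
    if estimate == 0.0:
        return float("nan")
    return 100.0 * SD / abs(estimate)


def analyze_fit(
    result: FitResult,
    obs: ObservationSet,
    rel_step: float = DEFAULT_REL_STEP,
    correlation_threshold: float = CORRELATION_THRESHOLD,
) -> IdentifiabilityReport:
    """Full a-posteriori identifiability report for a fit.

    Builds the residual Jacobian at θ̂, the asymptotic covariance, the
    per-parameter SD/CV%/confidence limits and the correlation matrix, and
    flags fixed-at-zero and highly correlated parameters in ``excluded``.
    """
    spec = result.spec
    theta = {n: result.theta_hat[n] for n in spec.free_names}
    # S(theta_hat) is recomputed from the unweighted residual vector so the
    # covariance stays consistent with J even when the fit minimised the
    # per-variable-normalized loss.
    r_hat = residuals(theta, obs, spec)
    J = residual_jacobian(result.theta_hat, obs, spec, rel_step=rel_step)
    N, q = result.n_obs, result.n_free
    V, s2 = asymptotic_covariance(J, float(r_hat @ r_hat), N, q)
    cond = float(np.linalg.cond(J.T @ J))
    names = list(spec.free_names)
    est = np.array([result.theta_hat[n] for n in names])
    sd = np.sqrt(np.clip(np.diag(V), 0.0, None))
    rows = []
    for e, s in zip(est, sd):
        llc, ulc = confidence_limits(e, s)
        rows.append((e, s, cv_percent(e, s), llc, ulc))
    table = pd.DataFrame(rows, index=names, columns=["estimate", "SD", "CV_pct", "LLC", "ULC"])
    corr = pd.DataFrame(_correlation_from(V), index=names, columns=names)

    excluded: list[tuple[str, str]] = []
    for name, value in spec.fixed.items():
        reason = "fixed_at_zero" if value == 0.0 else "determined"
        excluded.append((name, reason))
    flagged = set()
    for a, b, _ in IdentifiabilityReport(table, s2, N, q, corr, cond).flagged_pairs(correlation_threshold):
        flagged.update((a, b))
    for name in names:
        if name in flagged:
            excluded.append((name, "correlated"))
    return IdentifiabilityReport(
        table=table,
        s2=s2,
        N=N,
        q=q,
        correlation_matrix=corr,
        condition_number=cond,
        excluded=tuple(excluded),
    )
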