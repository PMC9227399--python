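"""Jitted fixed-step RK4 cores for the two kinetic models.

These kernels integrate the smooth right-hand sides between events and
record the state at a strictly increasing list of node times, landing each
node exactly by shortening the final partial step.  Dosing events (the
pulse washout) are applied by the caller between kernel invocations, so the
kernels themselves never see a discontinuity.

Parameter vector layouts (kG is the derived production rate):

* Model 1: ``[kZY, kXY, kYZ, rhoZY, kXZ, kXG, kXGZ, lambdaGZ, kG]``
* Model 2: ``[kZY, kXY, kYZ, rhoZY, kXZ, kXG, kXGU, lambdaUBG, kBUZ, kUBG, kG]``

Round-off undershoots larger than ``-1e-12`` (relative to the state scale)
are the caller's responsibility to reject; the kernels only clip values in
``(-1e-12, 0)`` to zero so that the exponential terms stay well defined.
"""

import numpy as np
from numba import njit

_NEG_TOL = 1e-12
U0 = 100.0


@njit(cache=True)
def _rhs1(y, p):
    kZY, kXY, kYZ, rho, kXZ, kXG, kXGZ, lGZ, kG = p
    Y, Z, G = y
    out = np.empty(3)
    out[0] = -(kZY + kXY) * Y + (kYZ / rho) * Z
    out[1] = rho * kZY * Y - (kXZ + kYZ) * Z
    out[2] = kG - (kXG + kXGZ * np.exp(-lGZ * Z)) * G
    return out


@njit(cache=True)
def _rhs2(y, p):
    kZY, kXY, kYZ, rho, kXZ, kXG, kXGU, lUBG, kBUZ, kUBG, kG = p
    Y, Z, G, B = y
    U = U0 - B
    out = np.empty(4)
    out[0] = -(kZY + kXY) * Y + (kYZ / rho) * Z
    out[1] = rho * kZY * Y - (kXZ + kYZ) * Z
    out[2] = kG - (kXGU * U + kXG) * G
    out[3] = kBUZ * Z * U - kUBG * np.exp(-lUBG * G) * B
    return out


@njit(cache=True)
def _clip_roundoff(y):
    for i in range(y.size):
        if -_NEG_TOL < y[i] < 0.0:
            y[i] = 0.0
    return y


@njit(cache=True)
def integrate_model1(p, y0, t0, nodes, step):
    """RK4 from ``t0`` recording states at ``nodes`` (ascending, >= t0)."""
    out = np.empty((nodes.size, 3))
    y = y0.copy()
    t = t0
    for k in range(nodes.size):
        t1 = nodes[k]
        while t < t1 - 1e-12:
            h = step if t + step <= t1 + 1e-12 else t1 - t
            k1 = _rhs1(y, p)
            k2 = _rhs1(_clip_roundoff(y + 0.5 * h * k1), p)
            k3 = _rhs1(_clip_roundoff(y + 0.5 * h * k2), p)
            k4 = _rhs1(_clip_roundoff(y + h * k3), p)
            y = _clip_roundoff(y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4))
            t += h
        out[k] = y
        t = t1
    return out


@njit(cache=True)
def integrate_model2(p, y0, t0, nodes, step):
    out = np.empty((nodes.size, 4))
    y = y0.copy()
    t = t0
    for k in range(nodes.size):
        t1 = nodes[k]
        while t < t1 - 1e-12:
            h = step if t + step <= t1 + 1e-12 else t1 - t
            k1 = _rhs2(y, p)
            k2 = _rhs2(_clip_roundoff(y + 0.5 * h * k1), p)
            k3 = _rhs2(_clip_roundoff(y + 0.5 * h * k2), p)
            k4 = _rhs2(_clip_roundoff(y + h * k3), p)
            y = _clip_roundoff(y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4))
            t += h
        out[k] = y
        t = t1
    return out
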