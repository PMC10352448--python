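"""Sampling-interval design for temporal effective-size estimation.

The per-generation drift rate ``Q = 1/(2*Ne_eq)`` is estimated by mapping
an estimate of ``Q(tau)`` through ``h(q) = 1 - (1-q)**(1/tau)``.  By the
delta method its standard deviation is proportional to

    sd_factor(tau) = (1/tau) * (1 - Q(tau))**(1/tau - 1),

with the proportionality constant sigma (the sampling noise of the raw
``Q(tau)`` estimate) left as a free scale.  The factor first decays like
``1/tau``, reaches a minimum at an interval length proportional to
``2*NeE``, and then grows — diverging at the existence boundary for the
forward and intermediate flavours.  This module computes the factor
curves, the optimal integer interval ``tau_opt``, the proportionality
constants ``d_opt`` (root of ``d + c*II_inf*exp(d) = 1``) and the
accuracy horizons ``tau_C``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .equilibrium import EquilibriumState, equilibrium_Q

__all__ = ["DesignCurve", "design_curve", "tau_opt", "d_opt", "tau_C"]


@dataclass(frozen=True)
class DesignCurve:
    """sd_factor over an integer grid of interval lengths.

    Grid points where ``Q(tau) >= 1`` (effective size no longer defined)
    carry ``sd_factor = inf``.
    """

    tau_grid: np.ndarray
    q_values: np.ndarray
    sd_factor: np.ndarray
    kind: str


def _sd_factor(tau: int, Q: float) -> float:
    if Q >= 1.0:
        return math.inf
    return (1.0 / tau) * (1.0 - Q) ** (1.0 / tau - 1.0)


def design_curve(
    state: EquilibriumState,
    II_tau: Callable[[int], float],
    kind: str,
    tau_max_scan: int,
) -> DesignCurve:
    """Evaluate the delta-method sd factor on ``tau = 1..tau_max_scan``."""
    taus = np.arange(1, int(tau_max_scan) + 1)
    q = np.empty(taus.shape)
    sd = np.empty(taus.shape)
    for j, t in enumerate(taus):
        t = int(t)
        q[j] = equilibrium_Q(state, II_tau(t), t, kind)
        sd[j] = _sd_factor(t, q[j])
    return DesignCurve(tau_grid=taus, q_values=q, sd_factor=sd, kind=kind)


def tau_opt(curve: DesignCurve) -> int:
    """Integer interval length minimizing the sd factor (smallest
    minimizer on ties)."""
    finite = np.isfinite(curve.sd_factor)
    if not finite.any():
        raise ValueError("sd factor is undefined on the whole grid")
    i = int(np.argmin(np.where(finite, curve.sd_factor, math.inf)))
    if i == len(curve.tau_grid) - 1 and finite[i]:
        raise ValueError(
            "sd factor still decreasing at the end of the grid; extend tau_max_scan"
        )
    return int(curve.tau_grid[i])


def d_opt(II_inf: float, kind: str) -> float:
    """Proportionality constant in ``tau_opt ~= d_opt * 2 * NeE``.

    Forward: root of ``d + II_inf*e**d = 1`` on (0, 1]; intermediate uses
    ``II_inf/2``; backward returns 1.  A negative ``II_inf`` (gene flow
    lengthens rather than shortens the usable horizon) returns 1 as well.
    """
    if kind == "backward" or kind == "GD":
        return 1.0
    if kind == "intermediate":
        c = II_inf / 2.0
    elif kind == "forward":
        c = II_inf
    else:
        raise ValueError(f"unknown effective-size kind {kind!r}")
    if c <= 0.0:
        return 1.0
    f = lambda d: d + c * math.exp(d) - 1.0
    if f(1.0) <= 0.0:
        return 1.0
    return float(brentq(f, 0.0, 1.0, xtol=1e-13, rtol=8.9e-16))


def tau_C(curve: DesignCurve, C: float) -> float:
    """Largest tau for which the sd factor has not yet reached ``C``:
    ``min{tau: sd_factor(tau) >= C} - 1``.  The factor starts at 1 for
    ``tau = 1`` and only exceeds ``C > 1`` past the curve minimum (or at
    the existence boundary, where it is infinite)."""
    if C <= 1.0:
        raise ValueError("C must exceed 1")
    hit = np.flatnonzero(curve.sd_factor >= C)
    if hit.size == 0:
        warnings.warn(
            f"sd factor never reaches C={C} on the grid; reporting infinity",
            stacklevel=2,
        )
        return math.inf
    return float(curve.tau_grid[hit[0]] - 1)
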