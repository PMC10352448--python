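"""Migration-drift-equilibrium analysis.

After many generations the pair-coancestry vector becomes proportional to
the leading (Perron) right eigenvector ``r`` of the recursion matrix
``A``, and every equilibrium quantity is a function of the leading
eigenvalue ``lambda`` — through the eigenvalue effective size
``NeE = 1/(2*(1-lambda))`` — and of ratios of the entries of ``r``:
the equilibrium fixation index, the equilibrium gene-flow term
``II_inf(tau)``, the four effective sizes of each weighting scheme, and
the maximal interval lengths over which the forward and intermediate
variance effective sizes remain defined.

Closed-form approximations for symmetric migration (island and circular
stepping-stone models), accurate under strong migration and large local
sizes, are provided alongside the exact eigen-based quantities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .effective_size import EffectiveSizeResult, ne_from_Q
from .model import (
    PopulationModel,
    make_island,
    reproductive_weights,
    validate_weights,
)
from .recursion import build_A

__all__ = [
    "EquilibriumState",
    "solve_equilibrium",
    "fst_eq",
    "fst_eq_approx",
    "ii_inf",
    "ii_inf_limit",
    "ii_inf_approx_symmetric",
    "ne_eq",
    "tau_max",
    "island_ne_v_eq",
    "TAU_SCAN_CAP",
]

TAU_SCAN_CAP = 10**7


@dataclass(frozen=True)
class EquilibriumState:
    """Leading eigenpair of A plus derived equilibrium quantities."""

    lam: float  # leading eigenvalue, in (0, 1)
    r: np.ndarray  # positive right eigenvector, unit sum, length s**2
    NeE: float  # eigenvalue effective size 1/(2*(1-lam))
    gamma: np.ndarray  # reproductive weights of B
    model: PopulationModel

    @property
    def s(self) -> int:
        return self.model.s

    def r_matrix(self) -> np.ndarray:
        return self.r.reshape(self.s, self.s)


def solve_equilibrium(model: PopulationModel) -> EquilibriumState:
    """Leading eigenpair of the order-``s**2`` recursion matrix.

    The Perron eigenvalue is real, simple and strictly dominant; the
    eigenvector is sign-fixed to positive entries and normalized to unit
    sum.  A dense solver is used up to order 400, a dominant-pair power
    iteration above.
    """
    A = build_A(model)
    n = A.shape[0]
    if n <= 400:
        ev, V = np.linalg.eig(A)
        i = int(np.argmax(ev.real - 1e6 * (np.abs(ev.imag) > 1e-10)))
        lam = ev[i]
        if abs(lam.imag) > 1e-10:
            raise ArithmeticError("leading eigenvalue is not real")
        lam = float(lam.real)
        r = V[:, i].real
    else:
        lam, r = _power_iteration(A)
    if not np.all(r > 0) and not np.all(r < 0):
        raise ArithmeticError("leading eigenvector is not single-signed")
    r = np.abs(r)
    r = r / r.sum()
    if not 0.0 < lam < 1.0:
        raise ArithmeticError(f"leading eigenvalue {lam} outside (0, 1)")
    return EquilibriumState(
        lam=lam,
        r=r,
        NeE=1.0 / (2.0 * (1.0 - lam)),
        gamma=reproductive_weights(model),
        model=model,
    )


def _power_iteration(A: np.ndarray, tol: float = 1e-12, maxiter: int = 10**5):
    v = np.ones(A.shape[0])
    v /= v.sum()
    lam = 0.0
    for _ in range(maxiter):
        w = A @ v
        lam_new = float(w.sum())
        w /= lam_new
        if np.max(np.abs(w - v)) < tol and abs(lam_new - lam) < tol:
            return lam_new, w
        v, lam = w, lam_new
    raise ArithmeticError("power iteration failed to converge")


def fst_eq(state: EquilibriumState, w) -> float:
    """Equilibrium fixation index for weights ``w`` (scale-invariant in r)."""
    w = validate_weights(w, state.s)
    if np.count_nonzero(w) < 2:
        raise ValueError("fixation index requires >=2 weighted subpopulations")
    R = state.r_matrix()
    den = float(w @ R @ w)
    return (den - float(w @ np.diag(R))) / den


def fst_eq_approx(eta, Nc: float, Ne: float, s: int) -> float:
    """Large-size strong-migration approximation to the equilibrium
    fixation index under reproductive weights and symmetric migration;
    ``eta`` are the eigenvalues of B with the unit eigenvalue first."""
    eta = np.sort(np.asarray(eta, dtype=float))[::-1]
    sub = eta[1:]
    if np.any(np.abs(sub) >= 1.0):
        raise ValueError("non-leading eigenvalues of B must have modulus < 1")
    mean_term = np.mean(sub**2 / (1.0 - sub**2))
    return (s - 1) / (2.0 * s) * (1.0 / Nc + mean_term / Ne)


def harmonic_size_island(m: float, Nc: float, Ne: float) -> float:
    """Harmonic average of census and effective sizes weighted by the
    migration parameter: ``1/Ntilde = (1-(1-m)^2)/Nc + (1-m)^2/Ne``."""
    return 1.0 / ((1.0 - (1.0 - m) ** 2) / Nc + (1.0 - m) ** 2 / Ne)


def fst_eq_approx_island(s: int, m: float, Nc: float, Ne: float) -> float:
    Ntilde = harmonic_size_island(m, Nc, Ne)
    return (s - 1) / (2.0 * s * Ntilde * (1.0 - (1.0 - m) ** 2))


def ii_inf(state: EquilibriumState, w, v, tau) -> float:
    """Exact equilibrium gene-flow term ``II_inf(tau)``.

    ``2*sum_{x,y} ((v B^tau)_x - w_x) w_y r_xy / sum_{x,y} w_x w_y r_xy``;
    for ``tau = math.inf`` the row ``v B^tau`` is replaced by the
    reproductive weights gamma.
    """
    w = validate_weights(w, state.s)
    v = validate_weights(v, state.s)
    R = state.r_matrix()
    den = float(w @ R @ w)
    if den == 0.0:
        raise ZeroDivisionError("weighted equilibrium gene diversity is zero")
    if tau is math.inf or tau == math.inf:
        vB = state.gamma
    else:
        tau = int(tau)
        if tau < 1:
            raise ValueError("tau must be >= 1 (or math.inf)")
        vB = v @ np.linalg.matrix_power(state.model.B, tau)
    return 2.0 * float((vB - w) @ R @ w) / den


def ii_inf_limit(state: EquilibriumState, w) -> float:
    """``lim_{tau->inf} II_inf(tau)`` for equal start/end weights ``w``."""
    return ii_inf(state, w, w, math.inf)


def ii_inf_approx_symmetric(model: PopulationModel, w, v, tau: int) -> float:
    """Strong-migration approximation of ``II_inf(tau)`` for symmetric B
    with equal local sizes, via the orthonormal eigenbasis of B."""
    B, s = model.B, model.s
    if not np.allclose(B, B.T, atol=1e-12):
        raise ValueError("approximation requires a symmetric migration matrix")
    if np.ptp(model.Nc) > 0 or np.ptp(model.Ne) > 0:
        raise ValueError("approximation requires equal local sizes")
    Nc, Ne = model.Nc[0], model.Ne[0]
    w = validate_weights(w, s)
    v = validate_weights(v, s)
    eta, L = np.linalg.eigh(B)
    order = np.argsort(eta)[::-1]
    eta, L = eta[order], L[:, order]
    kappa = w @ L
    rho = v @ L
    total = 0.0
    for i in range(1, s):
        e = eta[i]
        total += (
            kappa[i]
            * (kappa[i] - e**tau * rho[i])
            / (1.0 - e**2)
            * ((1.0 - e**2) / Nc + e**2 / Ne)
        )
    return float(total)


def ii_inf_approx_island(
    s: int, m: float, Nc: float, Ne: float, w, v, tau: int
) -> float:
    """Island-model shortcut of the symmetric approximation."""
    w = validate_weights(w, s)
    v = validate_weights(v, s)
    Ntilde = harmonic_size_island(m, Nc, Ne)
    num = float(w @ w) - 1.0 / s - (1.0 - m) ** tau * (float(w @ v) - 1.0 / s)
    return num / (Ntilde * (1.0 - (1.0 - m) ** 2))


def equilibrium_Q(state: EquilibriumState, II: float, tau: int, kind: str) -> float:
    """Q(tau) at equilibrium: drift part ``1 - lam**tau`` combined with the
    gene-flow term according to the effective-size flavour."""
    drift = 1.0 - state.lam**tau
    if kind == "GD":
        return drift
    if kind == "forward":
        return drift + II
    if kind == "intermediate":
        return (drift + II) / (1.0 + II / 2.0)
    if kind == "backward":
        return (drift + II) / (1.0 + II)
    raise ValueError(f"unknown effective-size kind {kind!r}")


def ne_eq(
    state: EquilibriumState,
    II_tau: Callable[[int], float],
    tau: int,
    kind: str,
) -> EffectiveSizeResult:
    """Equilibrium effective size of the requested flavour at interval
    length ``tau``; ``II_tau`` maps tau to the equilibrium gene-flow term
    (pass ``lambda t: 0.0`` for reproductive weights).

    The root ``(1 - Q)**(1/tau)`` is evaluated in log space where it is a
    pure product (gene-diversity and backward flavours, and any flavour
    with a vanishing gene-flow term), so very long intervals do not
    underflow through ``lam**tau``.
    """
    import math as _math

    tau = int(tau)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    lam = state.lam
    II = II_tau(tau)
    if abs(II) < 1e-14:
        II = 0.0
    Q = equilibrium_Q(state, II, tau, kind)
    log_lam = _math.log(lam)
    if kind == "GD" or II == 0.0:
        root = lam
    elif kind == "backward":
        root = _math.exp(log_lam - _math.log1p(II) / tau)
    else:
        # forward / intermediate involve a genuine subtraction; fall back
        # to the direct Q when the drift part has not underflowed
        lam_tau = _math.exp(tau * log_lam)
        if kind == "forward":
            base = lam_tau - II
            scale = 1.0
        else:
            base = lam_tau - II / 2.0
            scale = 1.0 + II / 2.0
        if base <= 0.0:
            return ne_from_Q(Q if Q > 1.0 or base < 0.0 else 1.0, tau, kind)
        root = (base / scale) ** (1.0 / tau)
    if root >= 1.0:
        return ne_from_Q(min(Q, 0.0), tau, kind)
    value = 1.0 / (2.0 * (1.0 - root))
    additive = tau / (2.0 * Q) if Q > 0.0 else _math.inf
    return EffectiveSizeResult(value, "finite", kind, tau, Q, additive)


def tau_max(
    state: EquilibriumState,
    II_tau: Callable[[int], float],
    kind: str,
    w=None,
    approx: bool = False,
    cap: int = TAU_SCAN_CAP,
) -> float:
    """Longest interval over which the effective size of the given flavour
    remains defined at equilibrium.

    Gene-diversity and backward sizes exist for intervals of any length.
    For the forward (intermediate) size the exact mode returns the largest
    integer tau with ``lam**tau > II_inf(tau)`` (``> II_inf(tau)/2``),
    found by exponential bracketing plus integer bisection; the condition
    eventually fails monotonically since ``II_inf(tau)`` converges
    geometrically.  The approximate mode evaluates the closed forms
    ``log(1/II_inf)*2*NeE`` and ``log(2/II_inf)*2*NeE`` and needs ``w``.
    """
    if kind in ("GD", "backward"):
        return math.inf
    if kind not in ("forward", "intermediate"):
        raise ValueError(f"unknown effective-size kind {kind!r}")
    half = 2.0 if kind == "intermediate" else 1.0
    if approx:
        if w is None:
            raise ValueError("approximate tau_max needs the weight vector w")
        II_lim = ii_inf_limit(state, w)
        if II_lim <= 0.0:
            return math.inf
        return math.log(half / II_lim) * 2.0 * state.NeE

    def holds(t: int) -> bool:
        return state.lam**t > II_tau(t) / half

    if not holds(1):
        return 0.0
    lo = 1
    hi = 2
    while hi <= cap and holds(hi):
        lo, hi = hi, hi * 2
    if hi > cap:
        if II_tau(cap) > 1e-14:
            warnings.warn(
                f"existence condition still holds at the scan cap {cap}; "
                "reporting infinity",
                stacklevel=2,
            )
        return math.inf
    # invariant: holds(lo) and not holds(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if holds(mid):
            lo = mid
        else:
            hi = mid
    return lo


def make_ii_tau(state: EquilibriumState, w, v=None) -> Callable[[int], float]:
    """Memoized ``tau -> II_inf(tau)`` for fixed weights (island-agnostic)."""
    w = validate_weights(w, state.s)
    v = w if v is None else validate_weights(v, state.s)
    cache: dict[int, float] = {}

    def f(tau: int) -> float:
        tau = int(tau)
        if tau not in cache:
            cache[tau] = ii_inf(state, w, v, tau)
        return cache[tau]

    return f


def island_ne_v_eq(
    s: int,
    m: float,
    Nc: float,
    Ne: float,
    k: int,
    l: int,
    tau: int,
    kind: str = "forward",
) -> EffectiveSizeResult:
    """Closed-form island-model approximation of the equilibrium variance
    effective size when ``k`` subpopulations share weight ``1/k`` at both
    ends of the interval and ``l`` of them overlap.

    The gene-flow term uses the strong-migration island approximation, so
    the result is an approximation of the exact eigen-based size (accurate
    unless ``m`` is small).
    """
    if not (max(2 * k - s, 0) <= l <= k <= s) or k < 1:
        raise ValueError("need max(2k-s, 0) <= l <= k <= s with k >= 1")
    state = solve_equilibrium(make_island(s, m, Nc, Ne))
    Ntilde = harmonic_size_island(m, Nc, Ne)
    II = (1.0 / k - 1.0 / s - (1.0 - m) ** tau * (l / k**2 - 1.0 / s)) / (
        Ntilde * (1.0 - (1.0 - m) ** 2)
    )
    Q = equilibrium_Q(state, II, tau, kind)
    return ne_from_Q(Q, tau, kind)
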