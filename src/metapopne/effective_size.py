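"""Drift/gene-flow decomposition and the four two-time-point effective sizes.

Expected squared weighted allele-frequency change over an interval
``[t, t+tau]`` splits into a drift term ``I`` (the relative decline of
weighted gene diversity) and a gene-flow term ``II`` (minus twice the
standardized covariance between past and present frequency change, which
vanishes under reproductive weights).  Each effective-size flavour maps a
quantity ``Q(tau)`` onto the size of a Wright-Fisher population that loses
variation at the same rate:

* gene diversity:     Q = I
* forward variance:   Q = I + II
* intermediate:       Q = (I + II)/(1 + II/2)
* backward:           Q = (I + II)/(1 + II)

``Q <= 0`` means no net change (size infinite), ``Q = 1`` total loss
(size zero) and ``Q > 1`` an undefined size; these are encoded as status
codes rather than floating-point sentinels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import PopulationModel, validate_weights
from .recursion import CoancestryState

__all__ = [
    "KINDS",
    "DriftDecomposition",
    "EffectiveSizeResult",
    "drift_term_I",
    "gene_flow_term_II",
    "q_from_decomposition",
    "ne_from_Q",
    "effective_size",
]

KINDS = ("GD", "forward", "intermediate", "backward")


@dataclass(frozen=True)
class DriftDecomposition:
    """Drift term I, gene-flow term II and the standardized changes."""

    I: float
    II: float
    tau: int

    @property
    def F(self) -> float:
        return self.I + self.II

    @property
    def F_int(self) -> float:
        return (self.I + self.II) / (1.0 - self.I / 4.0 + self.II / 4.0)

    @property
    def F_back(self) -> float:
        if self.I >= 1.0:
            raise ZeroDivisionError("backward standardization requires I < 1")
        return (self.I + self.II) / (1.0 - self.I)


@dataclass(frozen=True)
class EffectiveSizeResult:
    """An effective size with existence status.

    ``status`` is 'finite' (0 < Q < 1), 'infinite' (Q <= 0), 'zero'
    (Q = 1) or 'undefined' (Q > 1).  ``value`` is the multiplicative
    size ``1/(2*(1-(1-Q)**(1/tau)))`` when finite, else ``nan``.
    ``additive_value`` is the short-interval approximation ``tau/(2*Q)``,
    defined whenever Q > 0.
    """

    value: float
    status: str
    kind: str
    tau: int
    Q: float
    additive_value: float

    @property
    def finite(self) -> bool:
        return self.status == "finite"


def drift_term_I(h_t: CoancestryState, h_t_tau: CoancestryState, w, v=None) -> float:
    """Relative decline of the weighted (pseudo-)gene diversity between the
    two states, computed directly on h vectors (which are proportional to
    gene diversities)."""
    if h_t.kind != "h" or h_t_tau.kind != "h":
        raise ValueError("drift term is computed from h states")
    if h_t.s != h_t_tau.s:
        raise ValueError("states must share the same number of subpopulations")
    w = validate_weights(w, h_t.s)
    v = w if v is None else validate_weights(v, h_t.s)
    den = float(w @ h_t.as_matrix() @ w)
    if den == 0.0:
        raise ZeroDivisionError("weighted gene diversity at time t is zero")
    num = den - float(v @ h_t_tau.as_matrix() @ v)
    return num / den


def gene_flow_term_II(
    h_t: CoancestryState, w, v, model: PopulationModel, tau: int
) -> float:
    """Gene-flow term ``2*sum_{x,y} ((v B^tau)_x - w_x) w_y h_txy / sum w w h``.

    Zero whenever ``w = v = gamma`` (reproductive weights), whenever all
    entries of ``h_t`` coincide (e.g. the founder generation), and under
    isolation with ``w = v``.
    """
    if h_t.kind != "h":
        raise ValueError("gene-flow term is computed from an h state")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    w = validate_weights(w, h_t.s)
    v = validate_weights(v, h_t.s)
    Hm = h_t.as_matrix()
    den = float(w @ Hm @ w)
    if den == 0.0:
        raise ZeroDivisionError("weighted gene diversity at time t is zero")
    vB = _row_times_matrix_power(v, model.B, tau)
    num = 2.0 * float((vB - w) @ Hm @ w)
    return num / den


def _row_times_matrix_power(v: np.ndarray, B: np.ndarray, tau: int) -> np.ndarray:
    # Row-vector product chain with repeated squaring of B for large tau.
    if tau <= 64:
        out = v
        for _ in range(tau):
            out = out @ B
        return out
    return v @ np.linalg.matrix_power(B, tau)


def q_from_decomposition(decomp: DriftDecomposition, kind: str) -> float:
    """The quantity Q(tau) for each effective-size flavour."""
    I, II = decomp.I, decomp.II
    if kind == "GD":
        return I
    if kind == "forward":
        return I + II
    if kind == "intermediate":
        return (I + II) / (1.0 + II / 2.0)
    if kind == "backward":
        return (I + II) / (1.0 + II)
    raise ValueError(f"unknown effective-size kind {kind!r}")


def ne_from_Q(Q: float, tau: int, kind: str = "GD") -> EffectiveSizeResult:
    """Invert ``Q = 1 - (1 - 1/(2*Ne))**tau`` with existence statuses."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    additive = tau / (2.0 * Q) if Q > 0.0 else math.inf
    if Q <= 0.0:
        return EffectiveSizeResult(math.nan, "infinite", kind, tau, Q, additive)
    if Q == 1.0:
        return EffectiveSizeResult(math.nan, "zero", kind, tau, Q, additive)
    if Q > 1.0:
        return EffectiveSizeResult(math.nan, "undefined", kind, tau, Q, additive)
    value = 1.0 / (2.0 * (1.0 - (1.0 - Q) ** (1.0 / tau)))
    return EffectiveSizeResult(value, "finite", kind, tau, Q, additive)


def effective_size(decomp: DriftDecomposition, kind: str) -> EffectiveSizeResult:
    """Effective size of the requested flavour from an (I, II) decomposition."""
    if kind == "backward" and decomp.I >= 1.0:
        # All diversity lost over the interval: the backward normalization
        # degenerates.
        return EffectiveSizeResult(
            math.nan, "undefined", kind, decomp.tau, math.inf, math.nan
        )
    return ne_from_Q(q_from_decomposition(decomp, kind), decomp.tau, kind)


def transient_decomposition(
    model: PopulationModel, T: int, tau: int, w, v=None
) -> DriftDecomposition:
    """Exact (I, II) over ``[t, t+tau]`` with the first sampling point ``T``
    generations past the founder, from the pair-coancestry recursions."""
    from .recursion import build_A, founder_state, iterate

    v_ = w if v is None else v
    A = build_A(model)
    h_t = iterate(founder_state(model, "h"), A, T)
    h_t_tau = iterate(h_t, A, tau)
    return DriftDecomposition(
        I=drift_term_I(h_t, h_t_tau, w, v_),
        II=gene_flow_term_II(h_t, w, v_, model, tau),
        tau=tau,
    )
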