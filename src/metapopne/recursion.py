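"""Transient recursions for coancestry, gene diversity and differentiation.

The genetic state of the metapopulation relative to a founder generation
(in which every subpopulation has allele frequency ``p``) is summarized by
a length-``s**2`` vector indexed by ordered subpopulation pairs (x, y):

* ``h``        -- one minus the standardized covariance of allele
                  frequency change between x and y (founder value 1);
* ``H``        -- the with-replacement gene diversity between x and y
                  (founder value ``2*p*(1-p)``), proportional to ``h``;
* ``H_tilde``  -- the without-replacement gene diversity.

``h`` and ``H`` evolve linearly under a matrix ``A`` of order ``s**2``
that combines local drift (census and effective sizes) with migration;
``H_tilde`` evolves under a companion matrix ``D`` that involves no census
sizes, which is why gene diversities are virtually census-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import PopulationModel, validate_weights

__all__ = [
    "CoancestryState",
    "founder_state",
    "build_A",
    "build_D",
    "iterate",
    "weighted_gene_diversity",
    "fst_transient",
]

# Ordered pairs (x, y) are laid out row-major: index(x, y) = x*s + y.


@dataclass(frozen=True)
class CoancestryState:
    """Pair-indexed recursion state at ``generations`` steps past the founder."""

    values: np.ndarray  # length s**2, row-major over ordered pairs
    generations: int
    kind: str  # 'h', 'H', or 'H_tilde'
    s: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.s * self.s,):
            raise ValueError("state length must be s**2")
        if self.kind not in ("h", "H", "H_tilde"):
            raise ValueError(f"unknown state kind {self.kind!r}")
        object.__setattr__(self, "values", v)

    def as_matrix(self) -> np.ndarray:
        return self.values.reshape(self.s, self.s)


def founder_state(model: PopulationModel, kind: str = "h", p: float = 0.5) -> CoancestryState:
    """State of the founder generation, in which all subpopulations share
    allele frequency ``p`` and all standardized covariances vanish."""
    s = model.s
    if kind == "h":
        v = np.ones(s * s)
    elif kind == "H":
        v = 2.0 * p * (1.0 - p) * np.ones(s * s)
    elif kind == "H_tilde":
        v = 2.0 * p * (1.0 - p) * np.ones((s, s))
        d = 2.0 * model.Nc / (2.0 * model.Nc - 1.0)
        v[np.diag_indices(s)] *= d
        v = v.ravel()
    else:
        raise ValueError(f"unknown state kind {kind!r}")
    return CoancestryState(values=v, generations=0, kind=kind, s=s)


def build_A(model: PopulationModel) -> np.ndarray:
    """Recursion matrix of order ``s**2`` for ``h`` and ``H`` states.

    Entry at row (x, y), column (z, u):
    ``(1 - 1/(2*Nc[x]))**[x==y] * B[x,z]*B[y,u]
      * ((1 - 1/(2*Ne[z]))/(1 - 1/(2*Nc[z])))**[z==u]``.
    """
    B, Nc, Ne, s = model.B, model.Nc, model.Ne, model.s
    A = np.einsum("xz,yu->xyzu", B, B)
    row = np.ones((s, s))
    row[np.diag_indices(s)] = 1.0 - 1.0 / (2.0 * Nc)
    col = np.ones((s, s))
    col[np.diag_indices(s)] = (1.0 - 1.0 / (2.0 * Ne)) / (1.0 - 1.0 / (2.0 * Nc))
    A *= row[:, :, None, None]
    A *= col[None, None, :, :]
    return A.reshape(s * s, s * s)


def build_D(model: PopulationModel) -> np.ndarray:
    """Recursion matrix for without-replacement gene diversities; contains
    effective sizes and migration rates but no census sizes."""
    B, Ne, s = model.B, model.Ne, model.s
    D = np.einsum("xz,yu->xyzu", B, B)
    col = np.ones((s, s))
    col[np.diag_indices(s)] = 1.0 - 1.0 / (2.0 * Ne)
    D *= col[None, None, :, :]
    return D.reshape(s * s, s * s)


def iterate(state: CoancestryState, matrix: np.ndarray, n: int) -> CoancestryState:
    """Advance the recursion ``n`` generations (repeated matrix-vector
    products; binary-power fast path for very long horizons)."""
    if n < 0:
        raise ValueError("cannot iterate a negative number of generations")
    if matrix.shape != (state.s**2, state.s**2):
        raise ValueError("matrix order does not match state")
    v = state.values
    if n > 10 * state.s**2:
        v = np.linalg.matrix_power(matrix, n) @ v
    else:
        for _ in range(n):
            v = matrix @ v
    return replace(state, values=v, generations=state.generations + n)


def weighted_gene_diversity(state: CoancestryState, w, v=None) -> float:
    """``sum_{x,y} w[x]*v[y]*state(x, y)``: the probability that two gene
    copies, drawn from subpopulations chosen with probabilities ``w`` and
    ``v``, carry different alleles (``v`` defaults to ``w``)."""
    if state.kind not in ("H", "H_tilde"):
        raise ValueError("weighted gene diversity is defined for H or H_tilde states")
    w = validate_weights(w, state.s)
    v = w if v is None else validate_weights(v, state.s)
    return float(w @ state.as_matrix() @ v)


def fst_transient(h_state: CoancestryState, w) -> float:
    """Predicted fixation index at the state's generation.

    ``(sum_{x,y} w_x w_y h_xy - sum_x w_x h_xx) / sum_{x,y} w_x w_y h_xy``.
    """
    if h_state.kind != "h":
        raise ValueError("fixation index is computed from an h state")
    w = validate_weights(w, h_state.s)
    if np.count_nonzero(w) < 2:
        raise ValueError("fixation index requires >=2 weighted subpopulations")
    Hm = h_state.as_matrix()
    den = float(w @ Hm @ w)
    if den == 0.0:
        raise ZeroDivisionError("fixation index denominator is zero (complete fixation)")
    num = den - float(w @ np.diag(Hm))
    return num / den
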