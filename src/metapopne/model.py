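"""Structured-population parameterizations.

A metapopulation is described by the number of subpopulations ``s``, an
irreducible row-stochastic backward migration matrix ``B`` (``B[x, z]`` is
the expected fraction of gene copies in subpopulation ``x`` whose parent
copy resided in ``z`` one generation earlier), per-subpopulation census
sizes ``Nc`` and per-subpopulation effective sizes under isolation ``Ne``
(diploid individuals).  Two canonical symmetric-migration models are
provided: the island model and the circular stepping-stone model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

__all__ = [
    "PopulationModel",
    "make_island",
    "make_circular_stepping_stone",
    "stepping_stone_eigenvalues",
    "reproductive_weights",
    "validate_weights",
    "uniform_weights",
    "local_weights",
]

_ROW_SUM_TOL = 1e-12
_WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PopulationModel:
    """A subdivided population with constant sizes and migration rates.

    Parameters
    ----------
    B : ndarray of shape (s, s)
        Backward migration matrix; rows sum to one, entries in [0, 1].
        Isolated or partially connected systems are allowed here;
        irreducibility (a single communicating class) is required — and
        checked — wherever uniqueness of the stationary structure
        matters (reproductive weights, equilibrium analysis).
    Nc : ndarray of shape (s,)
        Local census sizes, diploid individuals.  Accepted as reals >= 1;
        the analytic recursions only use ``1/(2*Nc)``.  The forward
        simulator additionally requires integer sizes.
    Ne : ndarray of shape (s,)
        Local effective sizes under isolation, ``1 <= Ne <= Nc``
        elementwise (the reproduction scheme draws ``2*Ne`` breeder
        copies without replacement out of ``2*Nc``).
    """

    B: np.ndarray
    Nc: np.ndarray
    Ne: np.ndarray
    s: int = field(init=False)

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1] or B.shape[0] < 1:
            raise ValueError("B must be a square matrix of order s >= 1")
        s = B.shape[0]
        Nc = np.broadcast_to(np.asarray(self.Nc, dtype=float), (s,)).copy()
        Ne = np.broadcast_to(np.asarray(self.Ne, dtype=float), (s,)).copy()
        if np.any(B < 0.0) or np.any(B > 1.0):
            raise ValueError("migration rates must lie in [0, 1]")
        if np.any(np.abs(B.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("every row of B must sum to 1")
        if np.any(Nc < 1.0) or np.any(Ne < 1.0):
            raise ValueError("local sizes must be >= 1 diploid individual")
        if np.any(Ne > Nc):
            raise ValueError("local effective sizes cannot exceed census sizes")
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "Nc", Nc)
        object.__setattr__(self, "Ne", Ne)
        object.__setattr__(self, "s", s)

    @property
    def has_integer_sizes(self) -> bool:
        return bool(
            np.all(self.Nc == np.round(self.Nc)) and np.all(self.Ne == np.round(self.Ne))
        )


def _check_irreducible(B: np.ndarray) -> None:
    # Support graph on strictly positive entries; B is user-specified so no
    # tolerance is applied.
    n, labels = connected_components(csr_matrix(B > 0), directed=True, connection="strong")
    if n > 1:
        classes = [np.flatnonzero(labels == k) + 1 for k in range(n)]
        raise ValueError(
            "migration matrix is reducible; communicating classes (1-based): "
            + ", ".join(str(list(c)) for c in classes)
        )


def make_island(s: int, m: float, Nc: float, Ne: float) -> PopulationModel:
    """Island model: ``B[x, z] = m/s`` off-diagonal, ``1-(s-1)*m/s`` on it.

    ``m`` is the fraction of offspring whose parents come from a global
    gene pool with equal contributions from all subpopulations (including
    the home one); the fraction of actual immigrant parents is
    ``m' = (s-1)*m/s``.
    """
    s = int(s)
    if s < 1:
        raise ValueError("island model needs s >= 1")
    if not 0.0 <= m <= 1.0:
        raise ValueError("migration parameter m must lie in [0, 1]")
    B = np.full((s, s), m / s)
    np.fill_diagonal(B, 1.0 - (s - 1) * m / s)
    return PopulationModel(B=B, Nc=np.full(s, float(Nc)), Ne=np.full(s, float(Ne)))


def make_circular_stepping_stone(s: int, m: float, Nc: float, Ne: float) -> PopulationModel:
    """Circular stepping-stone model: each deme draws ``m/2`` of its genes
    from each cyclic neighbour and keeps ``1-m``."""
    s = int(s)
    if s < 3:
        raise ValueError("circular stepping stone needs s >= 3")
    if not 0.0 <= m <= 1.0:
        raise ValueError("migration parameter m must lie in [0, 1]")
    B = np.zeros((s, s))
    np.fill_diagonal(B, 1.0 - m)
    for x in range(s):
        B[x, (x - 1) % s] += m / 2.0
        B[x, (x + 1) % s] += m / 2.0
    return PopulationModel(B=B, Nc=np.full(s, float(Nc)), Ne=np.full(s, float(Ne)))


def stepping_stone_eigenvalues(s: int, m: float) -> np.ndarray:
    """Closed-form eigenvalues of the circular stepping-stone matrix.

    The circulant symbol gives ``1 - m + m*cos(2*pi*j/s)`` for
    ``j = 0, ..., s-1``, with ``j`` and ``s-j`` coinciding.  Listing the
    spectrum in decreasing order, eigenvalue ``i`` (1-based) uses
    ``j = floor(i/2)``, so the leading eigenvalue is 1.
    """
    i = np.arange(1, s + 1)
    return 1.0 - m + m * np.cos(2.0 * np.pi * (i // 2) / s)


def reproductive_weights(model: PopulationModel) -> np.ndarray:
    """Stationary distribution gamma of B (``gamma @ B = gamma``).

    ``gamma[x]`` is the long-term fraction of ancestry contributed by
    subpopulation ``x``.  Solved as the singular linear system
    ``(B.T - I) @ gamma = 0`` with a unit-sum normalization row appended;
    uniqueness and positivity follow from irreducibility.
    """
    B = model.B
    s = model.s
    _check_irreducible(B)
    M = np.vstack([B.T - np.eye(s), np.ones((1, s))])
    rhs = np.zeros(s + 1)
    rhs[-1] = 1.0
    gamma, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    if np.any(gamma <= 0.0):
        raise ArithmeticError("stationary vector of B is not strictly positive")
    return gamma / gamma.sum()


def validate_weights(w, s: int) -> np.ndarray:
    """Validate a subpopulation weight vector: nonnegative, unit sum."""
    w = np.asarray(w, dtype=float)
    if w.shape != (s,):
        raise ValueError(f"weight vector must have length {s}, got shape {w.shape}")
    if np.any(w < 0.0):
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > _WEIGHT_SUM_TOL:
        raise ValueError("weights must sum to 1")
    return w


def uniform_weights(s: int) -> np.ndarray:
    return np.full(s, 1.0 / s)


def local_weights(s: int, x: int) -> np.ndarray:
    """Unit weight on subpopulation ``x`` (0-based)."""
    w = np.zeros(s)
    w[x] = 1.0
    return w
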