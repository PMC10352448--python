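"""Weighted temporal estimation of effective size from two-time-point data.

Given per-subpopulation sample allele frequencies at two time points tau
generations apart, subpopulation weight vectors pool them into one
metapopulation frequency per locus and time point.  The squared change,
standardized by the midpoint heterozygosity and pooled across loci as a
ratio of sums, yields the intermediate-flavour standardized change
``F_int``; inverting the Wright-Fisher decay law gives the intermediate
variance effective size.  Maximizing that estimate over the weight
simplex (same weights at both ends) estimates the eigenvalue effective
size of the metapopulation, and the maximizing weights estimate the
reproductive weights — without knowing any migration rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .effective_size import EffectiveSizeResult, ne_from_Q
from .model import validate_weights

__all__ = [
    "TemporalSample",
    "pooled_frequencies",
    "harmonic_sample_sizes",
    "estimate_ne_v_int",
    "maximize_over_weights",
]


@dataclass(frozen=True)
class TemporalSample:
    """Per-locus, per-subpopulation sample frequencies at two time points.

    ``p_t`` and ``p_t_tau`` have shape (L, s); entries may be NaN for a
    locus missing in some subpopulation at either time point, in which
    case the locus is dropped by the estimator.  Sample sizes are diploid
    individuals, either per subpopulation (shape (s,)) or per locus and
    subpopulation (shape (L, s)); locus-averaged values are used for the
    sampling correction.
    """

    p_t: np.ndarray
    p_t_tau: np.ndarray
    n_t: np.ndarray
    n_t_tau: np.ndarray
    tau: int

    def __post_init__(self) -> None:
        p1 = np.atleast_2d(np.asarray(self.p_t, dtype=float))
        p2 = np.atleast_2d(np.asarray(self.p_t_tau, dtype=float))
        if p1.shape != p2.shape:
            raise ValueError("frequency arrays must share shape (L, s)")
        if np.any(p1 < 0) or np.any(p1 > 1) or np.any(p2 < 0) or np.any(p2 > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        n1 = np.asarray(self.n_t, dtype=float)
        n2 = np.asarray(self.n_t_tau, dtype=float)
        if np.any(n1 <= 0) or np.any(n2 <= 0):
            raise ValueError("sample sizes must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        object.__setattr__(self, "p_t", p1)
        object.__setattr__(self, "p_t_tau", p2)
        object.__setattr__(self, "n_t", n1)
        object.__setattr__(self, "n_t_tau", n2)

    @property
    def L(self) -> int:
        return self.p_t.shape[0]

    @property
    def s(self) -> int:
        return self.p_t.shape[1]

    def mean_sizes(self) -> tuple[np.ndarray, np.ndarray]:
        """Locus-averaged per-subpopulation sample sizes."""
        n1 = self.n_t if self.n_t.ndim == 1 else self.n_t.mean(axis=0)
        n2 = self.n_t_tau if self.n_t_tau.ndim == 1 else self.n_t_tau.mean(axis=0)
        return n1, n2


def pooled_frequencies(sample: TemporalSample, w, v):
    """Per-locus pooled frequencies ``sum_x w_x p_txl`` and
    ``sum_x v_x p_(t+tau)xl``; loci with a missing frequency at either
    time point are dropped.  Returns ``(p_t, p_t_tau, n_dropped)``."""
    w = validate_weights(w, sample.s)
    v = validate_weights(v, sample.s)
    keep = ~(np.isnan(sample.p_t).any(axis=1) | np.isnan(sample.p_t_tau).any(axis=1))
    p1 = sample.p_t[keep] @ w
    p2 = sample.p_t_tau[keep] @ v
    return p1, p2, int((~keep).sum())


def harmonic_sample_sizes(n_by_subpop, weights) -> float:
    """Weight-squared harmonic pooled sample size ``1/sum_x w_x**2/n_x``,
    the homogeneous-sample size whose binomial variance matches that of
    the pooled frequency."""
    n = np.asarray(n_by_subpop, dtype=float)
    w = validate_weights(weights, len(n))
    used = w > 0
    if np.any(n[used] <= 0):
        raise ValueError("positive weight on a subpopulation with no sample")
    return float(1.0 / np.sum(w[used] ** 2 / n[used]))


def estimate_ne_v_int(
    sample: TemporalSample, w, v=None, correct_sampling: bool = False
) -> EffectiveSizeResult:
    """Intermediate variance effective size from pooled temporal data.

    ``F_int = sum_l (p2_l - p1_l)**2 / sum_l z_l*(1 - z_l)`` with
    ``z_l = (p1_l + p2_l)/2`` (ratio of sums across loci, stabilizing
    loci near fixation), then ``Ne`` solves
    ``1 - (1 - 1/(2*Ne))**tau = F_int / (1 + F_int/4)``.

    With ``correct_sampling`` the numerator subtracts the binomial
    sampling variance ``z_l*(1-z_l)*(1/(2*n_t) + 1/(2*n_t_tau))`` per
    locus, using weight-harmonic pooled sample sizes — an approximation
    to the full finite-sampling adjustment of the underlying estimator.
    """
    w = validate_weights(w, sample.s)
    v = w if v is None else validate_weights(v, sample.s)
    p1, p2, _ = pooled_frequencies(sample, w, v)
    if len(p1) == 0:
        raise ValueError("no loci present at both time points")
    z = (p1 + p2) / 2.0
    num = ((p2 - p1) ** 2).sum()
    den = (z * (1.0 - z)).sum()
    if den == 0.0:
        raise ZeroDivisionError("all loci fixed at both time points")
    if correct_sampling:
        n1_sub, n2_sub = sample.mean_sizes()
        n1 = harmonic_sample_sizes(n1_sub, w)
        n2 = harmonic_sample_sizes(n2_sub, v)
        num = num - (z * (1.0 - z)).sum() * (1.0 / (2.0 * n1) + 1.0 / (2.0 * n2))
    F_int = num / den
    Q = F_int / (1.0 + F_int / 4.0)
    return ne_from_Q(Q, sample.tau, "intermediate")


def _simplex_grid(s: int, steps: int):
    for combo in itertools.combinations(range(steps + s - 1), s - 1):
        parts = []
        prev = -1
        for c in combo:
            parts.append(c - prev - 1)
            prev = c
        parts.append(steps + s - 2 - prev)
        yield np.array(parts) / steps


def _entropy(w: np.ndarray) -> float:
    nz = w[w > 0]
    return float(-(nz * np.log(nz)).sum())


def maximize_over_weights(
    sample: TemporalSample,
    correct_sampling: bool = False,
    grid_steps: int = 12,
    refine: bool = True,
) -> tuple[np.ndarray, EffectiveSizeResult]:
    """Maximize the intermediate effective size over the weight simplex
    (same weights at both time points); the maximum estimates the
    eigenvalue effective size and the argmax the reproductive weights.

    Deterministic: a coarse simplex grid (step ``1/grid_steps``) is
    scanned, ties broken toward maximal entropy (closest to uniform),
    then the best point is refined with Nelder-Mead on softmax logits.
    Non-finite estimates count as -inf.
    """
    s = sample.s
    if s == 1:
        return np.ones(1), estimate_ne_v_int(sample, np.ones(1), correct_sampling=correct_sampling)

    def value(w: np.ndarray) -> float:
        try:
            res = estimate_ne_v_int(sample, w, correct_sampling=correct_sampling)
        except (ZeroDivisionError, ValueError):
            return -math.inf
        return res.value if res.finite else -math.inf

    best_w, best_val = None, -math.inf
    for w in _simplex_grid(s, grid_steps):
        val = value(w)
        if val > best_val + 1e-12 or (
            abs(val - best_val) <= 1e-12 and best_w is not None and _entropy(w) > _entropy(best_w)
        ):
            best_w, best_val = w, val
    if best_w is None or not np.isfinite(best_val):
        raise ArithmeticError(
            "no weight vector on the grid yields a finite effective size"
        )
    if refine:
        z0 = np.log(np.maximum(best_w, 1e-3))

        def neg(z):
            ez = np.exp(z - z.max())
            return -value(ez / ez.sum())

        opt = minimize(neg, z0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if np.isfinite(opt.fun) and -opt.fun > best_val:
            ez = np.exp(opt.x - opt.x.max())
            best_w = ez / ez.sum()
            best_val = -opt.fun
    best_w = np.where(best_w < 1e-12, 0.0, best_w)
    best_w = best_w / best_w.sum()
    return best_w, estimate_ne_v_int(sample, best_w, correct_sampling=correct_sampling)
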