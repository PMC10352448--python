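"""Forward-time Wright-Fisher metapopulation simulator.

Reproduction follows the migration-before-fertilization scheme with fixed
migrant proportions and fixed migrant allele frequencies: each generation,
every subpopulation x (i) draws ``2*Ne[x]`` breeder gene copies without
replacement from its ``2*Nc[x]`` copies (hypergeometric), (ii) mixes the
resulting infinite gene pools deterministically in proportions given by
the backward migration matrix, and (iii) samples ``2*Nc[x]`` new copies
binomially from the mixed pool.  Loci are independent replicates of this
single-marker process, all starting from a common founder frequency.

The module also builds, for tiny systems, the exact transition matrix of
the joint allele-count Markov chain, whose largest non-unit eigenvalue
equals the leading eigenvalue of the pair-coancestry recursion matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, hypergeom

from .model import PopulationModel, validate_weights

__all__ = [
    "SimulationConfig",
    "TrajectoryPanel",
    "step_generation",
    "simulate_panel",
    "empirical_terms",
    "EmpiricalTerms",
    "exact_chain",
    "EXACT_CHAIN_STATE_CAP",
]

EXACT_CHAIN_STATE_CAP = 5000


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for a synthetic two-time-point panel.

    ``burn_in_T`` generations elapse between the founder generation and
    the first sampling point t; the second sampling point is ``tau``
    generations later.  Loci that fix during burn-in are retained: the
    theory's expectations are over the unconditional process and dropping
    fixed loci would bias the empirical drift ratios.
    """

    model: PopulationModel
    founder_p: float = 0.5
    L: int = 1000
    burn_in_T: int = 0
    tau: int = 1
    seed: int | None = None
    extra_checkpoints: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 < self.founder_p < 1.0:
            raise ValueError("founder frequency must lie in (0, 1)")
        if self.L < 1:
            raise ValueError("need at least one locus")
        if self.burn_in_T < 0 or self.tau < 0:
            raise ValueError("burn_in_T and tau must be nonnegative")
        if not self.model.has_integer_sizes:
            raise ValueError("the simulator requires integer census/effective sizes")


@dataclass(frozen=True)
class TrajectoryPanel:
    """Allele-A frequencies at requested checkpoints.

    ``frequencies[k, x, l]`` is the frequency in subpopulation x at locus
    l at generation ``checkpoints[k]`` (generations since the founder).
    """

    frequencies: np.ndarray  # (n_checkpoints, s, L)
    checkpoints: tuple[int, ...]

    def at(self, generation: int) -> np.ndarray:
        k = self.checkpoints.index(generation)
        return self.frequencies[k]


def step_generation(
    counts: np.ndarray, model: PopulationModel, rng: np.random.Generator
) -> np.ndarray:
    """One generation of reproduction for allele-A copy counts.

    ``counts`` has shape (..., s) with ``counts[..., x]`` in
    ``{0, ..., 2*Nc[x]}``.  When ``Ne[x] == Nc[x]`` the breeder draw is
    the whole subpopulation and the hypergeometric step is an exact
    pass-through.
    """
    if not model.has_integer_sizes:
        raise ValueError("the simulator requires integer census/effective sizes")
    twoNc = (2 * model.Nc).astype(np.int64)
    twoNe = (2 * model.Ne).astype(np.int64)
    counts = np.asarray(counts)
    passthrough = twoNe == twoNc
    if passthrough.all():
        K = counts
    else:
        K = np.where(
            passthrough,
            counts,
            rng.hypergeometric(counts, twoNc - counts, twoNe),
        )
    q = K / twoNe
    q_post = q @ model.B.T
    return rng.binomial(twoNc, q_post)


def simulate_panel(config: SimulationConfig) -> TrajectoryPanel:
    """Simulate L independent loci and record the requested checkpoints.

    Checkpoints are ``burn_in_T`` (time point t), ``burn_in_T + tau``
    (time point t + tau) and any ``extra_checkpoints``.  The founder
    count ``round(2*Nc*p)`` must represent ``p`` exactly so that the
    founder condition of the recursions holds.
    """
    model = config.model
    twoNc = (2 * model.Nc).astype(np.int64)
    founder = np.round(twoNc * config.founder_p).astype(np.int64)
    if np.any(np.abs(founder - twoNc * config.founder_p) > 1e-9):
        raise ValueError("founder_p must be representable as a count in every deme")
    wanted = sorted(
        {config.burn_in_T, config.burn_in_T + config.tau, *config.extra_checkpoints}
    )
    rng = np.random.default_rng(config.seed)
    counts = np.tile(founder, (config.L, 1))  # (L, s)
    recorded = {}
    if wanted[0] == 0:
        recorded[0] = counts / twoNc
    for gen in range(1, wanted[-1] + 1):
        counts = step_generation(counts, model, rng)
        if gen in wanted:
            recorded[gen] = counts / twoNc
    freqs = np.stack([recorded[g].T for g in wanted])  # (k, s, L)
    return TrajectoryPanel(frequencies=freqs, checkpoints=tuple(wanted))


@dataclass(frozen=True)
class EmpiricalTerms:
    """Across-locus drift ratios from a simulated panel, with bootstrap SEs."""

    F: float
    F_int: float
    F_back: float
    I: float
    II: float  # F - I: the empirical gene-flow component
    se_F: float
    se_F_int: float
    se_F_back: float
    se_I: float
    se_II: float
    L: int


def empirical_terms(
    panel: TrajectoryPanel,
    w,
    v,
    t: int,
    tau: int,
    n_boot: int = 200,
    seed: int | None = None,
) -> EmpiricalTerms:
    """Empirical standardized squared frequency change between checkpoints.

    Pooled frequencies use weights ``w`` at t and ``v`` at ``t + tau``;
    each statistic is a ratio of across-locus averages, with standard
    errors from an across-locus bootstrap.
    """
    s = panel.frequencies.shape[1]
    w = validate_weights(w, s)
    v = validate_weights(v, s)
    p1 = w @ panel.at(t)  # (L,)
    p2 = v @ panel.at(t + tau)
    num = (p2 - p1) ** 2
    den_f = p1 * (1.0 - p1)
    z = (p1 + p2) / 2.0
    den_i = z * (1.0 - z)
    den_b = p2 * (1.0 - p2)
    if den_f.mean() == 0.0:
        raise ZeroDivisionError(
            "all loci fixed at time t; use more loci, larger sizes or shorter burn-in"
        )

    def ratios(idx):
        F = num[idx].mean() / den_f[idx].mean()
        I = (den_f[idx].mean() - den_b[idx].mean()) / den_f[idx].mean()
        return (
            F,
            num[idx].mean() / den_i[idx].mean(),
            num[idx].mean() / den_b[idx].mean(),
            I,
            F - I,
        )

    L = len(p1)
    full = ratios(slice(None))
    rng = np.random.default_rng(seed)
    boots = np.array([ratios(rng.integers(0, L, L)) for _ in range(n_boot)])
    se = boots.std(axis=0, ddof=1)
    return EmpiricalTerms(
        F=full[0],
        F_int=full[1],
        F_back=full[2],
        I=full[3],
        II=full[4],
        se_F=se[0],
        se_F_int=se[1],
        se_F_back=se[2],
        se_I=se[3],
        se_II=se[4],
        L=L,
    )


def exact_chain(model: PopulationModel) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Exact transition matrix of the joint allele-count Markov chain.

    States are tuples of per-subpopulation allele-A copy counts; the
    kernel composes the hypergeometric breeder draw, deterministic pool
    mixing and binomial fertilization.  Feasible only for tiny systems
    (state space ``prod(2*Nc[x] + 1) <= 5000``).
    """
    if not model.has_integer_sizes:
        raise ValueError("exact chain requires integer sizes")
    twoNc = (2 * model.Nc).astype(np.int64)
    twoNe = (2 * model.Ne).astype(np.int64)
    n_states = int(np.prod(twoNc + 1))
    if n_states > EXACT_CHAIN_STATE_CAP:
        raise ValueError(
            f"state space of size {n_states} exceeds the cap {EXACT_CHAIN_STATE_CAP}"
        )
    s = model.s
    states = list(itertools.product(*(range(n + 1) for n in twoNc)))
    # Per-subpop hypergeometric pmfs: hyp[x][c] is a vector over k = 0..2Ne[x]
    hyp = [
        [
            hypergeom.pmf(np.arange(twoNe[x] + 1), twoNc[x], c, twoNe[x])
            for c in range(twoNc[x] + 1)
        ]
        for x in range(s)
    ]
    P = np.zeros((n_states, n_states))
    k_space = list(itertools.product(*(range(n + 1) for n in twoNe)))
    for i, c in enumerate(states):
        for k in k_space:
            pk = 1.0
            for x in range(s):
                pk *= hyp[x][c[x]][k[x]]
            if pk == 0.0:
                continue
            q_post = model.B @ (np.array(k) / twoNe)
            # Independent binomial fertilization per subpop: the joint row
            # is the outer product of the per-subpop pmfs.
            row = np.array([1.0])
            for x in range(s):
                row = np.outer(row, binom.pmf(np.arange(twoNc[x] + 1), twoNc[x], q_post[x])).ravel()
            P[i] += pk * row
    return P, states
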