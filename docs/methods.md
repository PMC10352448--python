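# Methods

## The model

`metapopne` analyses a diploid metapopulation of `s` subpopulations with
non-overlapping generations and constant local census sizes `Nc_x` and
local effective sizes under isolation `Ne_x` (both in diploid
individuals, `1 <= Ne_x <= Nc_x`).  Gene flow is summarized by a
row-stochastic backward migration matrix `B`, where `B[x, z]` is the
expected fraction of gene copies in `x` whose parent copy lived in `z`
one generation earlier.  Reproduction follows the
migration-before-fertilization scheme with fixed migrant proportions and
allele frequencies: each generation, subpopulation `x` (1) draws `2*Ne_x`
breeder gene copies without replacement from its `2*Nc_x` copies and lets
them found an infinite pre-migration gene pool, (2) the pools mix
deterministically in proportions `B[x, :]`, and (3) `2*Nc_x` new copies
are sampled binomially from the mixed pool.  Mutation, selection, linkage
and any time variation of sizes or migration are outside the model.

Genetic state is tracked at a single biallelic marker whose founder
frequency `p` is shared by all subpopulations; multi-locus data are
treated as independent replicates of this process.  Two subpopulation
weight vectors `w` (start of the observation interval) and `v` (end)
pool local allele frequencies into one metapopulation frequency each.
Three weightings recur: local weights `e_x` (all mass on one deme),
uniform weights, and the reproductive weights `gamma` — the stationary
distribution of `B`, i.e. the long-run ancestry shares of the demes.

## Recursions

For each ordered pair `(x, y)` of subpopulations, `h_xy` denotes one
minus the standardized covariance of allele-frequency change (founder
value 1); the with-replacement gene diversity obeys
`H_xy = 2p(1-p) * h_xy` at every generation.  The length-`s^2` vector of
pair values evolves linearly, `h_{t+1} = A h_t`, with

    A[(x,y),(z,u)] = (1 - 1/(2*Nc_x))^{1(x=y)} * B[x,z] * B[y,u]
                     * ((1 - 1/(2*Ne_z)) / (1 - 1/(2*Nc_z)))^{1(z=u)} .

Without-replacement gene diversities follow the companion matrix `D`
that contains no census sizes, which is why gene diversities — and
everything built on the drift term below — are virtually independent of
the `Nc_x`.  Pairs are laid out row-major (`index(x, y) = x*s + y`,
0-based internally; reports are 1-based).  Iteration is by repeated
matrix-vector products, with a binary-power fast path for horizons
beyond `10*s^2` generations.

## Drift and gene flow

Expected squared pooled-frequency change over `[t, t+tau]`, standardized
by expected heterozygosity at `t`, decomposes as `F = I + II`:

* `I` — the relative decline of weighted gene diversity (drift term),
  `I = (w'h_t w - v'h_{t+tau} v) / (w'h_t w)`, always `<= 1`;
* `II` — the gene-flow term
  `II = 2 ((vB^tau - w)' h_t w) / (w' h_t w)`, minus twice the
  standardized covariance between past and present frequency change.
  It vanishes identically for reproductive weights (`gamma B = gamma`),
  at the founder generation, and under isolation with `w = v`.

Each effective size equates a quantity `Q(tau)` with the Wright-Fisher
decay `1 - (1 - 1/(2*Ne))^tau`: gene diversity uses `Q = I`, the forward
variance size `Q = I + II`, the intermediate `Q = (I+II)/(1+II/2)` and
the backward `Q = (I+II)/(1+II)`.  `Q <= 0`, `Q = 1` and `Q > 1` are
reported as the statuses `infinite`, `zero` and `undefined` rather than
numeric sentinels, and the additive short-interval approximation
`tau/(2Q)` is always reported alongside the multiplicative inversion.
For nonnegative `II` the sizes order as
`NeV <= NeV_int <= NeV_back <= NeGD`.

## Equilibrium

As the founder recedes (`T -> inf`) the pair vector aligns with the
Perron eigenvector `r` of `A`; every equilibrium quantity is a function
of the leading eigenvalue `lambda` — through the eigenvalue effective
size `NeE = 1/(2(1-lambda))` — and of ratios of `r`'s entries: the
equilibrium fixation index, the equilibrium gene-flow term
`II_inf(tau)` (with `vB^tau -> gamma` giving its `tau -> inf` limit
`II_inf`), and the four effective sizes per weighting.  The forward size
exists while `lambda^tau > II_inf(tau)` and the intermediate while
`lambda^tau > II_inf(tau)/2`; the largest such integers (`tau_max`) are
found by exponential bracketing plus integer bisection, capped at `1e7`
generations (beyond the cap infinity is reported, with a warning when
the gene-flow term is genuinely positive).  Closed-form approximations
`log(1/II_inf) * 2*NeE` and `log(2/II_inf) * 2*NeE` are exposed
separately, as are the strong-migration eigenbasis approximation of
`II_inf(tau)` for symmetric `B` and its island shortcut through the
harmonic size `1/Ntilde = (1-(1-m)^2)/Nc + (1-m)^2/Ne`.

Numerical choices: the eigenpair is obtained from a dense nonsymmetric
solver up to matrix order 400 and a power iteration (tolerance `1e-12`,
at most `1e5` sweeps) above; the Perron eigenvalue is required real
within `1e-10` and the eigenvector single-signed, then normalized to
unit sum (any normalization is equivalent; ratios are what matter).  In
`ne_eq` the root `(1-Q)^{1/tau}` is evaluated in log space wherever it
is a pure product (gene-diversity and backward flavours, and any flavour
with vanishing gene flow) so that `lambda^tau` cannot underflow at very
long horizons; an absolute threshold of `1e-14` treats a numerically
tiny `II` as zero.  The tau=1 tables are computed with the exact
eigen-based `II_inf(1)`, not the island approximation.

## Sampling design

An estimator of the per-generation drift rate `1/(2*Ne_eq)` built from an
estimate of `Q(tau)` has delta-method standard deviation proportional to
`sd_factor(tau) = (1/tau) (1 - Q(tau))^{1/tau - 1}`; the sampling noise
scale sigma multiplies everything and is taken as given (modeling it as
a function of marker count and sample sizes is out of scope).  The
factor decays like `1/tau`, bottoms out near `2*NeE`, and diverges at
the existence boundary for the forward and intermediate flavours.
`tau_opt` is the exhaustive integer argmin over the computed grid
(smallest minimizer on ties — this convention reproduces the reference
values); grid points with `Q >= 1` are masked as infinite.  The
proportionality constant `d_opt` in `tau_opt ~ d_opt * 2*NeE` solves
`d + c*II_inf*e^d = 1` (`c = 1` forward, `1/2` intermediate; backward
and gene-diversity use `d = 1`) by bisection to `1e-12`; a nonpositive
`II_inf` returns 1.  The accuracy horizon `tau_C` is
`min{tau: sd_factor >= C} - 1`.  One caveat observed on the reference
model: within one generation of the existence boundary the factor is so
steep that `tau_C` for large `C` is sensitive at the level of a single
generation.

## Simulator

The forward simulator implements the three reproduction steps exactly
(hypergeometric breeder draw — an exact pass-through when `Ne = Nc` —
deterministic pool mixing, binomial fertilization), with integer counts
as state so absorbing boundaries are exact.  Loci are fully independent
replicates driven by one seeded generator; the founder count
`round(2*Nc*p)` must represent `p` exactly.  Loci that fix during
burn-in are retained, since the theory's expectations are over the
unconditional process.  Empirical `F`, `F_int`, `F_back` and the
drift/gene-flow split are across-locus ratios of means with standard
errors from a 200-resample locus bootstrap.  What the generator does
*not* emulate about real data: mutation, selection, linkage
disequilibrium, overlapping generations, uncertain generation intervals
and genotyping error — so passing tests certify the mathematics, not
robustness to those features.  For tiny systems
(`prod(2*Nc_x + 1) <= 5000` states) the exact joint allele-count chain
is assembled; its third-largest eigenvalue equals `lambda_max(A)`, which
serves as an independent cross-check of the recursion matrix.

Monte-Carlo validations compare simulated ratios against the *exact
transient* recursion predictions at a moderate burn-in (300 generations,
`1e4` loci for the reference model) — exact at any horizon and far
better conditioned than a near-fixation equilibrium burn-in — while
equilibrium convergence of the recursions themselves is verified
deterministically.

## Temporal estimation

The estimator pools sample frequencies per locus with `w` and `v` and
forms
`F_int = sum_l (p2_l - p1_l)^2 / sum_l z_l (1 - z_l)` with
`z = (p1+p2)/2` as a ratio of sums across loci, and inverts the
intermediate decay law.  Sample sizes enter through weight-squared
harmonic pooling `n = 1/sum_x w_x^2/n_x`, matching the binomial variance
of the pooled frequency.  The optional sampling correction subtracts
`z(1-z)(1/(2 n_t) + 1/(2 n_{t+tau}))` per locus from the numerator; it
is a deliberate approximation of the full published finite-sampling
adjustment and is off by default.  Maximizing the estimate over the
weight simplex (same weights at both ends) estimates the eigenvalue
effective size, and the maximizer the reproductive weights: a
deterministic coarse simplex grid (step 1/12) with ties broken toward
uniform is followed by Nelder-Mead refinement on softmax logits.
The maximization rests on the equilibrium/symmetric-migration theory, so
for strongly asymmetric or non-equilibrium systems the maximizer is a
heuristic; tests assert its structural properties (dominance over fixed
weightings, permutation equivariance, source-population attraction), not
specific values.

## Reference problem sizes

The analytic reference computations use the island model with `s = 10`,
`Nc = Ne = 50`, `m = 0.1` (recursion matrix of order 100), design curves
on integer grids of 4000-12000 generations, and scans capped at `1e7`.
Stochastic checks use `1e4`-`3e4` loci with burn-ins of 40-300
generations and `1e5` replicates for single-generation variance checks —
sizes at which all bootstrap bands are a few per mille wide while the
whole suite stays interactive.
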