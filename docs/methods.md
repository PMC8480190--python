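# Methods

`arcdating` dates the nodes of a fixed rooted phylogeny from tip sampling
dates and observed branch lengths in substitution units, using six
alternative molecular clock models, and provides the simulation, model
comparison and temporal-signal machinery around that core. This note
records the models, the numerical and design choices, and what the test
suite does and does not establish.

## Branch substitution models

A clock model is the conditional law of the number of substitutions `x_i`
accumulated on a branch of duration `l_i` years. All six models share the
mean `E(x_i) = mu * l_i`, with `mu` in substitutions per genome per year:

| model | law of `x_i` | variance | additive | support |
|-------|--------------|----------|----------|---------|
| SC    | Poisson(mu l)                               | mu l              | yes | integers |
| RC    | NegBin(k, tl/(1+tl)), k=mu²/sigma², t=sigma²/mu | mu l + sigma² l² | no | integers |
| ARC   | NegBin(mu l/omega, omega/(1+omega))         | mu l (1+omega)    | yes | integers |
| cSC   | Gamma(mu l, 1)                              | mu l              | yes | reals ≥ 0 |
| cRC   | Gamma(mu² l/(mu+sigma² l), 1+sigma² l/mu)   | mu l + sigma² l²  | no | reals ≥ 0 |
| cARC  | Gamma(mu l/(1+omega), 1+omega)              | mu l (1+omega)    | yes | reals ≥ 0 |

Conventions. All gamma distributions are shape–scale, funnelled through a
single helper to avoid rate/scale mix-ups. NegBin(r, p) has pmf
`C(x+r-1, x) p^x (1-p)^r` and mean `r p/(1-p)`; with the ARC
parameterization this reproduces the gamma–Poisson mixture in which the
branch rate is `m_i ~ Gamma(mu l_i/omega, omega/l_i)` and
`x_i | m_i ~ Poisson(m_i l_i)` — the test suite verifies the pmf against
numerical integration of that mixture to eight significant digits.

Additivity. A law is additive when the sum of the counts on two abutting
branches is distributed as the count on the merged branch — equivalently,
the law is infinitely divisible in `l`. SC/cSC/ARC/cARC are (Poisson,
negative-binomial and gamma processes are Lévy processes); RC/cRC are not:
their variance falls short by exactly `2 sigma² l1 l2` when a branch is
split. `additivity_gap` quantifies both facts, returning a numerical
distribution distance (exact truncated convolution for the discrete
models, quadrature of the convolution integral for the continuous ones)
and the closed-form variance gap.

Degenerate inputs. A zero-duration branch carries a point mass at zero
substitutions under every model (the `l -> 0` limit of each law); the ARC
per-branch rate is undefined at `l = 0` and its sampler raises. cARC
defines the count law directly and its implied per-branch rates are not
identically distributed, so no cARC rate sampler is exposed. Observed
zero branch lengths under the continuous models are floored at `1e-9`
before density evaluation, because the gamma density diverges at zero
when its shape is below one; reconstructed trees routinely contain such
branches. This flooring is adequate for parameter estimation but **not**
for comparing continuous models on data containing many exact zeros (the
relaxed gamma, with smaller shape, harvests unbounded density at the
floor); model comparison between cSC and cARC should therefore be run on
genuinely continuous branch lengths. All likelihoods are computed in log
space; the `lgamma(x+r) - lgamma(r)` term of the negative binomial is
evaluated as `sum_j log(r+j)` for integer x, which stays accurate when a
near-zero relaxation sends `r` to ~1e10.

## Simulator

Genealogies are drawn from the heterochronous coalescent with constant
pairwise coalescence rate `1/alpha` (`alpha = Ne*g`, in years): looking
backwards, `k` active lineages coalesce after an exponential wait of rate
`k(k-1)/(2 alpha)`, and lineages activate at their sampling dates. The
benchmark generator emulates a standard simulation design for bacterial
genomic epidemiology: 100 genomes of 10,000 bp sampled at regular
intervals over 2010–2020 (both endpoints included), `alpha = 5` years,
and the discrete ARC clock with `mu = 5` substitutions/genome/year and
relaxation `omega` between 0 and 10. ARC branch counts are generated by
the two-stage mechanism (gamma rate, then Poisson), which equals the
direct negative-binomial draw.

The generator runs in *error-free reconstruction* mode: the observed tree
is the true topology with branch lengths drawn from the clock law.
Jukes–Cantor alignments can be produced (per-site substitution
probability `(3/4)(1 - exp(-4d/3))` with `d` the branch's realized
per-site divergence) for users who wish to interpose their own tree
estimator, but no reconstruction step is included. Consequently the
simulated data lack three features of real pipelines — branch-length
estimation noise, topology error, and root misplacement — and passing
tests demonstrate correct inference *given a correct rooted tree*, not
robustness to reconstruction error. This matters most for the width of
TMRCA intervals, which is the quantity most sensitive to root placement
(see Limitations).

## Bayesian dating

The sampler targets the posterior of all internal-node dates (the root
date is the TMRCA), `mu`, and the relaxation parameter (`omega` or
`sigma2`), given the fixed rooted topology, per-branch substitution
counts, and tip dates:

    posterior ∝ prod_i P(x_i | l_i(dates), mu, relax)
                × coalescent(dates | alpha) × priors(mu, relax, alpha)

Tree prior. Default is the heterochronous constant-rate coalescent, with
`alpha` estimated under an Exponential hyperprior of mean 10 years; a
uniform prior over ordering-constrained dates is selectable.

Parameter priors (shape–scale gammas). `mu ~ Gamma(0.001, 1000)` (vague,
mean 1, variance 1000) and, by default, the same vague prior on the
relaxation parameter. The latter choice is deliberate: under the
classical RC model the rate variance `sigma2` routinely needs values of
order 10–100 to explain strongly relaxed data (its variance contribution
`sigma2 l²` must stand in for `mu omega l` on sub-year branches), and an
informative prior with mean 0.1 was observed to collapse RC to a strict
clock, producing overconfident, badly covering intervals. The
conservative `Gamma(0.1, 1)` prior (mean and variance 0.1) remains the
default for reversible-jump model selection, where a proper, concentrated
prior on `omega` is essential for a meaningful Bayes factor.

Moves. Each sweep updates every internal-node date with a uniform-window
proposal truncated to the parent/child bounds, then `mu`, the relaxation,
and `alpha` with multiplicative (log-scale) proposals. Widths adapt
toward 20–40% acceptance during the first 20% of the run and are then
frozen, keeping the remainder a valid fixed-kernel chain. Date moves use
incremental three-branch likelihood updates; the coalescent prior is
recomputed in full per proposal (a ~2n argsort, measured cheap). Recorded
log-likelihoods are re-summed from scratch at each thinning point so the
trace is free of incremental floating-point drift. The inner loop is
compiled with numba; the public `log_posterior` provides an independent
scipy-backed implementation of the same density, and the two routes are
cross-checked in the tests. Chains are exactly reproducible given
`(data, model, priors, n_iter, thin, seed)`.

Initialization. Internal dates are set recursively below their children
using a root-to-tip regression estimate of the rate; `mu` starts at that
estimate, the relaxation at 0.5, `alpha` at its prior mean. Burn-in
(default: first half of recorded samples) is discarded by summaries.

Discrete models require integral per-genome counts; per-site trees are
converted with `to_genome_units` (half-integer ties round away from
zero — documented as part of the conversion contract, since upstream
tools do not specify one). Polytomies are resolved arbitrarily with
zero-length branches, which provably leaves additive-model likelihoods
unchanged (and is logged, because it is not innocuous under RC/cRC).

Reversible jump. `run_rjmcmc` moves between cSC and cARC (nested at
`omega = 0`): strict→relaxed proposes `omega` from its prior
(independence sampler, so prior and proposal cancel and the acceptance
ratio is the likelihood ratio), relaxed→strict drops it; model prior odds
are 1:1, so the Bayes factor is the posterior indicator odds. With the
conservative omega prior the comparison is decisive when relaxation is
present and close to indifferent (BF near, usually just above, 1) on
strict data — tiny proposed `omega` values make the relaxed model shadow
the strict one, the familiar cost of nesting.

## Model evaluation

DIC. `DIC = Dbar + pD` with `D = -2 log L` over the post-burn-in trace.
The default effective-parameter estimator is `pD = Var(D)/2`, which is
reparameterization-invariant and robust when the focus includes ~n wide,
skewed node-date posteriors; the classical plug-in
`pD = Dbar - D(theta_bar)` at natural-scale posterior means is available
as an option. The default matters: on strongly relaxed data the plug-in
variant was measured to assign the misspecified RC model an absurdly
small pD (≈5–10 for ~102 parameters) and corrupt the ranking, while the
variance form prefers the true model in 10/10 datasets.

Temporal signal. The date-randomization test permutes sampling dates
among tips (without replacement), reruns the dating MCMC per permutation,
and declares significance iff the original 95% CI for `mu` overlaps none
of the randomized CIs. Root-to-tip regression (OLS of root-to-tip
distance on date) is provided as the classical quick check; its slope
estimates the rate only under a strict clock and its points are not
independent, so it is deliberately not used for formal decisions.

## Problem sizes used by the tests and the acceptance script

Monte-Carlo distribution checks use 10^5–10^6 draws (3–4 standard-error
bands). The benchmark precision comparison runs 20 datasets × 2 models at
2×10^4 sweeps (about 5 s per chain for 100 tips after JIT compilation);
DIC preference uses 10 datasets at 10^4 sweeps; relaxation recovery uses
the `omega ∈ {0,1,2,5,10}` grid × 4 seeds at 10^4 sweeps. These sizes
were chosen so the entire battery reruns from scratch on one CPU in well
under half an hour while keeping Monte-Carlo error far below the effect
sizes under test.

## Limitations

- Two-step method: branch counts, not alignments, are the data; joint
  inference by the pruning algorithm is out of scope.
- The topology and root are taken as given; no re-rooting, no topology
  error model. On the benchmark, posterior coverage of `mu` and the TMRCA
  is at the nominal level, but credible intervals — especially for the
  TMRCA — are systematically narrower than published full-pipeline
  analyses that carry reconstruction and rooting uncertainty
  (approximately 0.6× for TMRCA interval widths, ~1.1–1.3× for rate
  interval widths at matched settings).
- Constant population size coalescent only; no recombination, indels, or
  site-heterogeneous substitution models.
- Continuous-model comparison is unreliable on data with many exact-zero
  branch lengths (see flooring note above); use the discrete models
  there.
- Autocorrelated clocks and lognormal/exponential rate distributions are
  not implemented.
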