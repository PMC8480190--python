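"""Bayesian MCMC dating of a fixed rooted topology with tip dates.

Given an observed tree with branch lengths in substitutions and known tip
sampling dates, the sampler infers the calendar dates of all internal
nodes (including the root, i.e. the TMRCA), the mean substitution rate mu,
and the clock relaxation parameter (omega for the additive relaxed clocks,
sigma2 for the classical ones), under one of the six branch substitution
laws of :mod:`arcdating.clock_models`.

The tree prior on node dates is, by default, the heterochronous
constant-rate coalescent with pairwise coalescence rate 1/alpha and an
exponential hyperprior on alpha; a uniform prior on ordering-constrained
dates can be selected instead. Proposals are Metropolis-Hastings: a
uniform window per internal-node date respecting parent/child bounds, and
multiplicative scale moves for mu, the relaxation parameter, and alpha;
widths adapt during the first 20% of the run and are then frozen.

A reversible-jump sampler toggling between the continuous strict clock and
the continuous additive relaxed clock (nested at omega = 0) provides
Bayes-factor model selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .clock_models import ClockModel, ClockParams, branch_loglik
from .timetree import SubstTree, resolve_polytomies

__all__ = [
    "Priors",
    "DatingState",
    "PosteriorTrace",
    "log_posterior",
    "run_mcmc",
    "run_rjmcmc",
    "summarize",
    "diagnostics",
]

_RELAX_NAME = {"rc": "sigma2", "crc": "sigma2", "arc": "omega", "carc": "omega"}


@dataclass(frozen=True)
class Priors:
    """Prior settings for the dating MCMC (gamma priors are shape-scale).

    Defaults: vague Gamma(0.001, 1000) priors on both mu and the
    relaxation parameter — under the classical relaxed clock the rate
    variance sigma2 routinely needs values of order 10-100 on relaxed
    data, so an informative prior on the relaxation would dominate the
    estimation — and an Exponential hyperprior with mean 10 years on the
    coalescent parameter alpha. ``tree_prior`` selects between the
    heterochronous coalescent density on node dates and a flat prior on
    the ordering-constrained dates.

    For reversible-jump model selection a *proper, conservative* prior on
    omega is essential (a vague prior makes the jump proposal hopeless and
    biases the Bayes factor toward the strict model);
    :func:`run_rjmcmc` therefore defaults to Gamma(0.1, 1), mean and
    variance 0.1.
    """

    mu: tuple[float, float] = (0.001, 1000.0)
    relax: tuple[float, float] = (0.001, 1000.0)
    alpha_mean: float = 10.0
    tree_prior: str = "coalescent"

    def __post_init__(self) -> None:
        if self.tree_prior not in ("coalescent", "uniform"):
            raise ValueError("tree_prior must be 'coalescent' or 'uniform'")


@dataclass
class DatingState:
    """One point in the dating parameter space.

    ``node_dates`` maps internal-node labels to decimal years; tips keep
    their fixed sampling dates. ``relax`` is omega or sigma2 depending on
    the model (None for strict clocks). ``alpha`` is the coalescent
    parameter (ignored under the uniform tree prior).
    """

    node_dates: dict[str, float]
    mu: float
    relax: float | None = None
    alpha: float | None = None
    model_indicator: str | None = None


class _TreeData:
    """Array encoding of a SubstTree + tip dates for the samplers."""

    def __init__(self, stree: SubstTree, need_binary: bool = True):
        stree = resolve_polytomies(stree, seed=0)
        self.stree = stree  # resolved copy whose internal nodes get labels
        nodes = list(stree.tree.preorder_node_iter())
        self.n = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n, -1, dtype=np.int64)
        self.c1 = np.full(self.n, -1, dtype=np.int64)
        self.c2 = np.full(self.n, -1, dtype=np.int64)
        self.is_tip = np.zeros(self.n, dtype=np.bool_)
        self.x = np.zeros(self.n)
        self.dates = np.full(self.n, np.nan)
        self.labels: list[str] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
                self.x[i] = float(nd.edge.length or 0.0)
            kids = nd.child_nodes()
            if nd.is_leaf():
                self.is_tip[i] = True
                lab = nd.taxon.label
                if lab not in stree.tip_dates:
                    raise ValueError(f"no sampling date for tip {lab!r}")
                self.dates[i] = stree.tip_dates[lab]
            else:
                if len(kids) == 1:
                    if need_binary:
                        raise ValueError(
                            "internal node with a single child; only the "
                            "root may be unary, and only with fix_dates"
                        )
                    self.c1[i] = self.c2[i] = index[id(kids[0])]
                else:
                    self.c1[i] = index[id(kids[0])]
                    self.c2[i] = index[id(kids[1])]
                lab = nd.taxon.label if nd.taxon else (nd.label or f"n{i}")
                nd.label = lab
            self.labels.append(lab)
        self.internals = np.where(~self.is_tip)[0]
        self.root = int(np.where(self.parent < 0)[0][0])
        self.tip_span = float(np.ptp(self.dates[self.is_tip]))
        if self.tip_span == 0.0:
            warnings.warn(
                "all tip dates are identical: node dates and the rate are "
                "not jointly identifiable", stacklevel=3
            )

    def init_dates(self, mu0: float) -> None:
        """Heuristic initial internal dates consistent with the ordering."""
        for i in range(self.n - 1, -1, -1):
            if self.is_tip[i]:
                continue
            c1, c2 = self.c1[i], self.c2[i]
            d = min(
                self.dates[c1] - max(self.x[c1], 0.5) / mu0,
                self.dates[c2] - max(self.x[c2], 0.5) / mu0,
            )
            self.dates[i] = d

    def rough_rate(self) -> float:
        """Root-to-tip based initial guess of the clock rate."""
        try:
            slope = _rtt_slope(self)
            if slope > 0 and math.isfinite(slope):
                return slope
        except Exception:
            pass
        return 1.0


def _rtt_slope(td: _TreeData) -> float:
    # root-to-tip distances from the encoded arrays
    depth = np.zeros(td.n)
    for i in range(td.n):
        p = td.parent[i]
        if p >= 0:
            depth[i] = depth[p] + td.x[i]
    t = td.dates[td.is_tip]
    d = depth[td.is_tip]
    if np.ptp(t) == 0:
        return np.nan
    return float(np.polyfit(t, d, 1)[0])


class PosteriorTrace:
    """Recorded MCMC samples plus run metadata.

    ``df`` holds one row per recorded iteration with columns ``iteration``,
    ``loglik``, ``logprior``, ``mu``, the relaxation parameter (``omega``
    or ``sigma2``), ``alpha`` (coalescent prior only), ``tmrca`` and one
    ``date_<label>`` column per internal node. The first ``burn_frac`` of
    rows is treated as burn-in by downstream summaries.
    """

    def __init__(self, df: pd.DataFrame, *, model: str, seed: int, n_iter: int,
                 thin: int, burn_frac: float = 0.5, relax_name: str | None = None,
                 acceptance: dict | None = None, extra: dict | None = None):
        self.df = df
        self.model = model
        self.seed = seed
        self.n_iter = n_iter
        self.thin = thin
        self.burn_frac = burn_frac
        self.relax_name = relax_name
        self.acceptance = acceptance or {}
        self.extra = extra or {}
        if not np.isfinite(df["loglik"]).all():
            raise ValueError("non-finite log-likelihood recorded in trace")

    def __len__(self) -> int:
        return len(self.df)

    def post_burnin(self) -> pd.DataFrame:
        return self.df.iloc[int(len(self.df) * self.burn_frac):]

    def to_csv(self, path, **kwargs) -> None:
        self.df.to_csv(path, index=False, **kwargs)


def _prepare(stree: SubstTree, model: str | ClockModel):
    model = ClockModel(model if isinstance(model, str) else model.value)
    if model.discrete:
        if stree.unit != "per_genome":
            raise ValueError(
                "discrete clock models need integer per-genome counts; "
                "convert with to_genome_units(..., rounding='nearest')"
            )
        lengths = [e.length for e in stree.tree.preorder_edge_iter()
                   if e.length is not None]
        if any(abs(v - round(v)) > 1e-9 for v in lengths):
            raise ValueError(
                "discrete clock models need integral branch lengths; "
                "re-run to_genome_units with rounding='nearest'"
            )
    return model


def run_mcmc(stree: SubstTree, model: str | ClockModel = "arc",
             priors: Priors | None = None, n_iter: int = 100_000,
             thin: int | None = None, seed: int = 0, *,
             fix_dates: bool = False, use_data: bool = True,
             burn_frac: float = 0.5, init: dict | None = None) -> PosteriorTrace:
    """Run the dating MCMC and return the posterior trace.

    Parameters largely mirror the run settings of tip-dating tools: the
    chain length ``n_iter`` counts full sweeps (every internal node date
    plus every scalar parameter updated once per sweep), ``thin`` defaults
    to keeping ~2000 samples, and the first half of the recorded trace is
    treated as burn-in. ``fix_dates`` holds node dates at their initial
    values (useful with single-parameter conjugate checks); ``use_data``
    = False runs the chain prior-only.

    Reproducibility: the chain is a deterministic function of
    ``(data, model, priors, n_iter, thin, seed)``.
    """
    if n_iter < 1000:
        raise ValueError("n_iter below the burn-in floor of 1000 sweeps")
    priors = priors or Priors()
    model = _prepare(stree, model)
    td = _TreeData(stree, need_binary=not fix_dates)
    if thin is None:
        thin = max(1, n_iter // 2000)

    init = init or {}
    mu0 = float(init.get("mu", td.rough_rate()))
    relax0 = float(init.get("relax", 0.5)) if model.relaxed else 0.0
    alpha0 = float(init.get("alpha", priors.alpha_mean))
    if "dates" in init:
        for lab, d in init["dates"].items():
            td.dates[td.labels.index(lab)] = d
    else:
        td.init_dates(mu0)

    n_rec = n_iter // thin
    out_dates = np.empty((n_rec, td.internals.size))
    out_par = np.empty((n_rec, 3))
    out_ll = np.empty(n_rec)
    out_lp = np.empty(n_rec)
    rates = _kernel.run_chain(
        td.parent, td.c1, td.c2, td.is_tip, td.dates.copy(), td.x, td.internals,
        _kernel.MODEL_CODES[model.value], mu0, relax0, alpha0,
        priors.mu[0], priors.mu[1], priors.relax[0], priors.relax[1],
        priors.alpha_mean,
        0 if priors.tree_prior == "coalescent" else 1,
        0 if fix_dates else 1,
        1 if use_data else 0,
        int(n_iter), int(thin), int(seed) % (2**31 - 1),
        out_dates, out_par, out_ll, out_lp,
    )

    cols = {"iteration": np.arange(1, n_rec + 1) * thin,
            "loglik": out_ll, "logprior": out_lp, "mu": out_par[:, 0]}
    relax_name = _RELAX_NAME.get(model.value)
    if relax_name:
        cols[relax_name] = out_par[:, 1]
    if priors.tree_prior == "coalescent":
        cols["alpha"] = out_par[:, 2]
    cols["tmrca"] = out_dates[:, list(td.internals).index(td.root)]
    for j, idx in enumerate(td.internals):
        cols[f"date_{td.labels[idx]}"] = out_dates[:, j]
    df = pd.DataFrame(cols)
    acc = dict(zip(("node_dates", "mu", "relax", "alpha"), rates.tolist()))
    return PosteriorTrace(df, model=model.value, seed=seed, n_iter=n_iter,
                          thin=thin, burn_frac=burn_frac, relax_name=relax_name,
                          acceptance=acc,
                          extra={"priors": priors, "root_label": td.labels[td.root],
                                 "internal_labels": [td.labels[i] for i in td.internals],
                                 "data_tree": td.stree})


# ---------------------------------------------------------------------------
# posterior density (pure-Python reference used by tests and model_eval)

def _coal_logp_py(dates: np.ndarray, is_tip: np.ndarray, alpha: float) -> float:
    order = np.argsort(dates)[::-1]
    logp, k, prev = 0.0, 0, dates[order[0]]
    for idx in order:
        t = dates[idx]
        logp -= 0.5 * k * (k - 1) * (prev - t) / alpha
        if is_tip[idx]:
            k += 1
        else:
            logp -= math.log(alpha)
            k -= 1
        prev = t
    return logp


def _state_params(model: ClockModel, mu: float, relax) -> ClockParams:
    if model in (ClockModel.RC, ClockModel.cRC):
        return ClockParams(model, mu=mu, sigma2=relax)
    if model in (ClockModel.ARC, ClockModel.cARC):
        return ClockParams(model, mu=mu, omega=relax)
    return ClockParams(model, mu=mu)


def _gamma_logpdf_py(v, shape, scale) -> float:
    if v <= 0:
        return -math.inf
    return (shape - 1) * math.log(v) - v / scale - math.lgamma(shape) - shape * math.log(scale)


def log_posterior(state: DatingState, stree: SubstTree,
                  model: str | ClockModel, priors: Priors | None = None) -> float:
    """Unnormalized log-posterior density of a dating state.

    Sum of per-branch substitution log-likelihoods, the tree-prior density
    of the node dates, and the parameter priors. Returns ``-inf`` (rather
    than raising) for states violating the parent-before-child ordering or
    parameter positivity.
    """
    priors = priors or Priors()
    model = _prepare(stree, model)
    td = _TreeData(stree, need_binary=False)
    for lab, d in state.node_dates.items():
        if lab not in td.labels:
            raise ValueError(f"state refers to unknown node {lab!r}")
        td.dates[td.labels.index(lab)] = d
    if np.isnan(td.dates).any():
        raise ValueError("state does not date every internal node")
    if state.mu <= 0 or (model.relaxed and (state.relax is None or state.relax < 0)):
        return -math.inf
    durations = td.dates - np.where(td.parent >= 0, td.dates[td.parent], td.dates)
    if (durations < 0).any():
        return -math.inf
    params = _state_params(model, state.mu, state.relax)
    ll = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v in range(td.n):
            if td.parent[v] >= 0:
                ll += branch_loglik(params, durations[v], td.x[v])
    if not math.isfinite(ll):
        return -math.inf
    lp = _gamma_logpdf_py(state.mu, *priors.mu)
    if model.relaxed:
        lp += _gamma_logpdf_py(state.relax, *priors.relax)
    if priors.tree_prior == "coalescent":
        alpha = state.alpha if state.alpha is not None else priors.alpha_mean
        if alpha <= 0:
            return -math.inf
        lp += _coal_logp_py(td.dates, td.is_tip, alpha)
        lp += -math.log(priors.alpha_mean) - alpha / priors.alpha_mean
    return ll + lp


# ---------------------------------------------------------------------------
# reversible jump between cSC (omega = 0) and cARC (omega > 0)

def run_rjmcmc(stree: SubstTree, priors: Priors | None = None,
               n_iter: int = 20_000, thin: int | None = None,
               seed: int = 0, burn_frac: float = 0.5):
    """Reversible-jump MCMC comparing the continuous strict clock against
    the continuous additive relaxed clock.

    The strict model is nested in the relaxed one at omega = 0, so the
    trans-model move toggles the relaxation on and off: strict -> relaxed
    proposes omega from its prior (independence sampler, acceptance ratio
    reduces to the likelihood ratio with 1:1 prior model odds), relaxed ->
    strict drops it. Returns ``(trace, bayes_factor)`` where the Bayes
    factor is the posterior odds of strict over relaxed.

    Only continuous models are supported: the discrete strict clock is not
    nested in the discrete relaxed laws.
    """
    priors = priors or Priors(relax=(0.1, 1.0))
    if n_iter < 1000:
        raise ValueError("n_iter below the burn-in floor of 1000 sweeps")
    td = _TreeData(stree)
    if thin is None:
        thin = max(1, n_iter // 2000)
    rng = np.random.default_rng(seed)
    bll = _kernel.branch_ll
    coal_fn = _kernel.coal_logp
    use_coal = priors.tree_prior == "coalescent"

    mu = td.rough_rate()
    omega = 0.0
    relaxed = 0
    alpha = priors.alpha_mean
    td.init_dates(mu)
    dates = td.dates.copy()
    model_of = lambda rel: _kernel.CARC if rel else _kernel.CSC

    def full_ll(m, mu_, om_):
        return _kernel.total_ll(td.parent, dates, td.x, m, mu_, om_)

    total = full_ll(model_of(relaxed), mu, omega)
    coal = coal_fn(dates, td.is_tip, alpha) if use_coal else 0.0
    wnode = 1.0
    smu = som = 0.3
    n_rec = n_iter // thin
    rows = np.empty((n_rec, 6))
    rec_dates = np.empty((n_rec, td.internals.size))
    rec = 0
    adapt_end = n_iter // 5
    acc = np.zeros(2)
    trials = np.zeros(2)

    for it in range(n_iter):
        m = model_of(relaxed)
        for v in td.internals:
            d0 = dates[v]
            d1 = d0 + wnode * (2 * rng.random() - 1)
            hi = min(dates[td.c1[v]], dates[td.c2[v]])
            trials[0] += 1
            if d1 > hi or (td.parent[v] >= 0 and d1 < dates[td.parent[v]]):
                continue
            delta = 0.0
            nb = []
            for w in (v, td.c1[v], td.c2[v]):
                if td.parent[w] < 0:
                    nb.append(0.0)
                    continue
                p = td.parent[w]
                l_new = (d1 - dates[p]) if w == v else (dates[w] - d1)
                nb.append(bll(m, mu, omega, l_new, td.x[w]))
                delta += nb[-1] - bll(m, mu, omega, dates[w] - dates[p], td.x[w])
            ncoal = coal
            if use_coal:
                dates[v] = d1
                ncoal = coal_fn(dates, td.is_tip, alpha)
                dates[v] = d0
                delta += ncoal - coal
            if delta >= 0 or math.log(rng.random()) < delta:
                dates[v] = d1
                coal = ncoal
                total = full_ll(m, mu, omega)
                acc[0] += 1

        # mu
        u = 2 * rng.random() - 1
        mu1 = mu * math.exp(smu * u)
        new = full_ll(m, mu1, omega)
        delta = (new - total + smu * u
                 + _gamma_logpdf_py(mu1, *priors.mu) - _gamma_logpdf_py(mu, *priors.mu))
        trials[1] += 1
        if delta >= 0 or math.log(rng.random()) < delta:
            mu, total = mu1, new
            acc[1] += 1
        # omega (within relaxed model)
        if relaxed:
            u = 2 * rng.random() - 1
            om1 = omega * math.exp(som * u)
            new = full_ll(m, mu, om1)
            delta = (new - total + som * u
                     + _gamma_logpdf_py(om1, *priors.relax)
                     - _gamma_logpdf_py(omega, *priors.relax))
            if delta >= 0 or math.log(rng.random()) < delta:
                omega, total = om1, new
        # alpha
        if use_coal:
            u = 2 * rng.random() - 1
            a1 = alpha * math.exp(0.5 * u)
            ncoal = coal_fn(dates, td.is_tip, a1)
            delta = ncoal - coal - (a1 - alpha) / priors.alpha_mean + 0.5 * u
            if delta >= 0 or math.log(rng.random()) < delta:
                alpha, coal = a1, ncoal
        # trans-model jump
        if relaxed:
            new = full_ll(_kernel.CSC, mu, 0.0)
            if new - total >= 0 or math.log(rng.random()) < new - total:
                relaxed, omega, total = 0, 0.0, new
        else:
            om1 = float(rng.gamma(priors.relax[0], priors.relax[1]))
            new = full_ll(_kernel.CARC, mu, om1)
            if new - total >= 0 or math.log(rng.random()) < new - total:
                relaxed, omega, total = 1, om1, new

        if it < adapt_end and (it + 1) % 50 == 0:
            if trials[0] > 0:
                r = acc[0] / trials[0]
                wnode = wnode * 1.4 if r > 0.4 else (wnode / 1.4 if r < 0.2 else wnode)
            if trials[1] > 0:
                r = acc[1] / trials[1]
                smu = smu * 1.4 if r > 0.4 else (smu / 1.4 if r < 0.2 else smu)
            acc[:] = 0
            trials[:] = 0

        if (it + 1) % thin == 0:
            rows[rec] = (it + 1, total, mu, omega, float(relaxed), alpha)
            rec_dates[rec] = dates[td.internals]
            rec += 1

    df = pd.DataFrame(rows, columns=["iteration", "loglik", "mu", "omega",
                                     "model_indicator", "alpha"])
    df["logprior"] = 0.0  # not tracked for the rj sampler
    df["tmrca"] = rec_dates[:, list(td.internals).index(td.root)]
    trace = PosteriorTrace(df, model="csc|carc", seed=seed, n_iter=n_iter,
                           thin=thin, burn_frac=burn_frac, relax_name="omega")
    post = trace.post_burnin()["model_indicator"]
    n_rel = float((post == 1.0).sum())
    n_str = float((post == 0.0).sum())
    bf = math.inf if n_rel == 0 else n_str / n_rel
    trace.extra["bayes_factor_strict_vs_relaxed"] = bf
    return trace, bf


# ---------------------------------------------------------------------------
# summaries and diagnostics

_META_COLS = ("iteration", "loglik", "logprior")


def summarize(trace: PosteriorTrace, min_samples: int = 100) -> pd.DataFrame:
    """Posterior mean and central 95% credible interval per parameter.

    Rows cover the TMRCA (root date), mu, the relaxation parameter, alpha,
    and every internal-node date; columns are ``mean``, ``q025``,
    ``median``, ``q975`` and ``ci_length``.
    """
    post = trace.post_burnin()
    if len(post) == 0:
        raise ValueError("empty trace")
    if len(post) < min_samples:
        raise ValueError(
            f"only {len(post)} post-burn-in samples; need >= {min_samples}"
        )
    rows = {}
    for col in post.columns:
        if col in _META_COLS:
            continue
        v = post[col].to_numpy()
        q = np.quantile(v, [0.025, 0.5, 0.975])
        rows[col] = {"mean": v.mean(), "q025": q[0], "median": q[1],
                     "q975": q[2], "ci_length": q[2] - q[0]}
    return pd.DataFrame(rows).T


def diagnostics(traces, include_dates: bool = False,
                ess_floor: float = 200.0, psrf_limit: float = 1.1) -> pd.DataFrame:
    """Effective sample size and split-R-hat convergence diagnostics.

    Accepts one trace (ESS only) or several parallel chains (adds the
    Gelman-Rubin PSRF). Chains of unequal length are truncated to the
    shortest with a warning. Parameters with ESS below ``ess_floor`` or
    PSRF above ``psrf_limit`` are flagged.
    """
    import arviz as az

    if isinstance(traces, PosteriorTrace):
        traces = [traces]
    if not traces:
        raise ValueError("need at least one trace")
    dfs = [t.post_burnin() for t in traces]
    n_min = min(len(d) for d in dfs)
    if any(len(d) != n_min for d in dfs):
        warnings.warn("chains of unequal length; truncating to the shortest")
        dfs = [d.iloc[:n_min] for d in dfs]
    params = [c for c in dfs[0].columns
              if c not in _META_COLS and (include_dates or not c.startswith("date_"))]
    out = {}
    for p in params:
        arr = np.stack([d[p].to_numpy() for d in dfs])  # (chain, draw)
        ess = float(np.ravel(az.ess(az.convert_to_dataset(arr[:, :, None]))["x"])[0])
        psrf = (float(np.ravel(az.rhat(az.convert_to_dataset(arr[:, :, None]))["x"])[0])
                if len(dfs) >= 2 else np.nan)
        out[p] = {"ess": ess, "psrf": psrf,
                  "flag": bool(ess < ess_floor or (psrf == psrf and psrf > psrf_limit))}
    return pd.DataFrame(out).T
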