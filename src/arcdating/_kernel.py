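"""Compiled inner loops for the Bayesian dating MCMC.

Trees are flattened to parent/child index arrays so the whole sampler can
run under numba: per-sweep Metropolis-Hastings updates of every internal
node date (uniform-window proposals, incremental 3-branch likelihood
updates) plus multiplicative scale moves for the mean rate, the relaxation
parameter, and the coalescent parameter alpha. The heterochronous
coalescent tree prior is recomputed in full after each date proposal (an
argsort over ~2n events), which profiling shows is cheap enough.

Everything here is an implementation detail; :mod:`arcdating.bayes_dating`
is the public surface. The branch log-likelihoods duplicate
:mod:`arcdating.clock_models` in scalar form and are cross-checked against
it in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# model codes
SC, RC, ARC, CSC, CRC, CARC = 0, 1, 2, 3, 4, 5

MODEL_CODES = {"sc": SC, "rc": RC, "arc": ARC, "csc": CSC, "crc": CRC, "carc": CARC}

_FLOOR = 1e-9
_STRICT_TOL = 1e-12


@njit(cache=False)
def _lgamma_ratio(x, r):
    """lgamma(x + r) - lgamma(r) for integer x >= 0, stable for huge r.

    The direct difference cancels catastrophically once r >> 1 (relaxation
    near zero sends the negative-binomial size to ~1e10); the product form
    sum_j log(r + j) is exact for integral x.
    """
    if x <= 1000.0:
        s = 0.0
        for j in range(int(x)):
            s += math.log(r + j)
        return s
    return math.lgamma(x + r) - math.lgamma(r)


@njit(cache=False)
def branch_ll(model, mu, relax, l, x):
    """Log-probability of x substitutions on a branch of duration l."""
    if l <= 0.0:
        return 0.0 if x <= _FLOOR else -math.inf
    if model == SC or (model == RC and relax <= _STRICT_TOL) or (
            model == ARC and relax <= _STRICT_TOL):
        lam = mu * l
        return x * math.log(lam) - lam - math.lgamma(x + 1.0)
    if model == RC:
        k = mu * mu / relax
        p = relax * l / (mu + relax * l)
        return (_lgamma_ratio(x, k) - math.lgamma(x + 1.0)
                + x * math.log(p) + k * math.log1p(-p))
    if model == ARC:
        r = mu * l / relax
        p = relax / (1.0 + relax)
        return (_lgamma_ratio(x, r) - math.lgamma(x + 1.0)
                + x * math.log(p) + r * math.log1p(-p))
    xx = x if x > _FLOOR else _FLOOR
    if model == CSC or (model == CARC and relax <= _STRICT_TOL) or (
            model == CRC and relax <= _STRICT_TOL):
        a = mu * l
        return (a - 1.0) * math.log(xx) - xx - math.lgamma(a)
    if model == CRC:
        a = mu * mu * l / (mu + relax * l)
        s = 1.0 + relax * l / mu
        return (a - 1.0) * math.log(xx) - xx / s - math.lgamma(a) - a * math.log(s)
    # CARC
    a = mu * l / (1.0 + relax)
    s = 1.0 + relax
    return (a - 1.0) * math.log(xx) - xx / s - math.lgamma(a) - a * math.log(s)


@njit(cache=False)
def total_ll(parent, dates, x, model, mu, relax):
    tot = 0.0
    for v in range(dates.size):
        if parent[v] >= 0:
            tot += branch_ll(model, mu, relax, dates[v] - dates[parent[v]], x[v])
    return tot


@njit(cache=False)
def coal_logp(dates, is_tip, alpha):
    """Heterochronous constant-rate coalescent log-density of node dates.

    Sweeping from the latest event backwards: each interval with k active
    lineages contributes -k(k-1)/2 * dt / alpha, each coalescence a factor
    1/alpha (the rate of merging one specific pair).
    """
    n = dates.size
    order = np.argsort(dates)
    logp = 0.0
    k = 0
    prev = dates[order[n - 1]]
    for i in range(n - 1, -1, -1):
        t = dates[order[i]]
        dt = prev - t
        logp -= 0.5 * k * (k - 1) * dt / alpha
        if is_tip[order[i]]:
            k += 1
        else:
            logp -= math.log(alpha)
            k -= 1
        prev = t
    return logp


@njit(cache=False)
def gamma_logpdf(v, shape, scale):
    if v <= 0.0:
        return -math.inf
    return ((shape - 1.0) * math.log(v) - v / scale
            - math.lgamma(shape) - shape * math.log(scale))


@njit(cache=False)
def run_chain(parent, c1, c2, is_tip, dates, x, internals,
              model, mu, relax, alpha,
              mu_a, mu_s, rl_a, rl_s, al_mean,
              tree_prior, sample_dates, use_data,
              n_iter, thin, seed,
              out_dates, out_par, out_ll, out_lp):
    """One MH chain; mutates ``dates`` in place and fills the out arrays.

    tree_prior: 0 = coalescent(alpha) with Exponential(al_mean) hyperprior,
    1 = uniform on ordering-constrained dates. Proposal widths adapt during
    the first 20% of iterations (target 20-40% acceptance), then freeze.
    Records every ``thin``-th iteration. Returns the overall acceptance
    rates (node, mu, relax, alpha).
    """
    np.random.seed(seed)
    N = dates.size
    nI = internals.size
    relaxed = model == RC or model == ARC or model == CRC or model == CARC

    bll = np.zeros(N)
    if use_data == 1:
        for v in range(N):
            if parent[v] >= 0:
                bll[v] = branch_ll(model, mu, relax, dates[v] - dates[parent[v]], x[v])
    total = bll.sum()
    coal = coal_logp(dates, is_tip, alpha) if tree_prior == 0 else 0.0

    wnode = np.full(nI, 1.0)
    smu, srl, sal = 0.2, 0.4, 0.5
    acc_n = np.zeros(nI)
    try_n = np.zeros(nI)
    acc_p = np.zeros(3)
    try_p = np.zeros(3)
    acc_tot = np.zeros(4)
    try_tot = np.zeros(4)
    adapt_end = n_iter // 5
    tmp = np.zeros(N)
    rec = 0

    for it in range(n_iter):
        if sample_dates == 1:
            for ii in range(nI):
                v = internals[ii]
                d0 = dates[v]
                d1 = d0 + wnode[ii] * (2.0 * np.random.random() - 1.0)
                try_n[ii] += 1.0
                try_tot[0] += 1.0
                hi = min(dates[c1[v]], dates[c2[v]])
                if d1 > hi:
                    continue
                if parent[v] >= 0 and d1 < dates[parent[v]]:
                    continue
                delta = 0.0
                nb0 = nb1 = nb2 = 0.0
                if use_data == 1:
                    if parent[v] >= 0:
                        nb0 = branch_ll(model, mu, relax,
                                        d1 - dates[parent[v]], x[v])
                        delta += nb0 - bll[v]
                    nb1 = branch_ll(model, mu, relax, dates[c1[v]] - d1, x[c1[v]])
                    nb2 = branch_ll(model, mu, relax, dates[c2[v]] - d1, x[c2[v]])
                    delta += nb1 - bll[c1[v]] + nb2 - bll[c2[v]]
                ncoal = coal
                if tree_prior == 0:
                    dates[v] = d1
                    ncoal = coal_logp(dates, is_tip, alpha)
                    dates[v] = d0
                    delta += ncoal - coal
                if delta >= 0.0 or math.log(np.random.random()) < delta:
                    dates[v] = d1
                    if use_data == 1:
                        if parent[v] >= 0:
                            total += nb0 - bll[v]
                            bll[v] = nb0
                        total += nb1 - bll[c1[v]] + nb2 - bll[c2[v]]
                        bll[c1[v]] = nb1
                        bll[c2[v]] = nb2
                    coal = ncoal
                    acc_n[ii] += 1.0
                    acc_tot[0] += 1.0

        # mean-rate scale move
        u = 2.0 * np.random.random() - 1.0
        mu1 = mu * math.exp(smu * u)
        try_p[0] += 1.0
        try_tot[1] += 1.0
        delta = gamma_logpdf(mu1, mu_a, mu_s) - gamma_logpdf(mu, mu_a, mu_s) + smu * u
        ntot = total
        if use_data == 1:
            ntot = 0.0
            for v in range(N):
                if parent[v] >= 0:
                    tmp[v] = branch_ll(model, mu1, relax,
                                       dates[v] - dates[parent[v]], x[v])
                    ntot += tmp[v]
            delta += ntot - total
        if delta >= 0.0 or math.log(np.random.random()) < delta:
            mu = mu1
            if use_data == 1:
                for v in range(N):
                    if parent[v] >= 0:
                        bll[v] = tmp[v]
                total = ntot
            acc_p[0] += 1.0
            acc_tot[1] += 1.0

        # relaxation scale move
        if relaxed:
            u = 2.0 * np.random.random() - 1.0
            rl1 = relax * math.exp(srl * u)
            try_p[1] += 1.0
            try_tot[2] += 1.0
            delta = (gamma_logpdf(rl1, rl_a, rl_s)
                     - gamma_logpdf(relax, rl_a, rl_s) + srl * u)
            ntot = total
            if use_data == 1:
                ntot = 0.0
                for v in range(N):
                    if parent[v] >= 0:
                        tmp[v] = branch_ll(model, mu, rl1,
                                           dates[v] - dates[parent[v]], x[v])
                        ntot += tmp[v]
                delta += ntot - total
            if delta >= 0.0 or math.log(np.random.random()) < delta:
                relax = rl1
                if use_data == 1:
                    for v in range(N):
                        if parent[v] >= 0:
                            bll[v] = tmp[v]
                    total = ntot
                acc_p[1] += 1.0
                acc_tot[2] += 1.0

        # coalescent-parameter scale move
        if tree_prior == 0:
            u = 2.0 * np.random.random() - 1.0
            a1 = alpha * math.exp(sal * u)
            try_p[2] += 1.0
            try_tot[3] += 1.0
            ncoal = coal_logp(dates, is_tip, a1)
            delta = ncoal - coal - (a1 - alpha) / al_mean + sal * u
            if delta >= 0.0 or math.log(np.random.random()) < delta:
                alpha = a1
                coal = ncoal
                acc_p[2] += 1.0
                acc_tot[3] += 1.0

        # burn-in adaptation of proposal widths
        if it < adapt_end and (it + 1) % 50 == 0:
            for ii in range(nI):
                if try_n[ii] > 0:
                    r = acc_n[ii] / try_n[ii]
                    if r > 0.4:
                        wnode[ii] *= 1.4
                    elif r < 0.2:
                        wnode[ii] /= 1.4
                acc_n[ii] = 0.0
                try_n[ii] = 0.0
            for j in range(3):
                if try_p[j] > 0:
                    r = acc_p[j] / try_p[j]
                    if j == 0:
                        if r > 0.4:
                            smu *= 1.4
                        elif r < 0.2:
                            smu /= 1.4
                    elif j == 1:
                        if r > 0.4:
                            srl *= 1.4
                        elif r < 0.2:
                            srl /= 1.4
                    else:
                        if r > 0.4:
                            sal *= 1.4
                        elif r < 0.2:
                            sal /= 1.4
                acc_p[j] = 0.0
                try_p[j] = 0.0

        if (it + 1) % thin == 0:
            for ii in range(nI):
                out_dates[rec, ii] = dates[internals[ii]]
            out_par[rec, 0] = mu
            out_par[rec, 1] = relax
            out_par[rec, 2] = alpha
            if use_data == 1:
                # fresh summation: purges float drift from the incremental
                # updates so recorded log-likelihoods are exactly two-pass
                total = 0.0
                for v in range(N):
                    if parent[v] >= 0:
                        bll[v] = branch_ll(model, mu, relax,
                                           dates[v] - dates[parent[v]], x[v])
                        total += bll[v]
                out_ll[rec] = total
            else:
                out_ll[rec] = 0.0
            lp = coal + gamma_logpdf(mu, mu_a, mu_s)
            if relaxed:
                lp += gamma_logpdf(relax, rl_a, rl_s)
            if tree_prior == 0:
                lp += -math.log(al_mean) - alpha / al_mean
            out_lp[rec] = lp
            rec += 1

    rates = np.zeros(4)
    for j in range(4):
        if try_tot[j] > 0:
            rates[j] = acc_tot[j] / try_tot[j]
    return rates
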