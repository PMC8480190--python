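"""MCMC dating: posterior density, sampler correctness, summaries, rjMCMC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arcdating import (
    ClockParams,
    DatingState,
    Priors,
    branch_loglik,
    diagnostics,
    log_posterior,
    make_benchmark_dataset,
    read_newick,
    run_mcmc,
    run_rjmcmc,
    summarize,
)
from arcdating.bayes_dating import PosteriorTrace, _TreeData
from arcdating import _kernel


def single_branch_tree(x=12, tip="A_2010", unit="per_genome"):
    return read_newick(f"({tip}:{x});", unit=unit)


# ---------------------------------------------------------------------------
# log_posterior

def test_log_posterior_single_branch_sc():
    """With fixed dates, posterior - prior is exactly the Poisson term."""
    stree = single_branch_tree(x=12)
    priors = Priors(mu=(2.0, 1.0), tree_prior="uniform")
    state = DatingState(node_dates={"n0": 2000.0}, mu=1.3)
    lp = log_posterior(state, stree, "sc", priors)
    prior_term = stats.gamma(a=2.0, scale=1.0).logpdf(1.3)
    lik = branch_loglik(ClockParams("sc", mu=1.3), 10.0, 12)
    assert lp == pytest.approx(prior_term + lik, abs=1e-10)


def test_log_posterior_ordering_violation_is_minus_inf():
    stree = read_newick("(A_2010:3,B_2012:5);", unit="per_genome")
    state = DatingState(node_dates={"n0": 2015.0}, mu=1.0)  # after tip A
    assert log_posterior(state, stree, "sc") == -math.inf


def test_log_posterior_invalid_params_minus_inf():
    stree = single_branch_tree()
    state = DatingState(node_dates={"n0": 2000.0}, mu=-1.0)
    assert log_posterior(state, stree, "sc", Priors(tree_prior="uniform")) == -math.inf


def test_zero_length_polytomy_resolution_leaves_arc_posterior_unchanged():
    """A degree-2 zero-length resolution branch carries no information."""
    priors = Priors(tree_prior="uniform")
    p = ClockParams("arc", mu=2.0, omega=1.0)
    # unresolved star: three branches hanging off a single node at 2000
    want = (branch_loglik(p, 10.0, 3) + branch_loglik(p, 11.0, 4)
            + branch_loglik(p, 12.0, 5)
            + stats.gamma(a=priors.mu[0], scale=priors.mu[1]).logpdf(2.0)
            + stats.gamma(a=priors.relax[0], scale=priors.relax[1]).logpdf(1.0))
    # resolved by hand: (A,(B,C):0) with both internals at the same date
    resolved = read_newick("(A_2010:3,(B_2011:4,C_2012:5)inner:0);",
                           unit="per_genome")
    state = DatingState(node_dates={"n0": 2000.0, "inner": 2000.0},
                        mu=2.0, relax=1.0)
    lp_res = log_posterior(state, resolved, "arc", priors)
    assert lp_res == pytest.approx(want, abs=1e-10)


def test_kernel_likelihood_matches_reference(small_dataset):
    """The compiled likelihood agrees with the scipy-backed branch law."""
    _, stree = small_dataset
    td = _TreeData(stree)
    td.init_dates(5.0)
    for model, mu, relax in (("arc", 4.0, 2.0), ("rc", 5.0, 3.0),
                             ("sc", 5.0, 0.0), ("carc", 4.5, 1.5),
                             ("crc", 5.0, 2.5), ("csc", 5.0, 0.0)):
        kern = _kernel.total_ll(td.parent, td.dates, td.x,
                                _kernel.MODEL_CODES[model], mu, relax)
        params = {"arc": ClockParams("arc", mu=mu, omega=relax),
                  "rc": ClockParams("rc", mu=mu, sigma2=relax),
                  "sc": ClockParams("sc", mu=mu),
                  "carc": ClockParams("carc", mu=mu, omega=relax),
                  "crc": ClockParams("crc", mu=mu, sigma2=relax),
                  "csc": ClockParams("csc", mu=mu)}[model]
        ref = 0.0
        for v in range(td.n):
            if td.parent[v] >= 0:
                ref += branch_loglik(params, td.dates[v] - td.dates[td.parent[v]],
                                     td.x[v])
        assert kern == pytest.approx(ref, rel=1e-12)


def test_kernel_coalescent_prior_matches_reference(small_dataset):
    from arcdating.bayes_dating import _coal_logp_py

    _, stree = small_dataset
    td = _TreeData(stree)
    td.init_dates(5.0)
    for alpha in (1.0, 5.0, 20.0):
        assert _kernel.coal_logp(td.dates, td.is_tip, alpha) == pytest.approx(
            _coal_logp_py(td.dates, td.is_tip, alpha), rel=1e-12
        )


# ---------------------------------------------------------------------------
# run_mcmc

def test_prior_only_run_recovers_prior_quantiles():
    """With the data switched off, mu samples its Gamma(2,1) prior."""
    stree = single_branch_tree()
    priors = Priors(mu=(2.0, 1.0), tree_prior="uniform")
    tr = run_mcmc(stree, model="sc", priors=priors, n_iter=50_000, thin=5,
                  seed=4, fix_dates=True, use_data=False)
    post = tr.post_burnin()["mu"].to_numpy()
    prior = stats.gamma(a=2.0, scale=1.0)
    for q in (0.1, 0.25, 0.5, 0.75, 0.9):
        assert np.quantile(post, q) == pytest.approx(prior.ppf(q), rel=0.1)


def test_conjugate_posterior_single_branch():
    """Poisson likelihood x gamma prior: the posterior is gamma in closed form."""
    x, l = 30, 10.0
    stree = single_branch_tree(x=x)
    priors = Priors(mu=(2.0, 1.0), tree_prior="uniform")
    tr = run_mcmc(stree, model="sc", priors=priors, n_iter=50_000, thin=5,
                  seed=5, fix_dates=True, init={"dates": {"n0": 2000.0}})
    post = tr.post_burnin()["mu"].to_numpy()
    truth = stats.gamma(a=2.0 + x, scale=1.0 / (1.0 + l))
    sd = truth.std()
    for q in (0.025, 0.5, 0.975):
        assert abs(np.quantile(post, q) - truth.ppf(q)) < 0.15 * sd


def test_mcmc_determinism(small_dataset):
    _, stree = small_dataset
    a = run_mcmc(stree, model="arc", n_iter=2000, seed=17)
    b = run_mcmc(stree, model="arc", n_iter=2000, seed=17)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_mcmc_rejects_tiny_runs(small_dataset):
    _, stree = small_dataset
    with pytest.raises(ValueError, match="burn-in"):
        run_mcmc(stree, model="arc", n_iter=500)


def test_mcmc_requires_genome_units():
    stree = read_newick("(A_2010:0.001,B_2012:0.002);")  # per_site
    with pytest.raises(ValueError, match="per-genome"):
        run_mcmc(stree, model="arc", n_iter=2000)


def test_identical_tip_dates_warn():
    stree = read_newick("(A_2010:3,B_2010:5);", unit="per_genome")
    with pytest.warns(UserWarning, match="identifiable"):
        run_mcmc(stree, model="sc", n_iter=2000, seed=1)


def test_recorded_loglik_matches_independent_recomputation(small_dataset):
    """Spot-check trace rows against the scipy-backed likelihood."""
    _, stree = small_dataset
    tr = run_mcmc(stree, model="arc", n_iter=2000, seed=3)
    td = _TreeData(stree)
    params_cols = [f"date_{lab}" for lab in tr.extra["internal_labels"]]
    for ridx in (len(tr.df) // 2, len(tr.df) - 1):
        row = tr.df.iloc[ridx]
        for lab, col in zip(tr.extra["internal_labels"], params_cols):
            td.dates[td.labels.index(lab)] = row[col]
        p = ClockParams("arc", mu=row["mu"], omega=row["omega"])
        ref = 0.0
        for v in range(td.n):
            if td.parent[v] >= 0:
                ref += branch_loglik(p, td.dates[v] - td.dates[td.parent[v]],
                                     td.x[v])
        assert row["loglik"] == pytest.approx(ref, rel=1e-10)


def test_posterior_recovers_truth_on_small_data(small_dataset):
    ttree, stree = small_dataset  # omega=2, mu=5
    tr = run_mcmc(stree, model="arc", n_iter=20_000, seed=8)
    s = summarize(tr)
    assert s.loc["mu", "q025"] < 5.0 < s.loc["mu", "q975"]
    assert (s.loc["tmrca", "q025"] - 5 < ttree.root_date
            < s.loc["tmrca", "q975"] + 5)


# ---------------------------------------------------------------------------
# summaries

def constant_trace(value=3.0, n=400):
    df = pd.DataFrame({
        "iteration": np.arange(n), "loglik": np.zeros(n),
        "logprior": np.zeros(n), "mu": np.full(n, value),
        "tmrca": np.full(n, 2000.0),
    })
    return PosteriorTrace(df, model="sc", seed=0, n_iter=n, thin=1)


def test_summarize_constant_trace():
    s = summarize(constant_trace())
    assert s.loc["mu", "mean"] == 3.0
    assert s.loc["mu", "ci_length"] == 0.0


def test_summarize_normal_draws():
    n = 40_000
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "iteration": np.arange(n), "loglik": np.zeros(n),
        "logprior": np.zeros(n), "mu": rng.standard_normal(n),
        "tmrca": np.zeros(n),
    })
    s = summarize(PosteriorTrace(df, model="sc", seed=0, n_iter=n, thin=1))
    assert s.loc["mu", "q025"] == pytest.approx(-1.96, abs=0.06)
    assert s.loc["mu", "q975"] == pytest.approx(1.96, abs=0.06)


def test_summarize_thinning_invariance(small_dataset):
    _, stree = small_dataset
    tr = run_mcmc(stree, model="arc", n_iter=20_000, thin=2, seed=9)
    s1 = summarize(tr)
    thinned = PosteriorTrace(tr.df.iloc[::4].reset_index(drop=True),
                             model=tr.model, seed=tr.seed, n_iter=tr.n_iter,
                             thin=tr.thin * 4, relax_name=tr.relax_name)
    s2 = summarize(thinned)
    assert s2.loc["mu", "mean"] == pytest.approx(s1.loc["mu", "mean"], abs=0.2)
    assert s2.loc["tmrca", "ci_length"] == pytest.approx(
        s1.loc["tmrca", "ci_length"], rel=0.25)


def test_summarize_empty_trace_errors():
    tr = constant_trace(n=10)
    with pytest.raises(ValueError):
        summarize(tr)


# ---------------------------------------------------------------------------
# diagnostics

def iid_trace(n=4000, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "iteration": np.arange(n), "loglik": np.zeros(n),
        "logprior": np.zeros(n), "mu": rng.standard_normal(n),
        "tmrca": rng.standard_normal(n),
    })
    return PosteriorTrace(df, model="sc", seed=seed, n_iter=n, thin=1,
                          burn_frac=0.0)


def test_ess_of_iid_samples_is_about_n():
    d = diagnostics(iid_trace(4000))
    assert d.loc["mu", "ess"] == pytest.approx(4000, rel=0.2)


def test_psrf_of_identical_chains_is_one():
    # split-R-hat still splits each chain in half, so two byte-identical
    # stationary chains sit at 1 only up to the half-vs-half wobble
    tr = iid_trace(2000, seed=1)
    d = diagnostics([tr, tr])
    assert d.loc["mu", "psrf"] == pytest.approx(1.0, abs=0.02)


def test_ar1_ess_closed_form():
    rho, n = 0.9, 40_000
    rng = np.random.default_rng(2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n) * math.sqrt(1 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    df = pd.DataFrame({"iteration": np.arange(n), "loglik": np.zeros(n),
                       "logprior": np.zeros(n), "mu": x, "tmrca": x})
    tr = PosteriorTrace(df, model="sc", seed=0, n_iter=n, thin=1, burn_frac=0.0)
    d = diagnostics(tr)
    expect = n * (1 - rho) / (1 + rho)
    assert d.loc["mu", "ess"] == pytest.approx(expect, rel=0.25)


def test_unequal_chains_truncated_with_warning():
    t1, t2 = iid_trace(2000, 1), iid_trace(1000, 2)
    with pytest.warns(UserWarning, match="truncat"):
        d = diagnostics([t1, t2])
    assert np.isfinite(d.loc["mu", "psrf"])


# ---------------------------------------------------------------------------
# reversible jump

@pytest.fixture(scope="module")
def continuous_datasets():
    """Continuous-length datasets from the cSC and cARC branch laws.

    The nested strict-vs-relaxed comparison is defined for the continuous
    models, whose observations are positive reals (no exact-zero branch
    lengths, which the floored gamma densities cannot rank fairly).
    """
    out = {}
    for name, clock in (("strict", ClockParams("csc", mu=5.0)),
                        ("relaxed", ClockParams("carc", mu=5.0, omega=5.0))):
        sets = []
        for seed in range(5):
            _, stree = make_benchmark_dataset(0.0, seed=100 + seed, n_tips=25,
                                              clock=clock)
            sets.append(stree)
        out[name] = sets
    return out


def test_rjmcmc_prefers_strict_on_strict_data(continuous_datasets):
    wins = 0
    for seed, stree in enumerate(continuous_datasets["strict"]):
        _, bf = run_rjmcmc(stree, n_iter=4000, seed=seed)
        if bf > 1:
            wins += 1
    assert wins >= 3  # majority of runs


def test_rjmcmc_prefers_relaxed_on_relaxed_data(continuous_datasets):
    wins = 0
    for seed, stree in enumerate(continuous_datasets["relaxed"]):
        _, bf = run_rjmcmc(stree, n_iter=4000, seed=seed)
        if bf < 1:
            wins += 1
    assert wins >= 3


def test_rjmcmc_indicator_frequencies_sum_to_one(continuous_datasets):
    trace, _ = run_rjmcmc(continuous_datasets["strict"][0], n_iter=3000, seed=0)
    ind = trace.post_burnin()["model_indicator"]
    freq = ind.value_counts(normalize=True)
    assert freq.sum() == pytest.approx(1.0)
    assert set(freq.index) <= {0.0, 1.0}
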