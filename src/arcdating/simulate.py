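"""Simulation of dated trees, branch substitution counts, and alignments.

The generator mirrors a standard genomic-epidemiology benchmark design:
``n`` genomes sampled serially through time, genealogy drawn from the
heterochronous coalescent with constant pairwise coalescence rate
``1/alpha`` (``alpha = Ne * g``, the expected coalescence time of any two
lineages), substitutions laid on branches by one of the six clock models,
and optionally Jukes-Cantor sequences evolved along the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .clock_models import ClockModel, ClockParams, sample_rate, sample_substitutions
from .timetree import SubstTree, TimeTree

__all__ = [
    "SimConfig",
    "coalescent_node_times",
    "sample_coalescent_tree",
    "simulate_observed_tree",
    "simulate_alignment",
    "make_benchmark_dataset",
    "alignment_to_fasta",
]

#: benchmark defaults: 100 genomes of 10 kb sampled regularly 2010-2020,
#: alpha = 5 years, mean rate mu = 5 substitutions/genome/year
BENCHMARK_N_TIPS = 100
BENCHMARK_DATE_RANGE = (2010.0, 2020.0)
BENCHMARK_ALPHA = 5.0
BENCHMARK_MU = 5.0
BENCHMARK_GENOME_LENGTH = 10_000


@dataclass
class SimConfig:
    """Parameters of one simulated dataset."""

    n_tips: int
    sampling_dates: list[float]
    alpha: float
    clock: ClockParams
    genome_length: int = BENCHMARK_GENOME_LENGTH
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if len(self.sampling_dates) != self.n_tips:
            raise ValueError("sampling_dates must have length n_tips")
        if self.genome_length is not None and not self.genome_length > 0:
            raise ValueError("genome_length must be > 0")


def _coalescent_events(sampling_dates: np.ndarray, alpha: float,
                       rng: np.random.Generator):
    """Backward-in-time sweep of the heterochronous coalescent.

    With ``k`` active lineages the waiting time to the next coalescence is
    exponential with rate ``k(k-1)/(2*alpha)``; lineages activate (looking
    backwards) at their sampling dates. Yields coalescence times in
    decreasing date order; the last one is the TMRCA.
    """
    dates = np.sort(np.asarray(sampling_dates, dtype=float))[::-1]
    n = dates.size
    coal_times = np.empty(n - 1)
    t = dates[0]
    k = 1
    next_tip = 1
    while next_tip < n and dates[next_tip] == t:
        k += 1
        next_tip += 1
    i = 0
    while i < n - 1:
        if k >= 2:
            wait = rng.exponential(2.0 * alpha / (k * (k - 1)))
            t_coal = t - wait
        else:
            t_coal = -np.inf
        if next_tip < n and dates[next_tip] >= t_coal:
            t = dates[next_tip]
            k += 1
            next_tip += 1
        else:
            t = t_coal
            coal_times[i] = t
            k -= 1
            i += 1
    return coal_times


def coalescent_node_times(sampling_dates, alpha: float, seed=None) -> np.ndarray:
    """Coalescence (internal node) dates for one genealogy draw.

    Lightweight core used both by :func:`sample_coalescent_tree` and by
    Monte-Carlo checks of closed-form TMRCA expectations (E[depth] = alpha
    for two contemporaneous tips; 2*alpha*(1-1/n) for n).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _coalescent_events(np.asarray(sampling_dates, float), alpha, rng)


def sample_coalescent_tree(config: SimConfig, seed=None) -> TimeTree:
    """Draw a dated binary genealogy from the heterochronous coalescent.

    Tip labels are ``t<i>_<date>`` so that sampling dates can be recovered
    from labels alone. Returns a :class:`TimeTree` with ``n_tips - 1``
    internal nodes whose dates respect the parent-before-child ordering.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dates = np.sort(np.asarray(config.sampling_dates, dtype=float))[::-1]
    coal_times = _coalescent_events(dates, config.alpha, rng)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes = []
    for i, d in enumerate(dates):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(f"t{i:03d}_{d:.6f}")
        node.date = float(d)
        nodes.append(node)

    # replay the event sweep: merge a uniformly chosen active pair at each
    # coalescence time (pair choice is independent of the waiting times)
    active = [nodes[0]]
    next_tip = 1
    while next_tip < dates.size and dates[next_tip] == dates[0]:
        active.append(nodes[next_tip])
        next_tip += 1
    for t in coal_times:
        while next_tip < dates.size and dates[next_tip] >= t:
            active.append(nodes[next_tip])
            next_tip += 1
        i, j = rng.choice(len(active), size=2, replace=False)
        parent = dendropy.Node()
        parent.date = float(t)
        parent.add_child(active[i])
        parent.add_child(active[j])
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(parent)
    assert len(active) == 1
    tree.seed_node = active[0]
    return TimeTree(tree)


def simulate_observed_tree(timetree: TimeTree, clock: ClockParams,
                           seed=None) -> SubstTree:
    """Simulate observed per-genome branch lengths under a clock model.

    For the discrete additive relaxed clock this follows the generative
    two-stage recipe: draw the branch rate m_i ~ Gamma(mu*l_i/omega,
    omega/l_i), then x_i ~ Poisson(m_i*l_i). All other models draw x_i
    from the branch law directly (the two routes are equivalent for ARC;
    the explicit rate stage is kept because it is the natural mechanism).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    timetree.sync_edge_lengths()
    dtree = timetree.tree.clone(depth=1)
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        l = node.edge.length or 0.0
        if clock.model is ClockModel.ARC and clock.omega > 0 and l > 0:
            m = sample_rate(clock, l, rng)
            x = float(rng.poisson(m * l))
        else:
            x = float(sample_substitutions(clock, l, rng))
        node.edge.length = x
    tip_dates = {leaf.taxon.label: leaf.date for leaf in timetree.tree.leaf_node_iter()}
    return SubstTree(dtree, unit="per_genome", tip_dates=tip_dates)


_NUC = np.frombuffer(b"ACGT", dtype="S1")


def simulate_alignment(timetree: TimeTree, clock: ClockParams,
                       genome_length: int, seed=None) -> dict[str, str]:
    """Evolve Jukes-Cantor sequences along a dated tree.

    The root sequence is uniform over {A,C,G,T}. On each branch the
    expected number of substitutions per site is d = m_i*l_i/L with m_i the
    branch's realized clock rate (x_i/L for cARC, which defines counts
    directly); each site then differs from its parent with probability
    ``(3/4)(1 - exp(-4d/3))`` and, if it changes, picks one of the other
    three bases uniformly — the JC transition law.
    """
    if not genome_length > 0:
        raise ValueError("genome_length must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    timetree.sync_edge_lengths()
    L = int(genome_length)
    root_seq = rng.integers(0, 4, size=L)
    seqs: dict[str, str] = {}
    stack = [(timetree.tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            l = child.edge.length or 0.0
            if clock.model is ClockModel.cARC:
                x = float(sample_substitutions(clock, l, rng))
                d = x / L
            else:
                m = sample_rate(clock, l, rng) if l > 0 else clock.mu
                d = m * l / L
            p_diff = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            cseq = seq.copy()
            hit = rng.random(L) < p_diff
            # uniform over the three other bases
            cseq[hit] = (cseq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = cseq
            else:
                stack.append((child, cseq))
    return {lab: b"".join(_NUC[s]).decode() for lab, s in
            ((lab, seqs[lab]) for lab in sorted(seqs))}


def alignment_to_fasta(alignment: dict[str, str]) -> str:
    return "".join(f">{lab}\n{seq}\n" for lab, seq in alignment.items())


def make_benchmark_dataset(omega: float, seed=None, with_alignment: bool = False,
                           n_tips: int = BENCHMARK_N_TIPS,
                           mu: float = BENCHMARK_MU,
                           alpha: float = BENCHMARK_ALPHA,
                           date_range: tuple[float, float] = BENCHMARK_DATE_RANGE,
                           genome_length: int = BENCHMARK_GENOME_LENGTH,
                           clock: ClockParams | None = None):
    """One benchmark dataset: serially sampled ARC-clocked genealogy.

    ``n_tips`` genomes sampled at regular intervals across ``date_range``
    (both endpoints included), genealogy from the heterochronous coalescent
    with the given ``alpha``, and per-genome substitution counts from the
    discrete additive relaxed clock with mean rate ``mu`` and relaxation
    ``omega`` (omega = 0 reduces to the strict clock). A different branch
    law can be substituted via ``clock`` (e.g. the continuous models for
    reversible-jump studies), in which case ``omega`` and ``mu`` are
    ignored. Returns ``(TimeTree, SubstTree)``, plus a JC alignment dict
    if requested.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dates = list(np.linspace(date_range[0], date_range[1], n_tips))
    if clock is None:
        clock = ClockParams(ClockModel.ARC, mu=mu, omega=float(omega))
    config = SimConfig(n_tips=n_tips, sampling_dates=dates, alpha=alpha,
                       clock=clock, genome_length=genome_length)
    ttree = sample_coalescent_tree(config, seed=rng)
    stree = simulate_observed_tree(ttree, clock, seed=rng)
    stree.genome_length = genome_length
    if with_alignment:
        aln = simulate_alignment(ttree, clock, genome_length, seed=rng)
        return ttree, stree, aln
    return ttree, stree
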