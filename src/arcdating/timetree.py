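"""Tree containers and I/O: dated trees, substitution trees, tip dates.

Two views of the same rooted topology are used throughout:

- :class:`TimeTree` — every node carries a calendar date in decimal years
  (2010.5 = mid-2010); branch lengths are durations ``l_i = date(child) -
  date(parent)`` and must be non-negative.
- :class:`SubstTree` — branch lengths are observed substitutions, either
  per site (as standard phylogenetic software reports them) or per genome;
  tips additionally carry sampling dates.

Newick I/O is delegated to dendropy; underscores in labels are preserved
verbatim (no space conversion).
"""

from __future__ import annotations

import io
import logging
import re
from typing import Callable, Mapping

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "SubstTree",
    "read_newick",
    "write_newick",
    "read_date_table",
    "to_genome_units",
    "root_to_tip",
    "branch_durations",
    "resolve_polytomies",
]

logger = logging.getLogger(__name__)


def _load_tree(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"could not parse Newick input: {exc}") from exc
    if tree.seed_node is None or not tree.leaf_nodes():
        raise ValueError("empty tree")
    return tree


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen, dups = set(), set()
    for lab in labels:
        if lab in seen:
            dups.add(lab)
        seen.add(lab)
    if dups:
        raise ValueError(f"duplicate tip labels: {sorted(dups)}")
    return labels


class SubstTree:
    """Rooted tree with branch lengths in substitution units.

    Parameters
    ----------
    tree:
        dendropy tree; edge lengths are substitutions (missing lengths are
        treated as 0).
    unit:
        ``"per_site"`` or ``"per_genome"``.
    genome_length:
        Genome length in bp, used by :func:`to_genome_units`.
    tip_dates:
        Mapping from tip label to sampling date in decimal years.
    """

    def __init__(self, tree, unit="per_site", genome_length=None, tip_dates=None):
        if unit not in ("per_site", "per_genome"):
            raise ValueError(f"unknown unit {unit!r}")
        self.tree = tree
        self.unit = unit
        self.genome_length = genome_length
        self.tip_dates = dict(tip_dates) if tip_dates else {}
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                edge.length = 0.0
        _tip_labels(tree)

    @property
    def tip_labels(self) -> list[str]:
        return _tip_labels(self.tree)

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def copy(self) -> "SubstTree":
        return SubstTree(
            self.tree.clone(depth=1), self.unit, self.genome_length, self.tip_dates
        )


class TimeTree:
    """Rooted tree with a calendar date (decimal years) at every node.

    Every node of the wrapped dendropy tree must have a ``date`` attribute;
    edge lengths are kept in sync as durations in years. Child dates may
    never precede their parent's date.
    """

    def __init__(self, tree):
        self.tree = tree
        for node in tree.preorder_node_iter():
            if getattr(node, "date", None) is None:
                raise ValueError("every node of a TimeTree needs a date")
        self.sync_edge_lengths()
        _tip_labels(tree)

    def sync_edge_lengths(self) -> None:
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                dur = node.date - node.parent_node.date
                if dur < -1e-9:
                    name = node.taxon.label if node.taxon else (node.label or "<internal>")
                    raise ValueError(
                        f"node {name} dated {node.date} before its parent "
                        f"({node.parent_node.date})"
                    )
                node.edge.length = max(dur, 0.0)

    @property
    def root_date(self) -> float:
        return self.tree.seed_node.date

    #: the root date is the time of the most recent common ancestor
    tmrca = root_date

    @property
    def tip_dates(self) -> dict[str, float]:
        return {leaf.taxon.label: leaf.date for leaf in self.tree.leaf_node_iter()}

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def copy(self) -> "TimeTree":
        return TimeTree(self.tree.clone(depth=1))


# ---------------------------------------------------------------------------
# tip-date handling

def read_date_table(text: str) -> dict[str, float]:
    """Parse a two-column (label, decimal year) table, tab/comma separated.

    A header row is detected and skipped if its second field is not numeric.
    """
    dates: dict[str, float] = {}
    rows = [ln for ln in io.StringIO(text) if ln.strip()]
    for i, line in enumerate(rows):
        parts = re.split(r"[\t,]", line.strip())
        if len(parts) < 2:
            raise ValueError(f"date table line {i + 1} has fewer than 2 columns")
        try:
            dates[parts[0].strip()] = float(parts[1])
        except ValueError:
            if i == 0:
                continue  # header
            raise ValueError(f"non-numeric date {parts[1]!r} on line {i + 1}")
    return dates


def _date_extractor(date_spec) -> Callable[[str], float | None]:
    """Build a label -> date function from a date_spec.

    date_spec may be: None or "trailing" (last ``_``-separated field);
    a dict with ``delimiter``/``field`` (0-based index, negative allowed);
    a dict with ``regex`` (first capture group); a mapping label -> year;
    or a two-column table string (via ``{"table": text}``).
    """
    if date_spec is None or date_spec == "trailing":
        date_spec = {"delimiter": "_", "field": -1}
    if isinstance(date_spec, Mapping) and "table" in date_spec:
        date_spec = read_date_table(date_spec["table"])
    if isinstance(date_spec, Mapping) and "regex" in date_spec:
        pat = re.compile(date_spec["regex"])

        def from_regex(label: str):
            m = pat.search(label)
            return float(m.group(1)) if m else None

        return from_regex
    if isinstance(date_spec, Mapping) and "delimiter" in date_spec:
        delim = date_spec["delimiter"]
        field = int(date_spec.get("field", -1))

        def from_field(label: str):
            parts = label.split(delim)
            try:
                return float(parts[field])
            except (IndexError, ValueError):
                return None

        return from_field
    if isinstance(date_spec, Mapping):
        table = {str(k): float(v) for k, v in date_spec.items()}
        return lambda label: table.get(label)
    raise ValueError(f"unsupported date_spec: {date_spec!r}")


def read_newick(text: str, date_spec="trailing", unit="per_site",
                genome_length=None) -> SubstTree:
    """Read a Newick tree and resolve a sampling date for every tip.

    Branch lengths are preserved exactly. ``date_spec`` controls how tip
    dates are found (see :func:`_date_extractor`); a tip whose date cannot
    be resolved raises an error naming it.
    """
    tree = _load_tree(text)
    extract = _date_extractor(date_spec)
    dates = {}
    for label in _tip_labels(tree):
        d = extract(label)
        if d is None:
            raise ValueError(f"no sampling date could be resolved for tip {label!r}")
        dates[label] = d
    return SubstTree(tree, unit=unit, genome_length=genome_length, tip_dates=dates)


def write_newick(tree) -> str:
    """Serialize a tree to Newick at full precision.

    ``TimeTree`` inputs are written with node dates encoded as branch
    lengths in years; ``SubstTree`` (or bare dendropy trees) are written
    as-is.
    """
    if isinstance(tree, TimeTree):
        tree.sync_edge_lengths()
        dtree = tree.tree
    elif isinstance(tree, SubstTree):
        dtree = tree.tree
    else:
        dtree = tree
    if (dtree is None or dtree.seed_node is None
            or not dtree.seed_node.child_nodes()):
        raise ValueError("cannot write an empty tree")
    out = dtree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    return out.strip() + "\n"


# ---------------------------------------------------------------------------
# unit conversion and distances

def to_genome_units(stree: SubstTree, genome_length: float,
                    rounding: str = "nearest") -> SubstTree:
    """Convert per-site branch lengths to per-genome substitution counts.

    ``rounding="nearest"`` rounds to integers (ties, i.e. exact halves,
    round away from zero) as required before discrete-model likelihoods;
    ``rounding="none"`` keeps fractional lengths for continuous models.
    """
    if stree.unit == "per_genome":
        raise ValueError("tree is already in per-genome units")
    if not genome_length > 0:
        raise ValueError("genome_length must be > 0")
    if rounding not in ("nearest", "none"):
        raise ValueError(f"unknown rounding {rounding!r}")
    out = stree.copy()
    for edge in out.tree.preorder_edge_iter():
        if edge.length is None:
            continue
        val = edge.length * genome_length
        if rounding == "nearest":
            val = float(np.floor(val + 0.5))  # half away from zero (val >= 0)
        edge.length = val
    out.unit = "per_genome"
    out.genome_length = genome_length
    return out


def root_to_tip(stree: SubstTree) -> dict[str, float]:
    """Sum of branch lengths on each root-to-tip path."""
    tree = stree.tree if isinstance(stree, SubstTree) else stree
    dists: dict[str, float] = {}
    acc = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            acc[node] = acc[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            dists[node.taxon.label] = acc[node]
    return dists


def branch_durations(ttree: TimeTree) -> list[tuple[str, float]]:
    """Per-branch durations ``l_i = date(child) - date(parent)`` in years.

    Branches are identified by their child node (tip label, or a stable
    preorder index for unlabeled internal nodes). Raises if any child is
    dated before its parent, naming the offending node.
    """
    out = []
    for i, node in enumerate(ttree.tree.preorder_node_iter()):
        if node.parent_node is None:
            continue
        name = node.taxon.label if node.taxon else (node.label or f"node{i}")
        dur = node.date - node.parent_node.date
        if dur < 0:
            raise ValueError(
                f"node {name} dated {node.date} before its parent "
                f"({node.parent_node.date})"
            )
        out.append((name, dur))
    return out


def resolve_polytomies(stree: SubstTree, seed=None) -> SubstTree:
    """Arbitrarily resolve polytomies into binary nodes with zero branches.

    Under additive clock models the likelihood is unchanged by inserting
    zero-length branches, so the resolution is harmless there; a notice is
    logged because it does matter under the non-additive RC/cRC models.
    """
    out = stree.copy()
    had = any(len(n.child_nodes()) > 2 for n in out.tree.preorder_node_iter())
    if had:
        rng = np.random.default_rng(seed)
        out.tree.resolve_polytomies(rng=_DendropyRng(rng))
        for edge in out.tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
        logger.info("polytomies resolved arbitrarily with zero-length branches")
    return out


class _DendropyRng:
    """Adapter exposing random.Random's sample() on a numpy Generator."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def sample(self, seq, k):
        idx = self.rng.choice(len(seq), size=k, replace=False)
        return [seq[i] for i in idx]

    def choice(self, seq):
        return seq[int(self.rng.integers(len(seq)))]

    def shuffle(self, seq):
        self.rng.shuffle(seq)
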