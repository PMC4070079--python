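"""Discrete Bayesian networks: representation, validation, sampling and I/O.

A network is a DAG over categorical variables together with one conditional
probability table (CPT) per node.  The CPT of a node with ``r`` levels and
parents with level counts ``(r_1, ..., r_d)`` is stored as an array of shape
``(q, r)`` with ``q = r_1 * ... * r_d`` rows, one per joint parent
configuration in mixed-radix order (last parent varying fastest, matching
:func:`numpy.ravel_multi_index` on the parent level indices).

Datasets are plain :class:`pandas.DataFrame` objects whose columns are
categorical; :func:`encode_dataset` is the validating boundary between the
string world and the integer-coded arrays used by the learners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CategoricalVariable",
    "CPT",
    "DiscreteBayesianNetwork",
    "InvalidNetworkError",
    "validate_network",
    "param_count",
    "possible_edge_count",
    "forward_sample",
    "random_network",
    "encode_dataset",
    "canonical_pairs",
]

_CPT_ROW_TOL = 1e-9


class InvalidNetworkError(ValueError):
    """Raised when an operation requires a valid network and gets violations."""


@dataclass(frozen=True)
class CategoricalVariable:
    """A named discrete variable with an ordered set of category labels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))

    @property
    def cardinality(self) -> int:
        return len(self.levels)


@dataclass
class CPT:
    """Conditional probability table P(node | parents).

    ``table[j, k]`` is P(node = level k | parent configuration j), where j
    ravels the parents' level indices in the order given by ``parents``.
    """

    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim == 1:
            self.table = self.table[None, :]


@dataclass
class DiscreteBayesianNetwork:
    variables: list[CategoricalVariable]
    cpts: dict[str, CPT] = field(default_factory=dict)

    @property
    def node_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Directed (parent, child) pairs implied by the CPT parent sets."""
        out: set[tuple[str, str]] = set()
        for child, cpt in self.cpts.items():
            for p in cpt.parents:
                out.add((p, child))
        return out

    def variable(self, name: str) -> CategoricalVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; raises InvalidNetworkError on a cycle."""
        parents = {v.name: set(self.cpts[v.name].parents) if v.name in self.cpts else set()
                   for v in self.variables}
        order: list[str] = []
        ready = sorted(n for n, ps in parents.items() if not ps)
        remaining = {n: set(ps) for n, ps in parents.items()}
        while ready:
            n = ready.pop(0)
            order.append(n)
            newly = []
            for m, ps in remaining.items():
                if n in ps:
                    ps.discard(n)
                    if not ps and m not in order and m not in ready:
                        newly.append(m)
            ready.extend(sorted(newly))
        if len(order) != len(self.variables):
            raise InvalidNetworkError("edge set contains a directed cycle")
        return order


def validate_network(net: DiscreteBayesianNetwork) -> list[str]:
    """Return a list of invariant violations; empty iff the network is valid.

    Reports (rather than raises) so callers can surface every problem at once:
    duplicate names, empty/duplicate level sets, cycles, CPT shape mismatches
    and CPT rows that do not sum to one within 1e-9.
    """
    problems: list[str] = []
    names = [v.name for v in net.variables]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            problems.append(f"duplicate variable name {n!r}")
        seen.add(n)
    for v in net.variables:
        if len(v.levels) < 2:
            problems.append(f"variable {v.name!r} has fewer than 2 levels")
        if len(set(v.levels)) != len(v.levels):
            problems.append(f"variable {v.name!r} has duplicate levels")

    card = {v.name: v.cardinality for v in net.variables}
    for child in names:
        if child not in net.cpts:
            problems.append(f"node {child!r} has no CPT")
            continue
        cpt = net.cpts[child]
        unknown = [p for p in cpt.parents if p not in card]
        if unknown:
            problems.append(f"CPT of {child!r} references undeclared parents {unknown}")
            continue
        q = int(np.prod([card[p] for p in cpt.parents], dtype=np.int64)) if cpt.parents else 1
        r = card[child]
        if cpt.table.shape != (q, r):
            problems.append(
                f"CPT of {child!r} has shape {cpt.table.shape}, expected ({q}, {r})"
            )
            continue
        sums = cpt.table.sum(axis=1)
        for j in np.nonzero(np.abs(sums - 1.0) > _CPT_ROW_TOL)[0]:
            problems.append(
                f"CPT row {int(j)} of {child!r} sums to {sums[j]:.10g}, not 1"
            )
        if np.any(cpt.table < -_CPT_ROW_TOL):
            problems.append(f"CPT of {child!r} contains negative probabilities")

    extra = set(net.cpts) - set(names)
    for child in sorted(extra):
        problems.append(f"CPT for undeclared variable {child!r}")

    try:
        net.topological_order()
    except InvalidNetworkError:
        problems.append("edge set contains a directed cycle")
    return problems


def _require_valid(net: DiscreteBayesianNetwork) -> None:
    problems = validate_network(net)
    if problems:
        raise InvalidNetworkError("; ".join(problems))


def param_count(net: DiscreteBayesianNetwork) -> int:
    """Number of free parameters: sum over nodes of (r - 1) * q.

    This is the ``p`` of the n/p sample-size-to-parameters ratio used to
    normalise difficulty across networks of different sizes.
    """
    _require_valid(net)
    card = {v.name: v.cardinality for v in net.variables}
    total = 0
    for child, cpt in net.cpts.items():
        q = int(np.prod([card[p] for p in cpt.parents], dtype=np.int64)) if cpt.parents else 1
        total += (card[child] - 1) * q
    return total


def possible_edge_count(num_nodes: int) -> int:
    """N(N-1)/2 unordered node pairs, the number of possible edges."""
    if num_nodes < 1:
        raise ValueError(f"num_nodes must be >= 1, got {num_nodes}")
    return num_nodes * (num_nodes - 1) // 2


def canonical_pairs(nodes) -> list[tuple[str, str]]:
    """All unordered pairs, each sorted lexicographically, in sorted order."""
    ns = sorted(nodes)
    return [(a, b) for i, a in enumerate(ns) for b in ns[i + 1:]]


def forward_sample(net: DiscreteBayesianNetwork, n: int, seed) -> pd.DataFrame:
    """Draw ``n`` i.i.d. observations by ancestral (topological-order) sampling.

    Returns a DataFrame of categorical columns in the network's variable order;
    deterministic given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    _require_valid(net)
    rng = np.random.default_rng(seed)
    order = net.topological_order()
    card = {v.name: v.cardinality for v in net.variables}
    codes: dict[str, np.ndarray] = {}
    for name in order:
        cpt = net.cpts[name]
        r = card[name]
        if not cpt.parents:
            probs = np.broadcast_to(cpt.table[0], (n, r))
        else:
            dims = [card[p] for p in cpt.parents]
            if n:
                cfg = np.ravel_multi_index(
                    tuple(codes[p] for p in cpt.parents), dims
                )
            else:
                cfg = np.zeros(0, dtype=np.intp)
            probs = cpt.table[cfg]
        # inverse-CDF draw, vectorised over rows
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        codes[name] = np.minimum(
            (u[:, None] > cum).sum(axis=1), r - 1
        ).astype(np.intp)
    data = {}
    for v in net.variables:
        data[v.name] = pd.Categorical.from_codes(
            codes[v.name], categories=list(v.levels)
        )
    return pd.DataFrame(data)


def random_network(
    num_nodes: int,
    avg_neighbours: float = 2.5,
    levels_per_node: int = 2,
    cpt_concentration: float = 0.5,
    seed=None,
) -> DiscreteBayesianNetwork:
    """Sample a random discrete Bayesian network fixture.

    Nodes are ordered uniformly at random and each forward pair (i, j) with
    i before j becomes an edge independently with probability
    ``avg_neighbours / (num_nodes - 1)``, so the expected average degree is
    ``avg_neighbours`` (expected edge count ``avg_neighbours * num_nodes / 2``).
    The default density of 2.5 neighbours per node matches the sparse
    benchmark networks used in structure-learning studies (1.2-1.9 edges per
    node).  CPT rows are drawn from a symmetric Dirichlet; the default
    concentration 0.5 favours peaked rows, i.e. learnable dependencies.
    """
    if num_nodes < 1:
        raise ValueError("num_nodes must be >= 1")
    if num_nodes > 1 and not (0 <= avg_neighbours < num_nodes - 1 + 1e-12):
        raise ValueError(
            f"avg_neighbours must be in [0, num_nodes-1), got {avg_neighbours}"
        )
    if levels_per_node < 2:
        raise ValueError("levels_per_node must be >= 2")
    if cpt_concentration <= 0:
        raise ValueError("cpt_concentration must be positive")
    rng = np.random.default_rng(seed)
    width = len(str(num_nodes - 1)) if num_nodes > 1 else 1
    names = [f"X{i:0{width}d}" for i in range(num_nodes)]
    level_labels = tuple(f"l{j}" for j in range(levels_per_node))
    variables = [CategoricalVariable(nm, level_labels) for nm in names]

    order = rng.permutation(num_nodes)
    p_edge = avg_neighbours / (num_nodes - 1) if num_nodes > 1 else 0.0
    parents: dict[str, list[str]] = {nm: [] for nm in names}
    for i in range(num_nodes):
        for j in range(i + 1, num_nodes):
            if rng.random() < p_edge:
                parents[names[order[j]]].append(names[order[i]])

    r = levels_per_node
    cpts: dict[str, CPT] = {}
    for nm in names:
        ps = tuple(sorted(parents[nm]))
        q = r ** len(ps)
        table = rng.dirichlet([cpt_concentration] * r, size=q)
        cpts[nm] = CPT(parents=ps, table=table)
    return DiscreteBayesianNetwork(variables=variables, cpts=cpts)


def encode_dataset(
    df: pd.DataFrame, variables: list[CategoricalVariable] | None = None
) -> tuple[np.ndarray, list[str], list[int], list[tuple[str, ...]]]:
    """Validate and integer-encode a categorical dataset.

    Returns ``(codes, columns, cardinalities, level_sets)`` where ``codes`` is
    an (n, N) int32 array.  Missing values and values outside a declared level
    set are rejected: the learners here assume complete data.  When
    ``variables`` is omitted the level sets are taken from the columns'
    categorical dtypes (or the sorted observed values for plain columns), so a
    level can be declared without being observed.
    """
    if df.shape[1] < 1:
        raise ValueError("dataset has no columns")
    columns = list(df.columns)
    declared = {v.name: list(v.levels) for v in (variables or [])}
    if variables is not None:
        missing = set(columns) - set(declared)
        if missing:
            raise ValueError(f"columns without a declared variable: {sorted(missing)}")
    codes = np.empty((len(df), len(columns)), dtype=np.int32)
    cards: list[int] = []
    level_sets: list[tuple[str, ...]] = []
    for j, col in enumerate(columns):
        s = df[col]
        if s.isna().any():
            raise ValueError(f"column {col!r} contains missing values")
        if col in declared:
            cat = pd.Categorical(s.astype(str), categories=declared[col])
            if cat.isna().any():
                bad = sorted(set(s.astype(str)) - set(declared[col]))
                raise ValueError(f"column {col!r} has undeclared values {bad}")
        elif isinstance(s.dtype, pd.CategoricalDtype):
            cat = pd.Categorical(s)
        else:
            cat = pd.Categorical(s.astype(str))
        if len(cat.categories) < 1:
            raise ValueError(f"column {col!r} has no levels")
        codes[:, j] = cat.codes
        cards.append(len(cat.categories))
        level_sets.append(tuple(str(c) for c in cat.categories))
    return codes, columns, cards, level_sets
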