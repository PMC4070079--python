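"""Score-based structure learning: BDeu scoring and greedy hill climbing.

The BDeu (Bayesian Dirichlet equivalent uniform) score is the log marginal
likelihood of the data under Dirichlet parameter priors with hyperparameters
``alpha_jk = ess / (q * r)``, where ``q`` is the number of parent
configurations, ``r`` the number of child levels and ``ess`` the equivalent
sample size (prior weight).  It decomposes over families (child, parent set),
which lets hill climbing re-score only the families a move touches, and it
assigns equal scores to Markov-equivalent DAGs.

The learner contract used throughout the package is any callable
``learner(df, seed) -> networkx.DiGraph`` whose output is an acyclic graph
over exactly the dataframe's columns; :func:`make_hc_learner` adapts
:func:`hill_climb` to it, and any other score-based, constraint-based or
hybrid algorithm can be plugged in the same way.
"""

from __future__ import annotations

from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .bn_model import encode_dataset

__all__ = [
    "bdeu_family_score",
    "network_score",
    "hill_climb",
    "make_hc_learner",
    "ScoreCache",
]

DEFAULT_ESS = 10.0
# moves whose score gain is below this are treated as non-improving, so that
# score-equivalent reversals (delta ~1e-13 of gammaln round-off) cannot cycle
_IMPROVEMENT_TOL = 1e-9

Learner = Callable[[pd.DataFrame, int], nx.DiGraph]


def _family_score_codes(
    child_codes: np.ndarray, parent_codes: list[np.ndarray],
    r: int, parent_cards: list[int], ess: float,
) -> float:
    """BDeu log marginal likelihood of one family from integer-coded columns."""
    q = int(np.prod(parent_cards, dtype=np.int64)) if parent_cards else 1
    if child_codes.size == 0:
        return 0.0
    if parent_cards:
        cfg = np.ravel_multi_index(tuple(parent_codes), parent_cards)
    else:
        cfg = np.zeros(child_codes.shape[0], dtype=np.intp)
    counts = np.bincount(cfg * r + child_codes, minlength=q * r).reshape(q, r)
    n_j = counts.sum(axis=1)
    nz = n_j > 0  # empty configurations contribute lnG(a)-lnG(a) = 0
    counts = counts[nz]
    n_j = n_j[nz]
    a_j = ess / q
    a_jk = ess / (q * r)
    score = np.sum(gammaln(a_j) - gammaln(a_j + n_j))
    score += np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
    return float(score)


class ScoreCache:
    """Encoded dataset plus a per-(child, parent-set) BDeu score cache.

    The cache is keyed on ``(child, frozenset(parents))`` and never evicted;
    at desk scale the number of distinct families visited by hill climbing is
    small.
    """

    def __init__(self, df: pd.DataFrame, ess: float = DEFAULT_ESS):
        if ess <= 0:
            raise ValueError(f"ess must be positive, got {ess}")
        codes, columns, cards, _ = encode_dataset(df)
        if min(cards) < 1:
            raise ValueError("every variable needs at least one level")
        self.columns = columns
        self.index = {c: j for j, c in enumerate(columns)}
        self.codes = codes
        self.cards = cards
        self.ess = float(ess)
        self._cache: dict[tuple[str, frozenset], float] = {}

    def family_score(self, child: str, parents) -> float:
        key = (child, frozenset(parents))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        ci = self.index[child]
        pis = [self.index[p] for p in sorted(parents)]
        val = _family_score_codes(
            self.codes[:, ci], [self.codes[:, j] for j in pis],
            self.cards[ci], [self.cards[j] for j in pis], self.ess,
        )
        self._cache[key] = val
        return val


def bdeu_family_score(child: str, parents, data: pd.DataFrame,
                      ess: float = DEFAULT_ESS) -> float:
    """BDeu log marginal likelihood of ``child`` given ``parents`` on ``data``.

    Equals sum_j [lnG(a_j) - lnG(a_j + n_j)] + sum_jk [lnG(a_jk + n_jk) -
    lnG(a_jk)] with a_j = ess/q, a_jk = ess/(q r); zero for an empty dataset.
    """
    return ScoreCache(data, ess=ess).family_score(child, list(parents))


def network_score(graph: nx.DiGraph, data: pd.DataFrame,
                  ess: float = DEFAULT_ESS, cache: ScoreCache | None = None) -> float:
    """Decomposable network score: sum of BDeu family scores over all nodes."""
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("graph must be acyclic")
    if cache is None:
        cache = ScoreCache(data, ess=ess)
    unknown = set(graph.nodes) - set(cache.columns)
    if unknown:
        raise ValueError(f"graph nodes not in data: {sorted(unknown)}")
    return sum(cache.family_score(n, list(graph.predecessors(n)))
               for n in cache.columns if n in graph)


def _has_path(adj: dict[str, set], src: str, dst: str) -> bool:
    """DFS reachability src -> dst over a parents->children adjacency."""
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w == dst:
                return True
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def hill_climb(
    data: pd.DataFrame,
    ess: float = DEFAULT_ESS,
    max_parents: int | None = None,
    max_iter: int = 200,
    seed: int | None = None,
    restarts: int = 0,
    cache: ScoreCache | None = None,
) -> nx.DiGraph:
    """Greedy hill climbing over single-edge additions, deletions and reversals.

    Starts from the empty graph and at each step applies the
    acyclicity-preserving move with the largest strictly positive score gain;
    stops when no move improves the BDeu score or after ``max_iter`` moves.
    Ties are broken by canonical move order (addition < deletion < reversal,
    then lexicographic edge), so the result is deterministic; ``seed`` only
    matters when ``restarts > 0``, where each restart perturbs the starting
    graph with random edges and the best-scoring final graph wins.
    """
    if data.shape[1] < 2:
        raise ValueError("hill climbing needs at least 2 columns")
    if cache is None:
        cache = ScoreCache(data, ess=ess)
    nodes = cache.columns
    rng = np.random.default_rng(seed)

    def climb(initial_parents: dict[str, set]) -> tuple[dict[str, set], float]:
        parents = {n: set(ps) for n, ps in initial_parents.items()}
        children = {n: set() for n in nodes}
        for c, ps in parents.items():
            for p in ps:
                children[p].add(c)
        fam = {n: cache.family_score(n, parents[n]) for n in nodes}

        def better(cand, best):
            # largest gain wins; exact ties go to the canonical-first move
            # (addition < deletion < reversal, then lexicographic edge)
            if best is None:
                return True
            if cand[0] != best[0]:
                return cand[0] > best[0]
            return (cand[1], cand[2]) < (best[1], best[2])

        for _ in range(max_iter):
            best = None  # (delta, move_rank, edge)
            for u in nodes:
                for v in nodes:
                    if u == v or u in parents[v] or v in parents[u]:
                        continue
                    # addition u -> v
                    if max_parents is not None and len(parents[v]) >= max_parents:
                        continue
                    if _has_path(children, v, u):
                        continue
                    delta = cache.family_score(v, parents[v] | {u}) - fam[v]
                    if better((delta, 0, (u, v)), best):
                        best = (delta, 0, (u, v))
            for v in nodes:
                for u in sorted(parents[v]):
                    # deletion u -> v
                    delta = cache.family_score(v, parents[v] - {u}) - fam[v]
                    if better((delta, 1, (u, v)), best):
                        best = (delta, 1, (u, v))
                    # reversal u -> v  becomes  v -> u; blocked when another
                    # directed path u ~> v survives removal of the edge itself
                    if max_parents is not None and len(parents[u]) >= max_parents:
                        continue
                    children[u].discard(v)
                    blocked = _has_path(children, u, v)
                    children[u].add(v)
                    if blocked:
                        continue
                    delta = (cache.family_score(v, parents[v] - {u}) - fam[v]
                             + cache.family_score(u, parents[u] | {v}) - fam[u])
                    if better((delta, 2, (u, v)), best):
                        best = (delta, 2, (u, v))
            if best is None or best[0] <= _IMPROVEMENT_TOL:
                break
            _, kind, (u, v) = best
            if kind == 0:
                parents[v].add(u)
                children[u].add(v)
                fam[v] = cache.family_score(v, parents[v])
            elif kind == 1:
                parents[v].discard(u)
                children[u].discard(v)
                fam[v] = cache.family_score(v, parents[v])
            else:
                parents[v].discard(u)
                children[u].discard(v)
                parents[u].add(v)
                children[v].add(u)
                fam[v] = cache.family_score(v, parents[v])
                fam[u] = cache.family_score(u, parents[u])
        return parents, sum(fam.values())

    empty = {n: set() for n in nodes}
    best_parents, best_score = climb(empty)
    for _ in range(restarts):
        start = {n: set() for n in nodes}
        # random DAG start: random order, sparse forward edges
        order = list(rng.permutation(nodes))
        for i, u in enumerate(order):
            for v in order[i + 1:]:
                if rng.random() < 1.0 / max(len(nodes) - 1, 1):
                    if max_parents is None or len(start[v]) < max_parents:
                        start[v].add(u)
        p, s = climb(start)
        if s > best_score + _IMPROVEMENT_TOL:
            best_parents, best_score = p, s

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from((u, v) for v, ps in best_parents.items() for u in sorted(ps))
    return g


def make_hc_learner(ess: float = DEFAULT_ESS, max_parents: int | None = None,
                    max_iter: int = 200, restarts: int = 0) -> Learner:
    """Bind hill-climbing options into a ``learner(df, seed)`` callable."""

    def learner(df: pd.DataFrame, seed: int | None = None) -> nx.DiGraph:
        return hill_climb(df, ess=ess, max_parents=max_parents,
                          max_iter=max_iter, seed=seed, restarts=restarts)

    learner.__name__ = "hc_bdeu"
    return learner
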