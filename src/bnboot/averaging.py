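"""Bootstrap model averaging and the permutation noise-floor baseline.

Friedman-style model averaging: draw ``m`` nonparametric bootstrap replicates
of the data, learn one network structure per replicate, and record for every
unordered node pair the fraction of replicates in which it appears in either
orientation.  That fraction — the edge confidence, or arc strength — is the
quantity the threshold module turns into a significant/non-significant call.

The noise floor is the older permutation alternative: destroy all dependence
by independently permuting each column, learn one network per permutation
replicate, and call an edge significant only when its bootstrap confidence
strictly exceeds the largest confidence any pair attains on permuted data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .bn_model import canonical_pairs

__all__ = [
    "EdgeConfidenceSet",
    "NoiseFloor",
    "bootstrap_resample",
    "bootstrap_confidences",
    "noise_floor",
    "select_by_noise_floor",
    "write_confidence_table",
    "read_confidence_table",
]


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeConfidenceSet:
    """Per-pair bootstrap confidences and per-direction counts.

    ``confidence[pair] * m`` is always an integer equal to
    ``direction_counts[pair][0] + direction_counts[pair][1]`` (counts of
    a->b and b->a over the m replicates, with pair = (a, b) canonical).
    """

    pairs: list[tuple[str, str]]
    confidence: dict[tuple[str, str], float]
    direction_counts: dict[tuple[str, str], tuple[int, int]]
    m: int

    @property
    def nodes(self) -> list[str]:
        return sorted({n for p in self.pairs for n in p})

    def vector(self) -> np.ndarray:
        """Confidences in canonical pair order."""
        return np.array([self.confidence[p] for p in self.pairs])

    @classmethod
    def from_confidences(cls, confidence: dict[tuple[str, str], float],
                         m: int = 0) -> "EdgeConfidenceSet":
        """Build from bare confidences (direction counts unknown, set to 0)."""
        conf = {_canon(*p): float(v) for p, v in confidence.items()}
        pairs = sorted(conf)
        return cls(pairs=pairs, confidence=conf,
                   direction_counts={p: (0, 0) for p in pairs}, m=m)


@dataclass
class NoiseFloor:
    """Per-pair confidences on column-permuted (dependence-free) data."""

    floor: dict[tuple[str, str], float]
    max_floor: float
    permutations: int


def bootstrap_resample(data: pd.DataFrame, seed) -> pd.DataFrame:
    """One nonparametric bootstrap replicate: n rows drawn with replacement."""
    n = len(data)
    if n < 1:
        raise ValueError("cannot resample an empty dataset")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=n)
    return data.iloc[idx].reset_index(drop=True)


def _replicate_seeds(seed, m: int) -> list[np.random.SeedSequence]:
    """Deterministic per-replicate seed streams from a master seed.

    Uses ``SeedSequence(master).spawn(m)``, so replicate b's stream depends
    only on (master, b): any execution order — or parallel execution — gives
    identical results.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    return ss.spawn(m)


def _learner_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _check_learner_output(graph: nx.DiGraph, columns: list[str]) -> None:
    if set(graph.nodes) != set(columns):
        raise ValueError(
            f"learner returned nodes {sorted(graph.nodes)}, "
            f"expected {sorted(columns)}")
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("learner returned a cyclic graph")


def _accumulate(graphs, columns: list[str], m: int) -> tuple[
        list[tuple[str, str]], dict, dict]:
    pairs = canonical_pairs(columns)
    ab = {p: 0 for p in pairs}
    ba = {p: 0 for p in pairs}
    for g in graphs:
        for u, v in g.edges:
            p = _canon(u, v)
            if (u, v) == p:
                ab[p] += 1
            else:
                ba[p] += 1
    confidence = {p: (ab[p] + ba[p]) / m for p in pairs}
    counts = {p: (ab[p], ba[p]) for p in pairs}
    return pairs, confidence, counts


def bootstrap_confidences(data: pd.DataFrame, learner, m: int = 500,
                          seed=None) -> EdgeConfidenceSet:
    """Edge confidences from ``m`` bootstrap replicates of ``data``.

    For each unordered pair the confidence is the fraction of learned graphs
    containing the edge in either orientation; the two orientations are also
    counted separately for later majority-direction orientation.  The default
    m = 500 replicates is ample; 200 gives very similar confidences.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if len(data) < 1:
        raise ValueError("cannot bootstrap an empty dataset")
    columns = list(data.columns)
    graphs = []
    for ss in _replicate_seeds(seed, m):
        resample_rng, learner_ss = ss.spawn(2)
        rep = bootstrap_resample(data, resample_rng)
        g = learner(rep, _learner_seed(learner_ss))
        _check_learner_output(g, columns)
        graphs.append(g)
    pairs, confidence, counts = _accumulate(graphs, columns, m)
    return EdgeConfidenceSet(pairs=pairs, confidence=confidence,
                             direction_counts=counts, m=m)


def noise_floor(data: pd.DataFrame, learner, permutations: int = 100,
                seed=None) -> NoiseFloor:
    """Confidence each pair attains once all dependence is destroyed.

    Each replicate permutes every column independently (preserving marginals,
    breaking associations) and learns a single network.  ``floor[pair]`` is
    the fraction of replicates containing the pair; ``max_floor`` is the
    baseline a bootstrap confidence must strictly exceed to be called
    significant by :func:`select_by_noise_floor`.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    if len(data) < 1:
        raise ValueError("cannot permute an empty dataset")
    columns = list(data.columns)
    graphs = []
    for ss in _replicate_seeds(seed, permutations):
        perm_ss, learner_ss = ss.spawn(2)
        rng = np.random.default_rng(perm_ss)
        shuffled = {}
        for col in columns:
            vals = data[col].to_numpy()
            shuffled[col] = vals[rng.permutation(len(vals))]
        rep = pd.DataFrame(shuffled, columns=columns)
        g = learner(rep, _learner_seed(learner_ss))
        _check_learner_output(g, columns)
        graphs.append(g)
    _, floor, _ = _accumulate(graphs, columns, permutations)
    max_floor = max(floor.values()) if floor else 0.0
    return NoiseFloor(floor=floor, max_floor=max_floor,
                      permutations=permutations)


def select_by_noise_floor(conf: EdgeConfidenceSet,
                          floor: NoiseFloor) -> set[tuple[str, str]]:
    """Pairs whose confidence strictly exceeds the maximum noise floor."""
    if set(conf.pairs) != set(floor.floor):
        raise ValueError("confidence set and noise floor cover different pairs")
    return {p for p in conf.pairs if conf.confidence[p] > floor.max_floor}


def write_confidence_table(conf: EdgeConfidenceSet, path: str | os.PathLike) -> None:
    """Canonical TSV: node_a, node_b, confidence, count_ab, count_ba."""
    rows = []
    for a, b in conf.pairs:
        ab, ba = conf.direction_counts[(a, b)]
        rows.append((a, b, conf.confidence[(a, b)], ab, ba))
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence",
                                     "count_ab", "count_ba"])
    df.to_csv(path, sep="\t", index=False)


def read_confidence_table(path: str | os.PathLike) -> EdgeConfidenceSet:
    """Read the TSV written by :func:`write_confidence_table`.

    Also accepts the minimal three-column (node_a, node_b, confidence) form,
    the learner-agnostic entry point for confidences computed elsewhere.
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    required = {"node_a", "node_b", "confidence"}
    if not required.issubset(df.columns):
        raise ValueError(f"confidence table needs columns {sorted(required)}")
    has_counts = {"count_ab", "count_ba"}.issubset(df.columns)
    confidence: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        a, b, c = row.node_a, row.node_b, float(row.confidence)
        p = _canon(a, b)
        if p in confidence:
            raise ValueError(f"duplicate pair {p} in confidence table")
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"confidence {c} for pair {p} outside [0, 1]")
        confidence[p] = c
        if has_counts:
            ab, ba = int(row.count_ab), int(row.count_ba)
            counts[p] = (ab, ba) if p == (a, b) else (ba, ab)
        else:
            counts[p] = (0, 0)
    pairs = sorted(confidence)
    total = max((sum(c) for c in counts.values()), default=0)
    return EdgeConfidenceSet(pairs=pairs, confidence=confidence,
                             direction_counts=counts, m=total)
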