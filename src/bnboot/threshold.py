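"""Significance threshold estimation for bootstrap edge confidences.

Given the confidences p-hat(1) <= ... <= p-hat(k) of the k possible edges, a
consistent learner at large sample size would produce the ideal configuration
{0, ..., 0, 1, ..., 1}: every edge either certainly absent or certainly
present.  The ideal CDF is therefore a one-step function with value t on
[0, 1), where t is the fraction of non-significant edges.  The estimator
picks the t whose one-step CDF is closest to the empirical CDF of the
observed confidences,

    t-hat = argmin_t  integral |F(x) - F_ideal(x; t)| dx ,

an L1 / least-absolute-deviations problem.  Because F is a step function the
integral collapses to a finite sum of |F(x_i) - t| * (x_{i+1} - x_i) terms
over the segments cut by {0} + jump points + {1}, so the objective is convex
piecewise-linear in t and the minimiser is a weighted median of segment CDF
values with segment widths as weights — no LP solver needed.  Edges with
confidence strictly greater than the empirical quantile F^{-1}(t-hat) are
declared significant; significant pairs are oriented by the direction seen
most often across the bootstrap replicates.

L2 (whose minimiser is the width-weighted mean) and L-infinity are provided
as diagnostic alternatives; L1 is the default because it does not inflate
large deviations relative to small ones.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .averaging import EdgeConfidenceSet

__all__ = [
    "ConfidenceCDF",
    "ThresholdResult",
    "empirical_cdf",
    "l1_distance",
    "l2_distance",
    "linf_distance",
    "cdf_quantile",
    "estimate_threshold",
    "select_significant",
    "build_averaged_network",
    "write_report",
    "write_dot",
]


@dataclass
class ConfidenceCDF:
    """Right-continuous empirical CDF of a confidence vector.

    ``plateau_values[i]`` is F(x) for x in [jump_points[i], jump_points[i+1]);
    F is 0 before the first jump and plateau_values[-1] == 1 after the last.
    Plateaus are integer multiples of 1/k.
    """

    jump_points: np.ndarray
    plateau_values: np.ndarray
    k: int

    def evaluate(self, x) -> np.ndarray:
        """F(x), vectorised, right-continuous."""
        idx = np.searchsorted(self.jump_points, np.asarray(x, dtype=float),
                              side="right")
        padded = np.concatenate([[0.0], self.plateau_values])
        return padded[idx]

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, widths) of F on the segments cut by {0} U jumps U {1}.

        Zero-width segments (a jump at 0 or at 1) are kept with width 0; they
        never contribute to any of the norms.
        """
        xs = np.concatenate([[0.0], self.jump_points, [1.0]])
        vals = np.concatenate([[0.0], self.plateau_values])
        widths = np.diff(xs)
        return vals, widths


def empirical_cdf(confidences) -> ConfidenceCDF:
    """Empirical CDF of a confidence vector: sort, deduplicate, accumulate."""
    p = np.asarray(confidences, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("confidences must be a non-empty 1-d vector")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("confidences must lie in [0, 1]")
    k = p.size
    jumps, mult = np.unique(p, return_counts=True)
    plateaus = np.cumsum(mult) / k
    plateaus[-1] = 1.0  # exact, guards against cumsum round-off
    return ConfidenceCDF(jump_points=jumps, plateau_values=plateaus, k=k)


def _check_t(t: float) -> float:
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    return t


def l1_distance(t: float, cdf: ConfidenceCDF) -> float:
    """L1 distance between the empirical CDF and the one-step CDF at t.

    Computed in one pass as sum_i |F(x_i) - t| * (x_{i+1} - x_i) over the
    segments; exactly the integral of |F - F_ideal| on [0, 1].
    """
    t = _check_t(t)
    vals, widths = cdf.segments()
    return float(np.sum(np.abs(vals - t) * widths))


def l2_distance(t: float, cdf: ConfidenceCDF) -> float:
    """Integral of (F - F_ideal)^2 over [0, 1]."""
    t = _check_t(t)
    vals, widths = cdf.segments()
    return float(np.sum((vals - t) ** 2 * widths))


def linf_distance(t: float, cdf: ConfidenceCDF) -> float:
    """Max over [0, 1] of |F - F_ideal|, ignoring zero-width segments."""
    t = _check_t(t)
    vals, widths = cdf.segments()
    live = widths > 0
    if not np.any(live):
        return 0.0
    return float(np.max(np.abs(vals[live] - t)))


def cdf_quantile(cdf: ConfidenceCDF, t: float) -> float:
    """Generalised inverse CDF: inf{x : F(x) >= t}, right-continuous.

    At t = 0 every real satisfies F(x) >= 0; by convention 0.0 is returned
    (the infimum of the confidence scale).
    """
    t = _check_t(t)
    if t == 0.0:
        return 0.0
    idx = int(np.searchsorted(cdf.plateau_values, t, side="left"))
    return float(cdf.jump_points[idx])


@dataclass
class ThresholdResult:
    """Estimated threshold, confidence cut-off and diagnostics."""

    t_hat: float
    cutoff: float
    norm_used: str
    l1_at_optimum: float
    cdf: ConfidenceCDF
    significant_indices: list[int] = field(default_factory=list)

    @property
    def min_significant_confidence(self) -> float | None:
        """Smallest confidence among selected edges (the '0.7689-style' value)."""
        jumps = self.cdf.jump_points
        above = jumps[jumps > self.cutoff]
        return float(above.min()) if above.size else None


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Minimiser of sum_i w_i |v_i - t|; midpoint of a flat optimal interval.

    ``values`` must be sorted ascending.  The optimum is any t where the
    cumulative weight reaches half the total; when it hits W/2 exactly at
    v_i, every t in [v_i, v_{i+1}] is optimal and the midpoint is returned.
    """
    live = weights > 0
    values, weights = values[live], weights[live]
    if values.size == 0:
        return 0.0
    w = np.cumsum(weights)
    half = w[-1] / 2.0
    i = int(np.searchsorted(w, half, side="left"))
    if np.isclose(w[i], half, rtol=0.0, atol=1e-12) and i + 1 < values.size:
        return float((values[i] + values[i + 1]) / 2.0)
    return float(values[i])


def estimate_threshold(confidences, norm: str = "l1") -> ThresholdResult:
    """Estimate the significance threshold t-hat from a confidence vector.

    norm = "l1" (default): t-hat is the width-weighted median of the segment
    CDF values, the exact least-absolute-deviations minimiser.  "l2": the
    width-weighted mean.  "linf": the midpoint of the extreme segment values.
    The result records the L1 objective at the chosen t-hat as an optimality
    certificate, the quantile cut-off F^{-1}(t-hat) and the indices of the
    confidences strictly above the cut-off.
    """
    norm = norm.lower()
    if norm not in {"l1", "l2", "linf"}:
        raise ValueError(f"norm must be one of l1, l2, linf; got {norm!r}")
    p = np.asarray(confidences, dtype=float)
    cdf = empirical_cdf(p)
    vals, widths = cdf.segments()
    if norm == "l1":
        t_hat = _weighted_median(vals, widths)
    elif norm == "l2":
        live = widths > 0
        t_hat = float(np.average(vals[live], weights=widths[live])) if live.any() else 0.0
    else:
        live = widths > 0
        t_hat = float((vals[live].min() + vals[live].max()) / 2.0) if live.any() else 0.0
    t_hat = min(max(t_hat, 0.0), 1.0)
    cutoff = cdf_quantile(cdf, t_hat)
    selected = [int(i) for i in np.nonzero(p > cutoff)[0]]
    return ThresholdResult(
        t_hat=t_hat, cutoff=cutoff, norm_used=norm,
        l1_at_optimum=l1_distance(t_hat, cdf), cdf=cdf,
        significant_indices=selected,
    )


def select_significant(conf: EdgeConfidenceSet,
                       result: ThresholdResult) -> set[tuple[str, str]]:
    """Pairs with confidence strictly greater than the estimated cut-off."""
    if result.cdf.k != len(conf.pairs):
        raise ValueError(
            f"threshold was estimated from {result.cdf.k} confidences but the "
            f"confidence set has {len(conf.pairs)} pairs")
    return {p for p in conf.pairs if conf.confidence[p] > result.cutoff}


def build_averaged_network(conf: EdgeConfidenceSet,
                           significant) -> nx.DiGraph:
    """Averaged network: significant pairs oriented by majority direction.

    Each significant pair (a, b) becomes the edge a->b or b->a according to
    which orientation occurred more often across the bootstrap replicates; an
    exact tie keeps the canonical orientation with the edge attribute
    ``undirected=True``.  Edge attributes carry the confidence and counts.
    """
    significant = set(significant)
    unknown = significant - set(conf.pairs)
    if unknown:
        raise ValueError(f"significant pairs not in confidence set: {sorted(unknown)}")
    g = nx.DiGraph()
    g.add_nodes_from(conf.nodes)
    for a, b in sorted(significant):
        ab, ba = conf.direction_counts[(a, b)]
        u, v = (a, b) if ab >= ba else (b, a)
        g.add_edge(u, v, confidence=conf.confidence[(a, b)],
                   count_ab=ab, count_ba=ba, undirected=(ab == ba))
    return g


def write_report(conf: EdgeConfidenceSet, result: ThresholdResult,
                 path: str | os.PathLike, extra: dict | None = None) -> None:
    """JSON report of the threshold estimate and the selected edges."""
    significant = sorted(select_significant(conf, result))
    graph = build_averaged_network(conf, significant)
    directions = []
    for u, v, attrs in sorted(graph.edges(data=True)):
        directions.append({
            "from": u, "to": v,
            "undirected": bool(attrs["undirected"]),
            "count_ab": attrs["count_ab"], "count_ba": attrs["count_ba"],
        })
    payload = {
        "t_hat": result.t_hat,
        "cutoff": result.cutoff,
        "min_significant_confidence": result.min_significant_confidence,
        "norm": result.norm_used,
        "l1_at_optimum": result.l1_at_optimum,
        "k": result.cdf.k,
        "m": conf.m,
        "significant_edges": [list(p) for p in significant],
        "directions": directions,
    }
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_dot(graph: nx.DiGraph, path: str | os.PathLike) -> None:
    """Minimal DOT export of an averaged network (ties drawn without arrows)."""
    lines = ["digraph averaged {"]
    for n in sorted(graph.nodes):
        lines.append(f'  "{n}";')
    for u, v, attrs in sorted(graph.edges(data=True)):
        style = ' [dir=none]' if attrs.get("undirected") else ""
        lines.append(f'  "{u}" -> "{v}"{style};')
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
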