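"""Structure-recovery metrics and the simulation harness.

Recovery is assessed at the skeleton level: a selected pair is a true
positive when the true network contains the edge in either orientation.
Sensitivity is the fraction of true edges recovered, specificity the
fraction of true non-edges correctly rejected, and accuracy the fraction of
correct calls over all N(N-1)/2 possible pairs.

``run_simulation`` reproduces the benchmark protocol at desk scale: sample
from a known network, bootstrap-average with hill climbing + BDeu, estimate
the threshold, and score the selected edges against the true skeleton — for
the estimated-threshold policy and for ad hoc confidence cut-offs (an ad hoc
threshold t selects pairs with confidence strictly above t directly).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .averaging import bootstrap_confidences
from .bn_model import DiscreteBayesianNetwork, canonical_pairs, forward_sample, param_count
from .learning import make_hc_learner
from .threshold import estimate_threshold, select_significant

__all__ = [
    "PerformanceMetrics",
    "SimulationResult",
    "skeleton_metrics",
    "run_simulation",
    "DEFAULT_AD_HOC_THRESHOLDS",
]

DEFAULT_AD_HOC_THRESHOLDS = (0.70, 0.80, 0.90, 0.95)


@dataclass(frozen=True)
class PerformanceMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def k(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else 1.0

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else 1.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.k


def _skeleton(net: DiscreteBayesianNetwork) -> set[tuple[str, str]]:
    return {tuple(sorted(e)) for e in net.edges}


def skeleton_metrics(true_net: DiscreteBayesianNetwork,
                     selected) -> PerformanceMetrics:
    """Confusion counts of a selected pair set against the true skeleton."""
    nodes = set(true_net.node_names)
    selected = {tuple(sorted(p)) for p in selected}
    unknown = {n for p in selected for n in p} - nodes
    if unknown:
        raise ValueError(f"selected pairs mention unknown nodes: {sorted(unknown)}")
    truth = _skeleton(true_net)
    all_pairs = set(canonical_pairs(true_net.node_names))
    tp = len(selected & truth)
    fp = len(selected - truth)
    fn = len(truth - selected)
    tn = len(all_pairs) - tp - fp - fn
    return PerformanceMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class SimulationResult:
    """Tidy per-replicate records plus aggregated summaries."""

    records: pd.DataFrame
    summary: pd.DataFrame
    n_params: int

    def to_csv(self, path: str | os.PathLike) -> None:
        self.records.to_csv(path, index=False)


def _policy_select(conf, policy):
    if policy == "estimated":
        result = estimate_threshold(conf.vector(), norm="l1")
        return select_significant(conf, result), result.t_hat
    t = float(policy)
    return {p for p in conf.pairs if conf.confidence[p] > t}, t


def run_simulation(
    fixture: DiscreteBayesianNetwork,
    sizes,
    m: int = 100,
    reps: int = 10,
    thresholds=("estimated",) + DEFAULT_AD_HOC_THRESHOLDS,
    seed=None,
    ess: float = 10.0,
    max_iter: int = 200,
) -> SimulationResult:
    """Sample / bootstrap-average / threshold / score, over sizes x reps.

    One bootstrap-averaging run per (n, rep) cell feeds every threshold
    policy, so policies are compared on identical confidence sets.  The
    summary aggregates each (n, policy) cell into the mean of each metric
    with a normal-approximation 95% interval.  Fully reproducible from
    ``seed``: cell (n, rep) uses streams spawned from SeedSequence([seed,
    n, rep]).
    """
    if not sizes:
        raise ValueError("sizes must be non-empty")
    p = param_count(fixture)
    learner = make_hc_learner(ess=ess, max_iter=max_iter)
    rows = []
    for n in sizes:
        for rep in range(reps):
            ss = np.random.SeedSequence([0 if seed is None else int(seed),
                                         int(n), int(rep)])
            sample_ss, boot_ss = ss.spawn(2)
            data = forward_sample(fixture, int(n), sample_ss)
            conf = bootstrap_confidences(data, learner, m=m, seed=boot_ss)
            for policy in thresholds:
                selected, t_used = _policy_select(conf, policy)
                met = skeleton_metrics(fixture, selected)
                rows.append({
                    "n": int(n), "rep": rep, "n_over_p": n / p, "m": m,
                    "policy": str(policy), "t": t_used,
                    "tp": met.tp, "fp": met.fp, "tn": met.tn, "fn": met.fn,
                    "sensitivity": met.sensitivity,
                    "specificity": met.specificity,
                    "accuracy": met.accuracy,
                })
    records = pd.DataFrame(rows)
    agg = []
    z = 1.959963984540054  # normal 97.5% quantile
    for (n, policy), grp in records.groupby(["n", "policy"], sort=True):
        row = {"n": n, "policy": policy, "n_over_p": float(grp["n_over_p"].iloc[0]),
               "reps": len(grp)}
        for metric in ("sensitivity", "specificity", "accuracy", "t"):
            vals = grp[metric].to_numpy()
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            row[f"{metric}_mean"] = mean
            row[f"{metric}_lo"] = mean - z * se
            row[f"{metric}_hi"] = mean + z * se
        agg.append(row)
    return SimulationResult(records=records, summary=pd.DataFrame(agg), n_params=p)
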