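"""Posterior clade-rate summaries and rate-constancy calls.

A clade's relative rate in one posterior sample is the time-weighted
mean of the rates on its crown branches (branches strictly inside the
clade; the stem branch is excluded because deep connecting branches are
the ones most affected by saturation).  Across samples this yields a
posterior distribution per clade; the 95% highest posterior density
(HPD) interval drives two calls:

* ``deviates_from_mean`` - the clade HPD excludes 1, the anchored
  tree-wide mean rate;
* ``differs_from_focal`` - the clade HPD and the focal clade's HPD are
  disjoint.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, InvalidCladeError
from .mcmc import Trace, ess
from .trees import TimeTree


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval over sorted samples containing
    ``ceil(prob * N)`` of them."""
    if not 0.0 < prob < 1.0:
        raise InvalidArgumentError("prob must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise InvalidArgumentError("need at least 20 samples for an HPD")
    k = int(np.ceil(prob * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def clade_mean_rate(tree_sample: TimeTree, clade) -> float:
    """Time-weighted mean rate over the clade's crown branches."""
    edges = tree_sample.clade_edges(clade)
    spans = tree_sample.durations()[edges]
    rates = tree_sample.rates[edges]
    total = spans.sum()
    if total <= 0:
        # degenerate zero-span clade: plain average keeps the estimand finite
        return float(rates.mean())
    return float((rates * spans).sum() / total)


@dataclass
class CladeRateSummary:
    clade: str
    mean_rate: float
    hpd_low: float
    hpd_high: float
    ess: float
    deviates_from_mean: bool
    differs_from_focal: bool
    n_samples_used: int
    n_samples_skipped: int = 0


@dataclass
class RateConstancyReport:
    summaries: list[CladeRateSummary]
    focal: str
    calibration_advice: str
    ess_warnings: list[str]

    def summary(self, clade: str) -> CladeRateSummary:
        for s in self.summaries:
            if s.clade == clade:
                return s
        raise KeyError(clade)


def _clade_rate_samples(trace: Trace, tips) -> tuple[np.ndarray, int]:
    """Per-sample clade mean rates; fixed topology makes this vectorizable."""
    topo = trace.topology
    if not topo.is_monophyletic(tips):
        raise InvalidCladeError(f"clade not monophyletic in the fixed "
                                f"topology: {sorted(tips)}")
    edges = topo.clade_edges(tips)
    par = topo.parent[edges]
    spans = trace.heights[:, par] - trace.heights[:, edges]
    rates = trace.rates[:, edges]
    tot = spans.sum(axis=1)
    ok = tot > 0
    out = np.empty(trace.n_samples)
    out[ok] = (rates[ok] * spans[ok]).sum(axis=1) / tot[ok]
    out[~ok] = rates[~ok].mean(axis=1)
    return out, 0


def rate_constancy_report(trace: Trace, clades: dict[str, frozenset[str]],
                          focal: str, prob: float = 0.95,
                          ess_threshold: float = 200.0) -> RateConstancyReport:
    """Per-clade posterior mean rates, HPDs and constancy flags.

    ``trace`` must already have burn-in removed.  The calibration advice
    states whether a secondary rate calibrated on the tree-wide mean is
    appropriate for the focal clade (its HPD includes 1).
    """
    if focal not in clades:
        raise InvalidArgumentError(f"focal clade {focal!r} not among clades")
    ess_warnings: list[str] = []
    ess_tab = trace.ess_table()
    low = ess_tab[ess_tab < ess_threshold]
    for name, value in low.items():
        ess_warnings.append(f"parameter {name}: ESS {value:.0f} < "
                            f"{ess_threshold:.0f}")
    if ess_warnings:
        warnings.warn("low ESS for " + ", ".join(low.index), stacklevel=2)

    rate_samples = {name: _clade_rate_samples(trace, tips)
                    for name, tips in clades.items()}
    f_lo, f_hi = hpd_interval(rate_samples[focal][0], prob)
    summaries = []
    for name, (samples, skipped) in rate_samples.items():
        lo, hi = hpd_interval(samples, prob)
        deviates = not (lo <= 1.0 <= hi)
        if name == focal:
            differs = False
        else:
            differs = hi < f_lo or lo > f_hi
        summaries.append(CladeRateSummary(
            clade=name, mean_rate=float(samples.mean()), hpd_low=lo,
            hpd_high=hi, ess=ess(samples), deviates_from_mean=deviates,
            differs_from_focal=differs, n_samples_used=samples.size,
            n_samples_skipped=skipped))
    f_sum = next(s for s in summaries if s.clade == focal)
    if not f_sum.deviates_from_mean:
        advice = (f"focal clade {focal!r}: 95% HPD "
                  f"[{f_sum.hpd_low:.3f}, {f_sum.hpd_high:.3f}] includes 1; "
                  "a secondary calibration at the tree-wide mean rate is "
                  "appropriate")
    else:
        advice = (f"focal clade {focal!r}: 95% HPD "
                  f"[{f_sum.hpd_low:.3f}, {f_sum.hpd_high:.3f}] excludes 1; "
                  "a secondary calibration at the tree-wide mean rate is "
                  "NOT appropriate")
    return RateConstancyReport(summaries, focal, advice, ess_warnings)


def mcc_tree(tree_samples: list[TimeTree]) -> TimeTree:
    """Maximum clade credibility tree with median node heights and rates.

    Scores every sampled tree by the sum of log clade posterior
    frequencies and annotates the winner with per-clade median heights
    and median branch rates across the samples containing each clade.
    """
    if not tree_samples:
        raise InvalidArgumentError("no tree samples")
    ref_taxa = set(tree_samples[0].labels)
    clade_count: dict[frozenset[str], int] = {}
    clade_heights: dict[frozenset[str], list[float]] = {}
    clade_rates: dict[frozenset[str], list[float]] = {}
    keys_per_tree = []
    for t in tree_samples:
        if set(t.labels) != ref_taxa:
            raise InvalidArgumentError("tree samples must share one taxon set")
        keys = {}
        leafsets = t.leaf_sets()
        for node in range(t.n_nodes):
            key = frozenset(t.labels[i] for i in leafsets[node])
            keys[node] = key
            if node >= t.n_tips:
                clade_count[key] = clade_count.get(key, 0) + 1
            clade_heights.setdefault(key, []).append(float(t.heights[node]))
            if t.parent[node] >= 0 and np.isfinite(t.rates[node]):
                clade_rates.setdefault(key, []).append(float(t.rates[node]))
        keys_per_tree.append(keys)
    n = len(tree_samples)
    best_i, best_score = 0, -np.inf
    for i, t in enumerate(tree_samples):
        score = sum(np.log(clade_count[keys_per_tree[i][node]] / n)
                    for node in range(t.n_tips, t.n_nodes))
        if score > best_score:
            best_i, best_score = i, score
    mcc = tree_samples[best_i].copy()
    keys = keys_per_tree[best_i]
    for node in range(mcc.n_nodes):
        key = keys[node]
        mcc.heights[node] = float(np.median(clade_heights[key]))
        if mcc.parent[node] >= 0 and key in clade_rates:
            mcc.rates[node] = float(np.median(clade_rates[key]))
    return mcc


def clade_support(tree_samples: list[TimeTree], mcc: TimeTree) -> dict[int, float]:
    """Posterior frequency of each internal clade of ``mcc``."""
    n = len(tree_samples)
    counts: dict[frozenset[str], int] = {}
    for t in tree_samples:
        leafsets = t.leaf_sets()
        for node in range(t.n_tips, t.n_nodes):
            key = frozenset(t.labels[i] for i in leafsets[node])
            counts[key] = counts.get(key, 0) + 1
    out = {}
    leafsets = mcc.leaf_sets()
    for node in range(mcc.n_tips, mcc.n_nodes):
        key = frozenset(mcc.labels[i] for i in leafsets[node])
        out[node] = counts.get(key, 0) / n
    return out
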