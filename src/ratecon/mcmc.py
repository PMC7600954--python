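"""Bayesian relative-rate estimation on a fixed topology.

A Metropolis-Hastings sampler over node heights, per-branch rates,
GTR exchangeabilities, base frequencies, gamma shape, proportion of
invariant sites, the lognormal clock standard deviation and the Yule
birth rate.  The clock's real-space mean rate is anchored to 1
(mu = -sigma^2/2), so sampled branch rates are relative rates in
substitutions/site/time and deviations from 1 are directly
interpretable.

The kernel is the standard fixed-topology set: multiplicative scale
moves for positive scalars and branch rates, a uniform slide for
internal node heights, a scale move for the root and the whole tree,
and a delta exchange for frequencies.  Proposal step sizes self-tune
toward 20-40% acceptance during burn-in and are frozen afterwards so
the post-burn-in chain is a fixed Markov kernel.  Single-branch moves
reuse cached partial likelihoods and only recompute the path from the
edited branch to the root.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .alignment import Alignment
from .errors import ConstraintError, InvalidArgumentError
from .likelihood import LikelihoodEngine, StatefulLikelihood
from .models import SubstitutionModel, discrete_gamma_rates
from .trees import TimeTree

SCALAR_COLUMNS = ["state", "posterior", "likelihood", "prior", "ucld_stdev",
                  "gamma_shape", "p_inv", "birth_rate",
                  "r_AC", "r_AG", "r_AT", "r_CG", "r_CT",
                  "freq_A", "freq_C", "freq_G", "freq_T"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MCMCConfig:
    generations: int = 500_000
    sample_every: int = 100
    burnin_fraction: float = 0.10
    seed: int = 0
    likelihood_on: bool = True
    n_cat: int = 4
    # prior hyperparameters
    ucld_prior_mean: float = 1.0 / 3.0
    shape_prior_mean: float = 1.0
    exch_prior_sigma: float = 1.5
    birth_bounds: tuple[float, float] = (1e-6, 1e3)
    # relative move weights; 'rate' and 'height' are additionally
    # multiplied by the number of branches / internal nodes
    move_weights: dict = field(default_factory=lambda: {
        "rate": 1.0, "height": 1.0, "root": 0.3, "tree_scale": 0.3,
        "ucld": 0.7, "shape": 0.7, "pinv": 0.7, "birth": 0.5,
        "exch": 3.0, "freqs": 1.5, "ucld_rates": 1.0, "updown": 0.7,
        "subtree_updown": 1.5,
    })
    tune: bool = True
    smart_init: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burnin_fraction < 1:
            raise InvalidArgumentError("burnin_fraction must be in [0, 1)")
        if self.generations < 1 or self.sample_every < 1:
            raise InvalidArgumentError("generations and sample_every must be >= 1")


@dataclass
class Trace:
    """MCMC output: scalar samples plus per-sample tree states."""

    topology: TimeTree
    scalars: pd.DataFrame
    heights: np.ndarray          # (n_samples, n_nodes)
    rates: np.ndarray            # (n_samples, n_nodes)
    config: MCMCConfig
    acceptance: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.scalars)

    def burned(self, fraction: float | None = None) -> "Trace":
        """Trace with the first ``fraction`` of samples removed."""
        frac = self.config.burnin_fraction if fraction is None else fraction
        k = int(np.floor(frac * self.n_samples))
        return Trace(self.topology, self.scalars.iloc[k:].reset_index(drop=True),
                     self.heights[k:], self.rates[k:], self.config,
                     self.acceptance)

    def tree_at(self, i: int) -> TimeTree:
        return self.topology.with_state(self.heights[i], self.rates[i])

    def tree_samples(self):
        for i in range(self.n_samples):
            yield self.tree_at(i)

    def ess_table(self) -> pd.Series:
        cols = [c for c in self.scalars.columns if c != "state"]
        return pd.Series({c: ess(self.scalars[c].to_numpy()) for c in cols})


def ess(samples: np.ndarray) -> float:
    """Effective sample size with initial-positive-sequence truncation:
    N / (1 + 2 * sum of autocorrelations up to the first non-positive)."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise InvalidArgumentError("need at least 10 samples")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real / (n * var)
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


@njit(cache=True)
def _lognormal_mean1_logpdf_sum(r: np.ndarray, sigma: float) -> float:
    mu = -0.5 * sigma * sigma
    tot = 0.0
    c = -np.log(sigma) - 0.5 * _LOG_2PI
    for i in range(r.size):
        if r[i] <= 0:
            return -np.inf
        lr = np.log(r[i])
        z = (lr - mu) / sigma
        tot += -lr + c - 0.5 * z * z
    return tot


@njit(cache=True)
def _yule_logp(h_internal: np.ndarray, birth: float) -> float:
    """Pure-birth log density of internal node heights (tips at 0):
    backward waiting times Exponential((k-1)*birth) while k lineages."""
    h = np.sort(h_internal)
    n = h.size + 1
    lp = 0.0
    prev = 0.0
    k = n
    for i in range(h.size):
        if h[i] < prev:
            return -np.inf
        rate = (k - 1) * birth
        lp += np.log(rate) - rate * (h[i] - prev)
        prev = h[i]
        k -= 1
    return lp


class _Sampler:
    def __init__(self, aln: Alignment | None, tree: TimeTree,
                 config: MCMCConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.tree = tree
        self.n_tips = tree.n_tips
        self.n_nodes = tree.n_nodes
        self.root = tree.root
        self.parent = tree.parent
        self.children = tree.children
        self.branch_ids = tree.branch_ids()
        self.internal = np.sort(tree.postorder_internal())
        self.nonroot_internal = self.internal[self.internal != self.root]
        # per-node subtree membership for the subtree stretch move
        leafsets = tree.leaf_sets()
        self._subtree_internal = {}
        self._subtree_edges = {}
        for v in self.nonroot_internal:
            desc = [u for u in range(self.n_nodes)
                    if u != v and leafsets[u] <= leafsets[v]]
            self._subtree_internal[v] = np.asarray(
                [v] + [u for u in desc if u >= self.n_tips], dtype=np.int64)
            self._subtree_edges[v] = np.asarray(desc, dtype=np.int64)

        # -- initial state --
        self.heights = self._init_heights(tree)
        self.rates = np.ones(self.n_nodes)
        self.rates[self.root] = 1.0  # unused slot kept finite
        self.exch = np.ones(6)
        self.freqs = np.full(4, 0.25)
        self.shape = 0.5
        self.pinv = 0.1
        self.ucld = 0.3
        self.birth = max(1.0, (self.n_tips - 1) /
                         max(self.heights[self.root], 1e-6))

        self.sl: StatefulLikelihood | None = None
        if config.likelihood_on:
            if aln is None:
                raise InvalidArgumentError("likelihood_on requires an alignment")
            if config.smart_init:
                self.freqs = np.maximum(aln.base_frequencies(), 1e-4)
                self.freqs /= self.freqs.sum()
                self.pinv = min(0.8, max(0.02, aln.proportion_invariant() * 0.8))
            engine = LikelihoodEngine(aln, tree)
            self.sl = StatefulLikelihood(engine, config.n_cat)
        self._eigen = None
        self._cat_rates = None
        self.loglik = self._full_loglik()
        self.logprior = self._compute_prior()

        # -- proposal tuning state --
        self.deltas = {"rate": 0.8, "height": 1.0, "root": 1.0,
                       "tree_scale": 0.4, "ucld": 0.7, "shape": 0.5,
                       "pinv": 0.15, "birth": 1.5, "exch": 0.5, "freqs": 0.1,
                       "ucld_rates": 0.5, "updown": 0.5, "subtree_updown": 0.5}
        self.acc: dict[str, list[int]] = {k: [0, 0] for k in self.deltas}
        self._tune_acc: dict[str, list[int]] = {k: [0, 0] for k in self.deltas}

    @staticmethod
    def _init_heights(tree: TimeTree) -> np.ndarray:
        h = tree.heights.copy()
        if tree.validate_heights() and h[tree.root] > 0 and tree.is_ultrametric(1e-6):
            return h
        h = np.zeros(tree.n_nodes)
        for node in tree.postorder_internal():
            c1, c2 = tree.children[node]
            h[node] = max(h[c1], h[c2]) + 0.05
        return h

    # -- posterior pieces ------------------------------------------------
    def _ensure_model_cache(self) -> None:
        if self._eigen is None:
            model = SubstitutionModel(self.exch.copy(), self.freqs.copy())
            self._eigen = model.eigensystem()
        if self._cat_rates is None:
            self._cat_rates = discrete_gamma_rates(self.shape, self.cfg.n_cat)

    def _lengths(self) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        b = self.branch_ids
        d[b] = (self.heights[self.parent[b]] - self.heights[b]) * self.rates[b]
        return d

    def _full_loglik(self) -> float:
        if self.sl is None:
            return 0.0
        self._ensure_model_cache()
        d = self._lengths()
        if np.any(d < 0):
            return -np.inf
        return self.sl.full_update(d, self._eigen, self._cat_rates,
                                   self.freqs, self.pinv)

    def _compute_prior(self) -> float:
        lo, hi = self.cfg.birth_bounds
        if not lo <= self.birth <= hi:
            return -np.inf
        if self.ucld <= 0 or self.shape <= 0 or not 0 <= self.pinv < 1:
            return -np.inf
        if self.exch.min() <= 0 or self.freqs.min() <= 0:
            return -np.inf
        lp = _yule_logp(self.heights[self.n_tips:], self.birth)
        if not np.isfinite(lp):
            return -np.inf
        lp += _lognormal_mean1_logpdf_sum(self.rates[self.branch_ids], self.ucld)
        r_u = 1.0 / self.cfg.ucld_prior_mean
        lp += np.log(r_u) - r_u * self.ucld
        r_s = 1.0 / self.cfg.shape_prior_mean
        lp += np.log(r_s) - r_s * self.shape
        sig = self.cfg.exch_prior_sigma
        le = np.log(self.exch[:5])
        lp += float(np.sum(-le - np.log(sig) - 0.5 * _LOG_2PI
                           - 0.5 * (le / sig) ** 2))
        lp += -np.log(self.birth)  # log-uniform birth rate within bounds
        return float(lp)

    # -- move machinery ---------------------------------------------------
    def _scale_factor(self, delta: float) -> float:
        return float(np.exp(delta * (self.rng.random() - 0.5)))

    def _edges_of_node_move(self, v: int) -> np.ndarray:
        """Branches whose length changes when height[v] moves."""
        edges = [int(c) for c in self.children[v]]
        if self.parent[v] >= 0:
            edges.append(v)
        return np.asarray(edges, dtype=np.int64)

    def step(self, move: str) -> bool:
        """One Metropolis-Hastings proposal; returns acceptance."""
        rng = self.rng
        log_h = 0.0
        lik_mode = "none"     # none | edges | root_only | full
        edges = None
        undo: list = []

        if move == "rate":
            i = int(self.branch_ids[rng.integers(self.branch_ids.size)])
            f = self._scale_factor(self.deltas["rate"])
            undo.append(("rates", i, self.rates[i]))
            self.rates[i] *= f
            log_h = np.log(f)
            lik_mode, edges = "edges", np.asarray([i], dtype=np.int64)
        elif move == "height":
            if self.nonroot_internal.size == 0:
                return False
            v = int(self.nonroot_internal[rng.integers(self.nonroot_internal.size)])
            lo = max(self.heights[int(self.children[v, 0])],
                     self.heights[int(self.children[v, 1])])
            hi = self.heights[self.parent[v]]
            undo.append(("heights", v, self.heights[v]))
            self.heights[v] = lo + rng.random() * (hi - lo)
            lik_mode, edges = "edges", self._edges_of_node_move(v)
        elif move == "root":
            v = self.root
            lo = max(self.heights[int(self.children[v, 0])],
                     self.heights[int(self.children[v, 1])])
            f = self._scale_factor(self.deltas["root"])
            undo.append(("heights", v, self.heights[v]))
            self.heights[v] = lo + (self.heights[v] - lo) * f
            log_h = np.log(f)
            lik_mode, edges = "edges", self._edges_of_node_move(v)
        elif move == "tree_scale":
            f = self._scale_factor(self.deltas["tree_scale"])
            undo.append(("heights_all", None, self.heights.copy()))
            self.heights[self.n_tips:] *= f
            log_h = (self.n_nodes - self.n_tips) * np.log(f)
            lik_mode = "full"
        elif move == "ucld":
            f = self._scale_factor(self.deltas["ucld"])
            undo.append(("ucld", None, self.ucld))
            self.ucld *= f
            log_h = np.log(f)
        elif move == "shape":
            f = self._scale_factor(self.deltas["shape"])
            undo.append(("shape", None, self.shape))
            self.shape *= f
            log_h = np.log(f)
            self._cat_rates = None
            lik_mode = "full"
        elif move == "pinv":
            w = self.deltas["pinv"]
            x = self.pinv + (rng.random() - 0.5) * w
            while x < 0 or x > 0.999:  # reflect at the boundaries
                x = -x if x < 0 else 2 * 0.999 - x
            undo.append(("pinv", None, self.pinv))
            self.pinv = x
            lik_mode = "root_only"
        elif move == "birth":
            f = self._scale_factor(self.deltas["birth"])
            undo.append(("birth", None, self.birth))
            self.birth *= f
            log_h = np.log(f)
        elif move == "ucld_rates":
            # scale sigma and stretch all log-rate deviations with it,
            # walking along the prior's funnel direction
            f = self._scale_factor(self.deltas["ucld_rates"])
            b = self.branch_ids
            undo.append(("ucld", None, self.ucld))
            undo.append(("rates_all", None, self.rates.copy()))
            mu_old = -0.5 * self.ucld ** 2
            self.ucld *= f
            mu_new = -0.5 * self.ucld ** 2
            lr_old = np.log(self.rates[b])
            lr_new = mu_new + (lr_old - mu_old) * f
            self.rates[b] = np.exp(lr_new)
            log_h = (b.size + 1) * np.log(f) + float(np.sum(lr_new - lr_old))
            lik_mode = "full"
        elif move == "subtree_updown":
            # scale a clade's internal heights by f and divide its crown
            # rates by f: crown branch lengths stay put, only the stem
            # length changes.  Traverses the rate-vs-time ridge directly.
            if self.nonroot_internal.size == 0:
                return False
            v = int(self.nonroot_internal[rng.integers(self.nonroot_internal.size)])
            f = self._scale_factor(self.deltas["subtree_updown"])
            sub_int = self._subtree_internal[v]
            sub_edges = self._subtree_edges[v]
            if self.heights[v] * f >= self.heights[self.parent[v]]:
                return False
            undo.append(("heights_all", None, self.heights.copy()))
            undo.append(("rates_all", None, self.rates.copy()))
            self.heights[sub_int] *= f
            self.rates[sub_edges] /= f
            log_h = (sub_int.size - sub_edges.size) * np.log(f)
            lik_mode = "edges"
            edges = np.concatenate((sub_edges, [v]))
        elif move == "updown":
            # heights x f, rates / f: branch lengths (and the likelihood)
            # are invariant; only the priors change
            f = self._scale_factor(self.deltas["updown"])
            b = self.branch_ids
            undo.append(("heights_all", None, self.heights.copy()))
            undo.append(("rates_all", None, self.rates.copy()))
            self.heights[self.n_tips:] *= f
            self.rates[b] /= f
            n_int = self.n_nodes - self.n_tips
            log_h = (n_int - b.size) * np.log(f)
        elif move == "exch":
            i = int(rng.integers(5))
            f = self._scale_factor(self.deltas["exch"])
            undo.append(("exch", i, self.exch[i]))
            self.exch[i] *= f
            log_h = np.log(f)
            self._eigen = None
            lik_mode = "full"
        elif move == "freqs":
            i, j = rng.choice(4, size=2, replace=False)
            d = rng.random() * self.deltas["freqs"]
            if self.freqs[i] - d <= 1e-4 or self.freqs[j] + d >= 1 - 1e-4:
                return False
            undo.append(("freqs", (int(i), int(j)),
                         (self.freqs[i], self.freqs[j])))
            self.freqs[i] -= d
            self.freqs[j] += d
            self._eigen = None
            lik_mode = "full"
        else:  # pragma: no cover
            raise InvalidArgumentError(f"unknown move {move!r}")

        new_prior = self._compute_prior()
        if not np.isfinite(new_prior):
            self._revert(undo, lik_mode, none_proposed=True)
            return False

        new_lik = self.loglik
        if self.sl is not None and lik_mode != "none":
            self._ensure_model_cache()
            if lik_mode == "edges":
                d = self._lengths()
                if np.any(d[edges] < 0):
                    self._revert(undo, "none", none_proposed=True)
                    return False
                new_lik = self.sl.propose_edges(edges, d, self._eigen,
                                                self._cat_rates, self.freqs,
                                                self.pinv)
            elif lik_mode == "root_only":
                new_lik = self.sl._root(self.freqs, self.pinv)
            else:  # full
                new_lik = self._full_loglik()

        log_alpha = (new_lik + new_prior) - (self.loglik + self.logprior) + log_h
        if np.log(rng.random()) < log_alpha:
            if self.sl is not None and lik_mode == "edges":
                self.sl.accept()
            self.loglik, self.logprior = new_lik, new_prior
            return True
        self._revert(undo, lik_mode)
        return False

    def _revert(self, undo, lik_mode: str, none_proposed: bool = False) -> None:
        for what, key, val in undo:
            if what == "rates":
                self.rates[key] = val
            elif what == "rates_all":
                self.rates[:] = val
            elif what == "heights":
                self.heights[key] = val
            elif what == "heights_all":
                self.heights[:] = val
            elif what == "ucld":
                self.ucld = val
            elif what == "shape":
                self.shape = val
                self._cat_rates = None
            elif what == "pinv":
                self.pinv = val
            elif what == "birth":
                self.birth = val
            elif what == "exch":
                self.exch[key] = val
                self._eigen = None
            elif what == "freqs":
                i, j = key
                self.freqs[i], self.freqs[j] = val
                self._eigen = None
        if self.sl is None or none_proposed:
            return
        if lik_mode == "edges":
            self.sl.reject()
        elif lik_mode == "full":
            # partials were overwritten at the rejected state: rebuild
            self.loglik = self._full_loglik()

    def _maybe_tune(self, move: str, accepted: bool, gen: int) -> None:
        if not self.cfg.tune or gen > self.cfg.burnin_fraction * self.cfg.generations:
            return
        rec = self._tune_acc[move]
        rec[0] += int(accepted)
        rec[1] += 1
        if rec[1] >= 30:
            rate = rec[0] / rec[1]
            if rate > 0.40:
                self.deltas[move] *= 1.25
            elif rate < 0.20:
                self.deltas[move] /= 1.25
            self.deltas[move] = float(np.clip(self.deltas[move], 1e-3, 10.0))
            rec[0] = rec[1] = 0

    # -- main loop -------------------------------------------------------
    def run(self) -> Trace:
        cfg = self.cfg
        names = list(cfg.move_weights)
        weights = np.array([cfg.move_weights[m] for m in names], dtype=float)
        for k, m in enumerate(names):
            if m == "rate":
                weights[k] *= self.branch_ids.size
            elif m == "height":
                weights[k] *= max(self.nonroot_internal.size, 1)
        weights /= weights.sum()
        n_samples = cfg.generations // cfg.sample_every + 1
        scal = np.empty((n_samples, len(SCALAR_COLUMNS)))
        hts = np.empty((n_samples, self.n_nodes))
        rts = np.empty((n_samples, self.n_nodes))
        row = 0

        def record(gen: int) -> None:
            nonlocal row
            scal[row, 0] = gen
            scal[row, 1] = self.loglik + self.logprior
            scal[row, 2] = self.loglik
            scal[row, 3] = self.logprior
            scal[row, 4:8] = (self.ucld, self.shape, self.pinv, self.birth)
            scal[row, 8:13] = self.exch[:5]
            scal[row, 13:17] = self.freqs
            hts[row] = self.heights
            rts[row] = self.rates
            row += 1

        record(0)
        move_draws = self.rng.choice(len(names), size=cfg.generations, p=weights)
        for gen in range(1, cfg.generations + 1):
            move = names[move_draws[gen - 1]]
            accepted = self.step(move)
            rec = self.acc[move]
            rec[0] += int(accepted)
            rec[1] += 1
            self._maybe_tune(move, accepted, gen)
            if gen % cfg.sample_every == 0:
                record(gen)
        scalars = pd.DataFrame(scal[:row], columns=SCALAR_COLUMNS)
        rts_out = rts[:row].copy()
        rts_out[:, self.root] = np.nan
        return Trace(self.tree.copy(), scalars, hts[:row], rts_out, cfg,
                     {m: (a, p) for m, (a, p) in self.acc.items()})


def mcmc_run(aln: Alignment | None, constraint_tree: TimeTree,
             config: MCMCConfig) -> Trace:
    """Run the relaxed-clock sampler on a fully resolved constraint topology.

    The topology is fixed throughout; node heights, branch rates and all
    substitution-model parameters are sampled.  Returns the full trace
    (burn-in NOT removed; use ``trace.burned()``).
    """
    if constraint_tree.n_tips < 3:
        raise ConstraintError("constraint tree needs at least 3 tips")
    if aln is not None:
        missing = set(constraint_tree.labels) ^ set(aln.taxa)
        if missing:
            raise ConstraintError(
                f"constraint tree and alignment taxa differ: {sorted(missing)}")
    sampler = _Sampler(aln, constraint_tree, config)
    return sampler.run()
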