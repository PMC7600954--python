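"""Felsenstein pruning log-likelihood under GTR+Γ+I on a fixed topology.

Site patterns are compressed once and the per-pattern recursion runs in
numba-compiled kernels with per-node rescaling.  Two entry points:

* :func:`pruning_loglik` / :meth:`LikelihoodEngine.loglik` — stateless
  full evaluation, used by distance/model estimation and tests.
* :class:`StatefulLikelihood` — keeps partial likelihoods per node and
  recomputes only the path from an edited branch to the root, which is
  what makes the MCMC's single-branch moves cheap.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .alignment import Alignment
from .errors import InvalidArgumentError
from .models import SubstitutionModel
from .trees import TimeTree

_TINY = 1e-300


@njit(cache=True, fastmath=True)
def _update_partials(L, nodescale, scale_sum, tipL, P, nodes, children, n_tips):
    """Recompute partials at ``nodes`` (children-first order) for all
    gamma categories, maintaining the per-pattern running log-scale sum.
    Rescaling kicks in only when values drift below 1e-140, keeping the
    hot path free of logarithms on shallow trees."""
    n_cat = P.shape[1]
    n_pat = tipL.shape[1]
    for c in range(n_cat):
        for k in range(nodes.size):
            v = nodes[k]
            c1 = children[v, 0]
            c2 = children[v, 1]
            L1 = tipL[c1] if c1 < n_tips else L[c, c1]
            L2 = tipL[c2] if c2 < n_tips else L[c, c2]
            P1 = P[c1, c]
            P2 = P[c2, c]
            for s in range(n_pat):
                m = 0.0
                for i in range(4):
                    a = (P1[i, 0] * L1[s, 0] + P1[i, 1] * L1[s, 1]
                         + P1[i, 2] * L1[s, 2] + P1[i, 3] * L1[s, 3])
                    b = (P2[i, 0] * L2[s, 0] + P2[i, 1] * L2[s, 1]
                         + P2[i, 2] * L2[s, 2] + P2[i, 3] * L2[s, 3])
                    val = a * b
                    L[c, v, s, i] = val
                    if val > m:
                        m = val
                new_sc = 0.0
                if 0.0 < m < 1e-140:
                    inv = 1.0 / m
                    for i in range(4):
                        L[c, v, s, i] *= inv
                    new_sc = np.log(m)
                old_sc = nodescale[c, v, s]
                if new_sc != old_sc:
                    scale_sum[c, s] += new_sc - old_sc
                    nodescale[c, v, s] = new_sc


@njit(cache=True, fastmath=True)
def _root_loglik(L, scale_sum, root, freqs, p_inv, pconst, weights):
    """Combine partials and per-pattern scale sums into the log-likelihood."""
    n_cat = L.shape[0]
    n_pat = L.shape[2]
    log_w = np.log(1.0 / n_cat)
    total = 0.0
    vals = np.empty(n_cat)
    for s in range(n_pat):
        mx = -np.inf
        for c in range(n_cat):
            tot = 0.0
            for i in range(4):
                tot += freqs[i] * L[c, root, s, i]
            if tot <= 0.0:
                tot = _TINY
            vals[c] = np.log(tot) + scale_sum[c, s]
            if vals[c] > mx:
                mx = vals[c]
        acc = 0.0
        for c in range(n_cat):
            acc += np.exp(vals[c] - mx)
        var_part = mx + log_w + np.log(acc)
        if p_inv > 0.0:
            inv_part = -np.inf
            if pconst[s] > 0.0:
                inv_part = np.log(p_inv * pconst[s])
            a1 = np.log1p(-p_inv) + var_part
            hi = a1 if a1 > inv_part else inv_part
            site = hi + np.log(np.exp(a1 - hi) + np.exp(inv_part - hi))
        else:
            site = var_part
        total += site * weights[s]
    return total


def _tip_partials(patterns: np.ndarray) -> np.ndarray:
    """(n_tips, n_pat, 4) indicator partials from bitmask patterns."""
    masks = patterns.T.astype(np.uint8).copy()
    masks[masks == 0] = 15  # gap/unknown observes every state
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    return ((masks[:, :, None] & bits[None, None, :]) > 0).astype(np.float64)


class LikelihoodEngine:
    """Stateless pruning-likelihood evaluator for one alignment + topology."""

    def __init__(self, aln: Alignment, tree: TimeTree):
        if set(aln.taxa) != set(tree.labels):
            only_a = sorted(set(aln.taxa) - set(tree.labels))
            only_t = sorted(set(tree.labels) - set(aln.taxa))
            raise InvalidArgumentError(
                f"alignment/tree taxon mismatch: alignment-only {only_a}, "
                f"tree-only {only_t}")
        aln = aln.subset_taxa(tree.labels)  # rows in tree tip order
        patterns, weights = aln.site_patterns()
        self.n_tips = tree.n_tips
        self.n_nodes = tree.n_nodes
        self.root = tree.root
        self.children = tree.children.copy()
        self.order = tree.postorder_internal().copy()
        self.parent = tree.parent.copy()
        self.weights = weights
        self.tipL = _tip_partials(patterns)
        masks = patterns.astype(np.uint8).copy()
        masks[masks == 0] = 15
        self._and_mask = np.bitwise_and.reduce(masks, axis=1)
        self.n_sites = int(weights.sum())
        self.n_patterns = weights.size

    def const_probs(self, freqs: np.ndarray) -> np.ndarray:
        """P(pattern could be an invariant-site realization), per pattern."""
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        allowed = (self._and_mask[:, None] & bits[None, :]) > 0
        return allowed @ freqs

    def transition_tensor(self, lengths: np.ndarray, eigen,
                          cat_rates: np.ndarray) -> np.ndarray:
        """(n_nodes, n_cat, 4, 4) transition matrices per branch x category."""
        lam, u, uinv = eigen
        t = np.asarray(lengths)[:, None] * cat_rates[None, :]
        e = np.exp(t[:, :, None] * lam[None, None, :])
        P = (u[None, None] * e[:, :, None, :]) @ uinv
        np.clip(P, 0.0, None, out=P)
        return np.ascontiguousarray(P)

    def branch_lengths(self, heights: np.ndarray, rates: np.ndarray) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        d[mask] = (heights[self.parent[mask]] - heights[mask]) * rates[mask]
        return d

    def loglik(self, heights: np.ndarray, rates: np.ndarray,
               model: SubstitutionModel, eigen=None,
               cat_rates: np.ndarray | None = None) -> float:
        """Full log-likelihood at the given node heights and branch rates."""
        d = self.branch_lengths(heights, rates)
        if np.any(d < -1e-12):
            return -np.inf
        return self.loglik_lengths(np.maximum(d, 0.0), model, eigen, cat_rates)

    def loglik_lengths(self, lengths: np.ndarray, model: SubstitutionModel,
                       eigen=None, cat_rates: np.ndarray | None = None) -> float:
        """Full log-likelihood given expected substitutions per branch."""
        if eigen is None:
            eigen = model.eigensystem()
        if cat_rates is None:
            cat_rates, _ = model.category_rates()
        P = self.transition_tensor(lengths, eigen, cat_rates)
        n_cat = cat_rates.size
        L = np.empty((n_cat, self.n_nodes, self.n_patterns, 4))
        nodescale = np.zeros((n_cat, self.n_nodes, self.n_patterns))
        scale_sum = np.zeros((n_cat, self.n_patterns))
        _update_partials(L, nodescale, scale_sum, self.tipL, P, self.order,
                         self.children, self.n_tips)
        pconst = (self.const_probs(model.freqs) if model.p_inv > 0
                  else np.zeros(self.n_patterns))
        return float(_root_loglik(L, scale_sum, self.root, model.freqs,
                                  float(model.p_inv), pconst, self.weights))


class StatefulLikelihood:
    """Persistent partials with dirty-path updates for the MCMC inner loop.

    Call pattern: ``propose_*`` evaluates the likelihood at a modified
    state, then either ``accept()`` keeps the new partials or
    ``reject()`` restores the saved ones.
    """

    def __init__(self, engine: LikelihoodEngine, n_cat: int):
        self.e = engine
        self.n_cat = n_cat
        self.L = np.empty((n_cat, engine.n_nodes, engine.n_patterns, 4))
        self.nodescale = np.zeros((n_cat, engine.n_nodes, engine.n_patterns))
        self.scale_sum = np.zeros((n_cat, engine.n_patterns))
        self.P = np.zeros((engine.n_nodes, n_cat, 4, 4))
        # ancestor chains: node -> internal nodes from it up to the root
        self._chain = {}
        for v in range(engine.n_nodes):
            chain = []
            x = v if v >= engine.n_tips else engine.parent[v]
            while x >= 0:
                if x >= engine.n_tips:
                    chain.append(x)
                x = engine.parent[x]
            self._chain[v] = np.asarray(chain, dtype=np.int64)
        self._saved: tuple | None = None

    # -- full state initialization --------------------------------------
    def full_update(self, lengths: np.ndarray, eigen, cat_rates: np.ndarray,
                    freqs: np.ndarray, p_inv: float) -> float:
        self.P[:] = self.e.transition_tensor(lengths, eigen, cat_rates)
        self.nodescale[:] = 0.0
        self.scale_sum[:] = 0.0
        _update_partials(self.L, self.nodescale, self.scale_sum, self.e.tipL,
                         self.P, self.e.order, self.e.children, self.e.n_tips)
        self._saved = None
        return self._root(freqs, p_inv)

    def _root(self, freqs: np.ndarray, p_inv: float) -> float:
        pconst = (self.e.const_probs(freqs) if p_inv > 0
                  else np.zeros(self.e.n_patterns))
        return float(_root_loglik(self.L, self.scale_sum, self.e.root, freqs,
                                  float(p_inv), pconst, self.e.weights))

    # -- partial updates --------------------------------------------------
    def propose_edges(self, edges: np.ndarray, lengths: np.ndarray, eigen,
                      cat_rates: np.ndarray, freqs: np.ndarray,
                      p_inv: float) -> float:
        """New likelihood after the branch lengths of ``edges`` changed."""
        dirty = self._chain[int(edges[0])]
        for v in edges[1:]:
            ch = self._chain[int(v)]
            if ch.size > dirty.size:
                dirty = ch
        # union of chains: chains share a suffix, so the longest chain of a
        # single edited node covers it only when edges share an ancestor path;
        # for safety take the explicit union in tree order
        if len(edges) > 1:
            seen = set()
            for v in edges:
                seen.update(self._chain[int(v)].tolist())
            dirty = np.asarray([n for n in self.e.order if n in seen],
                               dtype=np.int64)
        self._saved = (dirty.copy(), self.L[:, dirty].copy(),
                       self.nodescale[:, dirty].copy(),
                       self.scale_sum.copy(),
                       edges.copy(), self.P[edges].copy())
        lam, u, uinv = eigen
        t = lengths[edges][:, None] * cat_rates[None, :]
        e = np.exp(t[:, :, None] * lam[None, None, :])
        Pnew = (u[None, None] * e[:, :, None, :]) @ uinv
        np.clip(Pnew, 0.0, None, out=Pnew)
        self.P[edges] = Pnew
        _update_partials(self.L, self.nodescale, self.scale_sum, self.e.tipL,
                         self.P, dirty, self.e.children, self.e.n_tips)
        return self._root(freqs, p_inv)

    def accept(self) -> None:
        self._saved = None

    def reject(self) -> None:
        if self._saved is None:
            return
        dirty, L, ns, ssum, edges, P = self._saved
        self.L[:, dirty] = L
        self.nodescale[:, dirty] = ns
        self.scale_sum[:] = ssum
        self.P[edges] = P
        self._saved = None


def pruning_loglik(tree: TimeTree, model: SubstitutionModel,
                   aln: Alignment) -> float:
    """One-shot pruning log-likelihood of ``aln`` on ``tree`` under ``model``.

    Branch expected substitutions are ``rate x time span``; branch rates
    must already be attached to the tree.
    """
    if np.isnan(tree.rates[tree.branch_ids()]).any():
        raise InvalidArgumentError("tree is missing branch rates")
    engine = LikelihoodEngine(aln, tree)
    return engine.loglik(tree.heights, tree.rates, model)
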