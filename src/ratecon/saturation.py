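"""Substitution-saturation diagnostics.

Two complementary screens decide whether fast-evolving sites (codon
position 3 in protein-coding mitochondrial genes) still carry usable
phylogenetic signal:

1. Linearity of uncorrected p-distances against GTR model-corrected
   distances, summarized by the coefficient of determination of a
   regression through the origin, computed per codon partition.
   Saturation makes uncorrected distances plateau, dragging R^2 down.

2. The entropy-based index of substitution saturation (Iss): mean
   per-site entropy of the variable fraction of sites relative to the
   expected entropy of a fully saturated column, compared against a
   simulation-derived critical value Iss.c at which neighbor-joining
   stops recovering the true topology reliably.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import multinomial as _multinomial
from scipy.stats import t as _t_dist

from .alignment import _BASE_INDEX_LUT, Alignment, encode_sequence
from .errors import (DegenerateFrequenciesError, DegenerateModelError,
                     InvalidArgumentError, UndefinedDistanceError)
from .models import SubstitutionModel
from .trees import TimeTree

__all__ = [
    "p_distance", "estimate_gtr", "gtr_distance", "regression_through_origin",
    "saturation_regression", "site_entropy", "iss", "iss_jackknife",
    "iss_critical", "iss_test", "SaturationRegression", "SaturationReport",
    "IssTestResult", "expected_saturation_entropy",
]


def _coerce(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode_sequence(seq)
    return np.asarray(seq, dtype=np.uint8)


def _pair_base_indices(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Base indices at sites where both sequences are unambiguous bases."""
    a, b = _coerce(a), _coerce(b)
    if a.shape != b.shape:
        raise InvalidArgumentError("sequences differ in length")
    ia, ib = _BASE_INDEX_LUT[a], _BASE_INDEX_LUT[b]
    ok = (ia >= 0) & (ib >= 0)
    return ia[ok], ib[ok]


def p_distance(a, b) -> float:
    """Uncorrected proportion of differing sites (pairwise deletion)."""
    ia, ib = _pair_base_indices(a, b)
    if ia.size == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    return float(np.mean(ia != ib))


def pair_counts(a, b) -> np.ndarray:
    """4x4 matrix of joint base counts over comparable sites."""
    ia, ib = _pair_base_indices(a, b)
    return np.bincount(ia * 4 + ib, minlength=16).reshape(4, 4).astype(float)


def gtr_distance(a, b, model: SubstitutionModel,
                 max_distance: float = 20.0) -> float:
    """Model-corrected pairwise distance: the branch length maximizing the
    two-sequence likelihood under the fixed GTR(+Γ) model."""
    counts = pair_counts(a, b)
    if counts.sum() == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    if np.trace(counts) == counts.sum():
        return 0.0
    lam, u, uinv = model.eigensystem()
    cat_rates, cat_w = model.category_rates()
    logpi = np.log(model.freqs)

    def neg_loglik(t: float) -> float:
        e = np.exp(np.multiply.outer(t * cat_rates, lam))
        p = (u[None] * e[:, None, :]) @ uinv
        p = np.clip(p, 1e-300, None)
        mix = np.tensordot(cat_w, p, axes=1)
        return -float((counts * (logpi[:, None] + np.log(mix))).sum())

    res = minimize_scalar(neg_loglik, bounds=(1e-9, max_distance),
                          method="bounded",
                          options={"xatol": 1e-10})
    d = float(res.x)
    if d > max_distance * (1 - 1e-4):
        warnings.warn("saturated pair: distance capped at the configured "
                      f"maximum {max_distance}", stacklevel=2)
        return max_distance
    return d


def estimate_gtr(aln: Alignment) -> SubstitutionModel:
    """Fit GTR exchangeabilities by maximum likelihood on a neighbor-joining
    guide tree built from p-distances; frequencies are empirical counts."""
    from .likelihood import LikelihoodEngine

    if aln.n_taxa < 3:
        raise InvalidArgumentError("GTR estimation needs at least 3 taxa")
    if not aln.variable_site_mask().any():
        raise DegenerateModelError("alignment has no variable sites")
    freqs = np.maximum(aln.base_frequencies(), 1e-6)
    freqs = freqs / freqs.sum()
    n = aln.n_taxa
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = p_distance(aln.codes[i], aln.codes[j])
    # Poisson-correct the p-distances so the guide tree's branch lengths
    # start near the ML scale (capped where the correction diverges)
    plateau = 1.0 - float(freqs @ freqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = -plateau * np.log(np.maximum(1.0 - dm / plateau, 1e-6))
    np.fill_diagonal(corr, 0.0)
    guide = _nj_timetree(corr, aln.taxa)
    engine = LikelihoodEngine(aln, guide)
    blens = guide.durations()
    edge_ids = guide.branch_ids()
    b0 = np.maximum(blens[edge_ids], 1e-4)
    x0 = np.concatenate([np.log(b0), np.zeros(5)])

    def neg_loglik(x: np.ndarray) -> float:
        b = np.exp(np.clip(x[: edge_ids.size], -20, 5))
        exch = np.concatenate([np.exp(np.clip(x[edge_ids.size:], -8, 8)), [1.0]])
        model = SubstitutionModel(exch, freqs)
        lengths = np.zeros(guide.n_nodes)
        lengths[edge_ids] = b
        return -engine.loglik_lengths(lengths, model)

    res = minimize(neg_loglik, x0, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12})
    exch = np.concatenate([np.exp(res.x[edge_ids.size:]), [1.0]])
    return SubstitutionModel(exch, freqs)


def _nj_timetree(dm: np.ndarray, labels: list[str]) -> TimeTree:
    """Rooted binary TimeTree from a neighbor-joining run (branch lengths
    become height differences; negative NJ edges are clamped to zero)."""
    import dendropy

    newick = _nj_newick(dm, labels)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    tree.resolve_polytomies(limit=2)
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length < 0:
            edge.length = 0.0
    return TimeTree.from_dendropy(tree)


def _nj_newick(dm: np.ndarray, labels: list[str]) -> str:
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = [f"x{i}" for i in range(len(labels))]  # avoid label quoting issues
    tree = nj(DistanceMatrix(dm, ids))
    newick = str(tree).strip()
    for i, lab in enumerate(labels):
        newick = newick.replace(f"x{i}:", f"'{lab}':")
    return newick


def regression_through_origin(x, y) -> tuple[float, float]:
    """Least-squares slope through the origin and the uncentered R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InvalidArgumentError("need equally sized vectors of length >= 2")
    sxx = float(x @ x)
    if sxx == 0:
        raise InvalidArgumentError("all x values are zero")
    slope = float(x @ y) / sxx
    syy = float(y @ y)
    if syy == 0:
        return slope, 1.0
    resid = y - slope * x
    return slope, 1.0 - float(resid @ resid) / syy


@dataclass
class SaturationRegression:
    partition: str
    slope: float
    r2: float
    n_pairs: int
    low_information: bool = False


@dataclass
class SaturationReport:
    regressions: list[SaturationRegression]
    include_codon3: bool
    threshold: float
    model: SubstitutionModel

    def r2(self, partition: str) -> float:
        for reg in self.regressions:
            if reg.partition == partition:
                return reg.r2
        raise KeyError(partition)


_PARTITIONS = (("1", (1,)), ("2", (2,)), ("3", (3,)),
               ("12", (1, 2)), ("123", (1, 2, 3)))


def saturation_regression(aln: Alignment, model: SubstitutionModel | None = None,
                          include_threshold: float = 0.01,
                          max_distance: float = 20.0) -> SaturationReport:
    """Per-partition regression of uncorrected on model-corrected distances.

    The GTR model is estimated once on the full alignment and reused for
    every partition's corrected distances.  Codon 3 is recommended for
    inclusion iff R^2(all positions) >= R^2(codons 1+2) - threshold.
    """
    if model is None:
        model = estimate_gtr(aln)
    n = aln.n_taxa
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    regs: list[SaturationRegression] = []
    for label, positions in _PARTITIONS:
        sub = aln.codon_partition(positions)
        xs, ys = [], []
        for i, j in pairs:
            try:
                y = p_distance(sub.codes[i], sub.codes[j])
                x = gtr_distance(sub.codes[i], sub.codes[j], model,
                                 max_distance=max_distance)
            except UndefinedDistanceError:
                continue
            xs.append(x)
            ys.append(y)
        if len(xs) == 1 and xs[0] != 0:
            # two-taxon alignment: a single point fits exactly
            regs.append(SaturationRegression(label, ys[0] / xs[0], 1.0, 1,
                                             low_information=True))
            continue
        if len(xs) < 2 or not np.any(np.asarray(xs) != 0):
            warnings.warn(f"partition {label}: fewer than 2 informative pairs; "
                          "skipped", stacklevel=2)
            regs.append(SaturationRegression(label, np.nan, np.nan, len(xs),
                                             low_information=True))
            continue
        slope, r2 = regression_through_origin(xs, ys)
        regs.append(SaturationRegression(label, slope, r2, len(xs),
                                         low_information=len(xs) < 3))
    by = {r.partition: r for r in regs}
    include = True
    if np.isfinite(by["12"].r2) and np.isfinite(by["123"].r2):
        include = by["123"].r2 >= by["12"].r2 - include_threshold
    return SaturationReport(regs, include, include_threshold, model)


def site_entropy(counts) -> float:
    """Shannon entropy (bits) of a site's unambiguous base counts."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise InvalidArgumentError("empty column")
    f = c[c > 0] / total
    return float(-(f * np.log2(f)).sum())


@lru_cache(maxsize=256)
def _expected_entropy_cached(m: int, freqs_key: tuple[float, ...]) -> float:
    p = np.array(freqs_key)
    p = p / p.sum()
    idx = np.indices((m + 1, m + 1, m + 1)).reshape(3, -1).T
    idx = idx[idx.sum(axis=1) <= m]
    counts = np.column_stack([idx, m - idx.sum(axis=1)])
    pmf = _multinomial.pmf(counts, n=m, p=p)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = counts / m
        h = -np.where(counts > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0).sum(axis=1)
    return float(np.sum(pmf * h))


def expected_saturation_entropy(m: int, freqs) -> float:
    """Expected column entropy at full saturation: every one of ``m``
    sequences drawn i.i.d. from the base frequencies."""
    p = np.asarray(freqs, dtype=float)
    if m < 2:
        raise InvalidArgumentError("need at least 2 sequences")
    return _expected_entropy_cached(m, tuple(np.round(p, 10)))


def _column_entropies(aln: Alignment) -> np.ndarray:
    idx = aln.base_indices()
    counts = np.stack([(idx == b).sum(axis=0) for b in range(4)], axis=1)
    totals = counts.sum(axis=1)
    ent = np.full(aln.n_sites, np.nan)
    ok = totals > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = counts[ok] / totals[ok, None]
        h = np.where(counts[ok] > 0, -f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    ent[ok] = h.sum(axis=1)
    return ent


def iss(aln_subset: Alignment, p_inv: float) -> float:
    """Index of substitution saturation for one taxon subset.

    Mean entropy of the ``round((1 - p_inv) * n_sites)`` most variable
    columns, divided by the expected entropy of a fully saturated column
    for this subset size and its empirical base frequencies.
    """
    if aln_subset.n_taxa < 4:
        raise InvalidArgumentError("Iss needs at least 4 sequences")
    if not 0.0 <= p_inv <= 1.0:
        raise InvalidArgumentError("p_inv must be in [0, 1]")
    ent = _column_entropies(aln_subset)
    ent = ent[np.isfinite(ent)]
    n_used = iss_sites_used(aln_subset.n_sites, p_inv)
    if n_used < 1:
        raise InvalidArgumentError("p_inv leaves no sites for the test")
    used = np.sort(ent)[::-1][:n_used]
    h_fss = expected_saturation_entropy(aln_subset.n_taxa,
                                        aln_subset.base_frequencies())
    if h_fss <= 0:
        raise DegenerateFrequenciesError(
            "single-base composition: full-saturation entropy is zero")
    return float(used.mean() / h_fss)


def iss_sites_used(n_sites: int, p_inv: float) -> int:
    """Number of sites entering the Iss statistic (df = this - 1)."""
    return int(round((1.0 - p_inv) * n_sites))


def iss_jackknife(aln: Alignment, num_otu: int, replicates: int,
                  p_inv: float, seed: int) -> tuple[float, float]:
    """Mean and standard error of Iss over random taxon subsets."""
    if num_otu > aln.n_taxa:
        raise InvalidArgumentError(
            f"num_otu={num_otu} exceeds taxon count {aln.n_taxa}")
    if replicates < 2:
        raise InvalidArgumentError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    vals = np.empty(replicates)
    for r in range(replicates):
        pick = rng.choice(aln.n_taxa, size=num_otu, replace=False)
        vals[r] = iss(aln.subset_taxa([aln.taxa[i] for i in pick]), p_inv)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(replicates))


# -- critical Iss via topology-recovery simulation ------------------------

def _shaped_tree(num_otu: int, shape: str, depth: float) -> TimeTree:
    """Ultrametric balanced ('sym') or caterpillar ('asym') tree of the
    given root height, with all branch rates 1."""
    n = num_otu
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    heights = np.zeros(2 * n - 1)
    if shape == "sym":
        levels = int(np.log2(n))
        if 2 ** levels != n:
            raise InvalidArgumentError("symmetric shape needs a power-of-2 "
                                       "taxon count")
        # pair up nodes level by level
        current = list(range(n))
        nxt = n
        level = 1
        while len(current) > 1:
            new = []
            for k in range(0, len(current), 2):
                a, b = current[k], current[k + 1]
                parent[a] = parent[b] = nxt
                children[nxt] = (a, b)
                heights[nxt] = depth * level / levels
                new.append(nxt)
                nxt += 1
            current = new
            level += 1
    elif shape == "asym":
        # caterpillar with every branch (spine and pendant) of equal
        # length, the classic equal-branch asymmetric test topology;
        # deliberately non-ultrametric
        b = depth / (n - 1)
        current = 0
        nxt = n
        for k in range(1, n):
            other = k
            heights[other] = (k - 1) * b
            parent[current] = parent[other] = nxt
            children[nxt] = (current, other)
            heights[nxt] = k * b
            current = nxt
            nxt += 1
    else:
        raise InvalidArgumentError("topology_shape must be 'sym' or 'asym'")
    labels = [f"t{i + 1}" for i in range(n)]
    tree = TimeTree(labels, parent, children, heights)
    rates = np.ones(tree.n_nodes)
    rates[tree.root] = np.nan
    tree.rates = rates
    return tree


def _nj_recovers(aln: Alignment, true_tree: TimeTree) -> bool:
    import dendropy
    from dendropy.calculate import treecompare

    n = aln.n_taxa
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = p_distance(aln.codes[i], aln.codes[j])
    ns = dendropy.TaxonNamespace()
    est = dendropy.Tree.get(data=_nj_newick(dm, aln.taxa), schema="newick",
                            taxon_namespace=ns, suppress_internal_node_taxa=True)
    truth = dendropy.Tree.get(data=true_tree.newick(), schema="newick",
                              taxon_namespace=ns,
                              suppress_internal_node_taxa=True)
    est.encode_bipartitions()
    truth.encode_bipartitions()
    return treecompare.symmetric_difference(est, truth) == 0


def iss_critical(num_otu: int, n_sites: int, freqs, topology_shape: str,
                 seed: int, reliability: float = 0.95,
                 depths: np.ndarray | None = None,
                 replicates: int = 16) -> float:
    """Simulation-estimated Iss at which NJ recovery of the true topology
    drops to ``reliability``, on balanced ('sym') or caterpillar ('asym')
    topologies over a grid of increasing tree depths."""
    from .synthetic import simulate_alignment

    if num_otu < 4:
        raise InvalidArgumentError("num_otu must be >= 4")
    if n_sites < 100:
        raise InvalidArgumentError("need at least 100 sites")
    if depths is None:
        depths = np.geomspace(0.02, 6.0, 8)
    model = SubstitutionModel(np.ones(6), np.asarray(freqs, dtype=float))
    sim_sites = int(np.ceil(n_sites / 3)) * 3
    rng_seeds = np.random.SeedSequence(seed).spawn(len(depths) * replicates)
    mean_iss = np.empty(len(depths))
    recovery = np.empty(len(depths))
    k = 0
    for di, depth in enumerate(depths):
        tree = _shaped_tree(num_otu, topology_shape, depth)
        vals, hits = [], []
        for _ in range(replicates):
            s = int(rng_seeds[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            aln = simulate_alignment(tree, model, sim_sites, seed=s)
            vals.append(iss(aln, p_inv=0.0))
            hits.append(_nj_recovers(aln, tree))
        mean_iss[di] = np.mean(vals)
        recovery[di] = np.mean(hits)
    # recovery rises with depth (signal accumulates) then falls as
    # saturation erases it; the critical Iss sits at the post-peak
    # crossing of the reliability threshold
    peak = int(np.argmax(recovery))
    if recovery[peak] < reliability:
        warnings.warn("recovery never reached the reliability threshold "
                      "(too few sites for this subset size); returning Iss "
                      "at the best-recovery depth", stacklevel=2)
        return float(mean_iss[peak])
    below = peak + np.flatnonzero(recovery[peak:] < reliability)
    if below.size == 0:
        warnings.warn("recovery never fell below the reliability threshold; "
                      "returning Iss at the deepest grid point", stacklevel=2)
        return float(mean_iss[-1])
    b = int(below[0])
    a = b - 1
    frac = (recovery[a] - reliability) / (recovery[a] - recovery[b])
    return float(mean_iss[a] + frac * (mean_iss[b] - mean_iss[a]))


@dataclass
class IssTestResult:
    num_otu: int
    iss_mean: float
    iss_se: float
    iss_c_sym: float
    iss_c_asym: float
    t_sym: float
    t_asym: float
    df: int
    p_sym: float
    p_asym: float
    verdict_sym: str = ""
    verdict_asym: str = ""


def _verdict(mean: float, crit: float, p: float, alpha: float) -> str:
    if p >= alpha:
        return "inconclusive"
    return "no significant saturation" if mean < crit else "significant saturation"


def iss_test(aln: Alignment, p_inv: float, seed: int,
             num_otus: tuple[int, ...] = (4, 8, 16, 32),
             replicates: int = 100, alpha: float = 0.05,
             critical_kwargs: dict | None = None) -> list[IssTestResult]:
    """Full Iss battery: jackknifed Iss per subset size against simulated
    critical values for symmetric and asymmetric topologies."""
    critical_kwargs = dict(critical_kwargs or {})
    battery = [k for k in num_otus if k <= aln.n_taxa]
    if not battery:
        raise InvalidArgumentError("alignment too small for any subset size")
    n_used = iss_sites_used(aln.n_sites, p_inv)
    df = n_used - 1
    freqs = aln.base_frequencies()
    ss = np.random.SeedSequence(seed).spawn(3 * len(battery))
    results = []
    for bi, k in enumerate(battery):
        s_jack, s_sym, s_asym = (int(s.generate_state(1)[0] % (2 ** 31))
                                 for s in ss[3 * bi: 3 * bi + 3])
        mean, se = iss_jackknife(aln, k, replicates, p_inv, s_jack)
        c_sym = iss_critical(k, aln.n_sites, freqs, "sym", s_sym,
                             **critical_kwargs)
        c_asym = iss_critical(k, aln.n_sites, freqs, "asym", s_asym,
                              **critical_kwargs)
        ts, ps = [], []
        for crit in (c_sym, c_asym):
            if se == 0:
                t = np.inf if mean != crit else 0.0
                p = 0.0 if mean != crit else 1.0
            else:
                t = abs(crit - mean) / se
                p = 2.0 * float(_t_dist.sf(t, df))
            ts.append(t)
            ps.append(p)
        results.append(IssTestResult(
            num_otu=k, iss_mean=mean, iss_se=se, iss_c_sym=c_sym,
            iss_c_asym=c_asym, t_sym=ts[0], t_asym=ts[1], df=df,
            p_sym=ps[0], p_asym=ps[1],
            verdict_sym=_verdict(mean, c_sym, ps[0], alpha),
            verdict_asym=_verdict(mean, c_asym, ps[1], alpha)))
    return results
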