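import itertools

import numpy as np
import pytest

from ratecon.alignment import Alignment
from ratecon.errors import InvalidArgumentError
from ratecon.likelihood import (LikelihoodEngine, StatefulLikelihood,
                                pruning_loglik)
from ratecon.models import SubstitutionModel, discrete_gamma_rates
from ratecon.synthetic import simulate_dataset
from ratecon.trees import TimeTree


def brute_force_loglik(tree, model, aln):
    """Exhaustive sum over internal-state assignments, per site."""
    cat_rates, cat_w = model.category_rates()
    d = tree.durations() * np.where(np.isfinite(tree.rates), tree.rates, 0.0)
    idx = aln.base_indices()
    internals = tree.postorder_internal()
    pi = model.freqs
    total = 0.0
    for s in range(aln.n_sites):
        tips = idx[:, s]
        site = 0.0
        if model.p_inv > 0:
            states = set(range(4))
            for x in tips:
                if x >= 0:
                    states &= {x}
            site += model.p_inv * sum(pi[x] for x in states)
        for cr, cw in zip(cat_rates, cat_w):
            P = {n: model.transition_matrix(d[n] * cr)
                 for n in tree.branch_ids()}
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = dict(zip(internals.tolist(), assign))
                pr = pi[amap[tree.root]]
                for n in tree.branch_ids():
                    x = amap[n] if n >= tree.n_tips else tips[n]
                    if x < 0:
                        continue  # missing tip marginalizes out
                    pr *= P[n][amap[tree.parent[n]], x]
                acc += pr
            site += (1 - model.p_inv) * cw * acc
        total += np.log(site)
    return total


def test_two_sequence_jc_closed_form():
    """n_same * log(pi (1/4 + 3/4 e^{-4d/3})) + n_diff * log(pi (1/4 - 1/4 e^{-4d/3}))."""
    d = 0.4
    tree = TimeTree(["a", "b"], [2, 2, -1], [[-1, -1], [-1, -1], [0, 1]],
                    [0.0, 0.0, d / 2], np.array([1.0, 1.0, np.nan]))
    aln = Alignment.from_strings(["a", "b"], ["AAAACCGG", "AAAACCGT"])
    model = SubstitutionModel.jc()
    n_same, n_diff = 7, 1
    p_same = 0.25 * (0.25 + 0.75 * np.exp(-4 * d / 3))
    p_diff = 0.25 * (0.25 - 0.25 * np.exp(-4 * d / 3))
    expect = n_same * np.log(p_same) + n_diff * np.log(p_diff)
    assert pruning_loglik(tree, model, aln) == pytest.approx(expect, abs=1e-10)


@pytest.mark.parametrize("n_tips,seed", [(4, 3), (5, 7)])
def test_matches_exhaustive_enumeration(n_tips, seed):
    truth, aln = simulate_dataset(n_tips=n_tips, n_sites=30, ucld_stdev=0.3,
                                  seed=seed)
    got = pruning_loglik(truth.tree, truth.model, aln)
    want = brute_force_loglik(truth.tree, truth.model, aln)
    assert got == pytest.approx(want, abs=1e-8)


def test_reroot_invariance():
    """Reversibility: sliding the root along a branch (with equal rates on
    the two root-adjacent segments) leaves the likelihood unchanged."""
    model = SubstitutionModel.coi_like(gamma_shape=0.5, p_inv=0.1)
    truth, aln = simulate_dataset(n_tips=4, n_sites=60, seed=2)
    t1 = truth.tree
    # build an alternative rooting of the same unrooted 4-tip tree by
    # moving the root along its left child edge
    ll1 = pruning_loglik(t1, model, aln)
    t2 = t1.copy()
    t2.heights[t2.root] = t1.heights[t1.root] * 1.7  # root slides up
    c1, c2 = t2.children[t2.root]
    # compensate rates so expected substitutions on the two root edges
    # are unchanged (same rate on both segments)
    for c in (c1, c2):
        span_old = t1.heights[t1.root] - t1.heights[c]
        span_new = t2.heights[t2.root] - t2.heights[c]
        t2.rates[c] = t1.rates[c] * span_old / span_new
    # identical branch expected substitutions => identical likelihood
    assert pruning_loglik(t2, model, aln) == pytest.approx(ll1, abs=1e-9)


def test_missing_data_tolerated():
    truth, aln = simulate_dataset(n_tips=4, n_sites=30, seed=4)
    rows = list(aln.sequences().values())
    rows[0] = "-" * 10 + rows[0][10:20] + "N" * 10
    aln2 = Alignment.from_strings(aln.taxa, rows)
    ll = pruning_loglik(truth.tree, truth.model, aln2)
    assert np.isfinite(ll)


def test_taxon_mismatch_error():
    truth, aln = simulate_dataset(n_tips=4, n_sites=30, seed=4)
    bad = Alignment.from_strings(["x1", "x2", "x3", "x4"],
                                 list(aln.sequences().values()))
    with pytest.raises(InvalidArgumentError):
        LikelihoodEngine(bad, truth.tree)


def test_stateful_matches_stateless_after_edge_updates():
    """Dirty-path partial updates equal a from-scratch evaluation."""
    truth, aln = simulate_dataset(n_tips=10, n_sites=300, seed=6)
    tree = truth.tree
    model = SubstitutionModel.coi_like(gamma_shape=0.4, p_inv=0.15)
    eng = LikelihoodEngine(aln, tree)
    sl = StatefulLikelihood(eng, 4)
    eigen = model.eigensystem()
    cats = discrete_gamma_rates(0.4, 4)
    rng = np.random.default_rng(0)
    heights = tree.heights.copy()
    rates = np.where(np.isfinite(tree.rates), tree.rates, 1.0)
    d = eng.branch_lengths(heights, rates)
    sl.full_update(d, eigen, cats, model.freqs, model.p_inv)
    for step in range(30):
        e = int(rng.choice(tree.branch_ids()))
        old = rates[e]
        rates[e] *= float(np.exp(rng.normal(0, 0.3)))
        d = eng.branch_lengths(heights, rates)
        got = sl.propose_edges(np.asarray([e]), d, eigen, cats, model.freqs,
                               model.p_inv)
        want = eng.loglik(heights, rates, model)
        assert got == pytest.approx(want, abs=1e-8)
        if rng.random() < 0.5:
            sl.accept()
        else:
            rates[e] = old
            sl.reject()
            # cached state must still match the restored configuration
            back = sl._root(model.freqs, model.p_inv)
            assert back == pytest.approx(eng.loglik(heights, rates, model),
                                         abs=1e-8)


def test_discrete_gamma_rates_mean_one():
    for shape in (0.1, 0.5, 1.0, 5.0):
        rates = discrete_gamma_rates(shape, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(rates) > 0)


def test_transition_matrix_rows_are_distributions():
    model = SubstitutionModel.coi_like()
    P = model.transition_matrix(0.7)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(P >= 0)
    # stationarity: pi P = pi
    assert np.allclose(model.freqs @ P, model.freqs, atol=1e-10)
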