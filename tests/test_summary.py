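import numpy as np
import pandas as pd
import pytest

from ratecon.errors import InvalidArgumentError, InvalidCladeError
from ratecon.mcmc import MCMCConfig, SCALAR_COLUMNS, Trace
from ratecon.summary import (clade_mean_rate, clade_support, hpd_interval,
                             mcc_tree, rate_constancy_report)
from ratecon.synthetic import simulate_dataset, simulate_yule_tree
from ratecon.trees import TimeTree


def brute_force_hpd(x, prob):
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    k = int(np.ceil(prob * n))
    best = None
    for i in range(n - k + 1):
        w = x[i + k - 1] - x[i]
        if best is None or w < best[0]:
            best = (w, x[i], x[i + k - 1])
    return best[1], best[2]


class TestHPD:
    def test_matches_exhaustive_window_search(self):
        rng = np.random.default_rng(3)
        for n in (20, 57, 200, 500):
            x = rng.gamma(2.0, 1.0, size=n)
            assert hpd_interval(x, 0.95) == brute_force_hpd(x, 0.95)
            assert hpd_interval(x, 0.5) == brute_force_hpd(x, 0.5)

    def test_constant_samples(self):
        assert hpd_interval(np.full(50, 3.3)) == (3.3, 3.3)

    def test_standard_normal(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_contains_enough_samples(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=301)
        lo, hi = hpd_interval(x, 0.9)
        inside = np.sum((x >= lo) & (x <= hi))
        assert inside >= int(np.ceil(0.9 * x.size))

    def test_invalid_prob(self):
        with pytest.raises(InvalidArgumentError):
            hpd_interval(np.arange(30.0), prob=1.2)


class TestCladeMeanRate:
    def test_uniform_rates(self):
        tree = simulate_yule_tree(10, 2.0, seed=1)
        rates = np.full(tree.n_nodes, 1.7)
        rates[tree.root] = np.nan
        tree.rates = rates
        clade = tree.named_clades_of_size(3, 6)
        tips = next(iter(clade.values()))
        assert clade_mean_rate(tree, tips) == pytest.approx(1.7)

    def test_time_weighting(self):
        # two crown branches with spans (3, 1) and rates (1, 3) -> 1.5
        tree = TimeTree.from_newick("((A:3,B:1):1,C:4);")
        # B's branch spans 1 only if its height is 2: build explicitly
        tree = TimeTree(["A", "B", "C"],
                        parent=[3, 3, 4, 4, -1],
                        children=[[-1, -1], [-1, -1], [-1, -1], [0, 1], [3, 2]],
                        heights=[0.0, 2.0, 0.0, 3.0, 4.0],
                        rates=np.array([1.0, 3.0, 1.0, 1.0, np.nan]))
        got = clade_mean_rate(tree, ["A", "B"])
        assert got == pytest.approx((1 * 3 + 3 * 1) / 4)

    def test_invariant_to_time_rescaling(self):
        tree = simulate_yule_tree(8, 2.0, seed=2)
        rng = np.random.default_rng(0)
        rates = rng.lognormal(0, 0.5, tree.n_nodes)
        rates[tree.root] = np.nan
        tree.rates = rates
        tips = next(iter(tree.named_clades_of_size(3, 5).values()))
        r1 = clade_mean_rate(tree, tips)
        tree2 = tree.copy()
        tree2.heights *= 7.3
        assert clade_mean_rate(tree2, tips) == pytest.approx(r1)


def _toy_trace(rate_by_clade, n_samples=200, seed=0):
    """Trace over a fixed 8-tip tree with noisy per-clade rates."""
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(8, 4.0, seed=3)
    tree.clades = tree.named_clades_of_size(2, 4)
    heights = np.tile(tree.heights, (n_samples, 1))
    rates = np.ones((n_samples, tree.n_nodes))
    for name, mult in rate_by_clade.items():
        edges = tree.clade_edges(tree.clades[name])
        rates[:, edges] = mult * np.exp(rng.normal(0, 0.05,
                                                   (n_samples, edges.size)))
    other = np.setdiff1d(tree.branch_ids(),
                         np.concatenate([tree.clade_edges(tree.clades[n])
                                         for n in rate_by_clade])
                         if rate_by_clade else tree.branch_ids())
    rates[:, other] *= np.exp(rng.normal(0, 0.05, (n_samples, other.size)))
    rates[:, tree.root] = np.nan
    scal = pd.DataFrame(rng.normal(size=(n_samples, len(SCALAR_COLUMNS))),
                        columns=SCALAR_COLUMNS)
    scal["state"] = np.arange(n_samples)
    cfg = MCMCConfig(generations=n_samples - 1, sample_every=1,
                     burnin_fraction=0.0)
    return tree, Trace(tree, scal, heights, rates, cfg)


class TestRateConstancyReport:
    def test_deviant_clade_flagged(self):
        tree, trace = _toy_trace({"c0": 3.0})
        names = sorted(tree.clades)
        focal = next(n for n in names
                     if not (tree.clades[n] & tree.clades["c0"]))
        rep = rate_constancy_report(trace, tree.clades, focal=focal)
        s = rep.summary("c0")
        assert s.deviates_from_mean and s.differs_from_focal
        assert not rep.summary(focal).deviates_from_mean
        assert not rep.summary(focal).differs_from_focal  # vs itself
        assert "NOT" not in rep.calibration_advice

    def test_flags_monotone_in_probability(self):
        # widening the HPD can only turn flags off
        tree, trace = _toy_trace({"c0": 1.3})
        names = sorted(tree.clades)
        focal = next(n for n in names
                     if not (tree.clades[n] & tree.clades["c0"]))
        flags = []
        for prob in (0.5, 0.8, 0.95, 0.99):
            rep = rate_constancy_report(trace, tree.clades, focal=focal,
                                        prob=prob)
            s = rep.summary("c0")
            flags.append((s.deviates_from_mean, s.differs_from_focal))
        for a, b in zip(flags, flags[1:]):
            assert a[0] >= b[0] and a[1] >= b[1]

    def test_unknown_focal(self):
        tree, trace = _toy_trace({})
        with pytest.raises(InvalidArgumentError):
            rate_constancy_report(trace, tree.clades, focal="nope")

    def test_non_monophyletic_clade(self):
        tree, trace = _toy_trace({})
        bad = dict(tree.clades)
        labels = tree.labels
        bad["weird"] = frozenset([labels[0], labels[-1], labels[3]])
        if tree.is_monophyletic(bad["weird"]):
            pytest.skip("random tip set happened to be monophyletic")
        with pytest.raises(InvalidCladeError):
            rate_constancy_report(trace, bad, focal="weird")


class TestMCCTree:
    def test_fixed_topology_recovered(self):
        truth, _ = simulate_dataset(n_tips=8, n_sites=9, seed=5)
        base = truth.tree
        samples = []
        rng = np.random.default_rng(2)
        for _ in range(25):
            t = base.copy()
            t.heights = base.heights * rng.uniform(0.8, 1.2)
            t.rates = base.rates * rng.uniform(0.9, 1.1)
            samples.append(t)
        mcc = mcc_tree(samples)
        assert mcc.newick().split(":")[0].count("(") == \
            base.newick().split(":")[0].count("(")
        support = clade_support(samples, mcc)
        assert all(v == 1.0 for v in support.values())

    def test_median_heights(self):
        truth, _ = simulate_dataset(n_tips=6, n_sites=9, seed=6)
        base = truth.tree
        factors = [0.5, 0.9, 1.0, 1.1, 2.0]
        samples = []
        for f in factors:
            t = base.copy()
            t.heights = base.heights * f
            samples.append(t)
        mcc = mcc_tree(samples)
        want = base.heights * np.median(factors)
        assert np.allclose(mcc.heights, want)

    def test_empty_samples(self):
        with pytest.raises(InvalidArgumentError):
            mcc_tree([])
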