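import numpy as np
import pytest

from ratecon.errors import (InvalidArgumentError, InvalidCladeError,
                            InvalidStateError)
from ratecon.models import SubstitutionModel
from ratecon.synthetic import (SimTruth, assign_branch_rates,
                               normalize_partition_multipliers,
                               simulate_alignment, simulate_dataset,
                               simulate_yule_tree, study_replicate)
from ratecon.trees import TimeTree


class TestYuleTree:
    def test_two_tip_root_height_is_exponential(self):
        # Monte-Carlo mean of the root height ~ 1/birth_rate
        lam = 4.0
        heights = [simulate_yule_tree(2, lam, s).heights[2]
                   for s in range(10_000)]
        assert np.mean(heights) == pytest.approx(1.0 / lam, rel=0.05)

    def test_binary_tree_counts(self):
        tree = simulate_yule_tree(8, 1.0, seed=5)
        assert tree.n_tips == 8
        assert tree.postorder_internal().size == 7
        assert tree.branch_ids().size == 14

    def test_deterministic_under_seed(self):
        a = simulate_yule_tree(9, 2.0, seed=11).newick()
        b = simulate_yule_tree(9, 2.0, seed=11).newick()
        assert a == b

    def test_heights_are_valid(self):
        tree = simulate_yule_tree(20, 3.0, seed=1)
        assert tree.validate_heights()
        assert tree.is_ultrametric()

    def test_too_few_tips(self):
        with pytest.raises(InvalidArgumentError):
            simulate_yule_tree(1, 1.0, 0)


class TestBranchRates:
    def test_strict_clock(self):
        tree = simulate_yule_tree(8, 2.0, seed=3)
        out = assign_branch_rates(tree, 0.0, seed=1)
        assert np.allclose(out.rates[out.branch_ids()], 1.0)

    def test_clade_multiplier_crown_only(self):
        tree = simulate_yule_tree(12, 2.0, seed=7)
        clades = tree.named_clades_of_size(3, 6)
        name, tips = next(iter(clades.items()))
        out = assign_branch_rates(tree, 0.0, {name: 3.0}, seed=1,
                                  clades=clades)
        crown = out.clade_edges(tips)
        stem = out.mrca(tips)
        others = np.setdiff1d(out.branch_ids(), crown)
        assert np.allclose(out.rates[crown], 3.0)
        assert np.allclose(out.rates[others], 1.0)
        assert out.rates[stem] == pytest.approx(1.0)  # stem not multiplied

    def test_lognormal_mean_one(self):
        # E[exp(N(-s^2/2, s^2))] = 1
        tree = simulate_yule_tree(2, 1.0, seed=0)
        rates = []
        for s in range(5000):
            out = assign_branch_rates(tree, 0.5, seed=s)
            rates.extend(out.rates[out.branch_ids()])
        assert np.mean(rates) == pytest.approx(1.0, abs=0.02)

    def test_unknown_clade(self):
        tree = simulate_yule_tree(8, 2.0, seed=3)
        with pytest.raises(InvalidCladeError):
            assign_branch_rates(tree, 0.1, {"nope": 2.0}, seed=0)


class TestAlignmentSimulation:
    def test_zero_length_tree_identical_sequences(self):
        tree = TimeTree.from_newick("((A:0,B:0):0,C:0);")
        rates = np.ones(tree.n_nodes)
        rates[tree.root] = np.nan
        tree.rates = rates
        aln = simulate_alignment(tree, SubstitutionModel.jc(), 300, seed=2)
        rows = list(aln.sequences().values())
        assert rows[0] == rows[1] == rows[2]

    def test_jc_expected_p_distance(self, jc_model):
        # d = 0.3043 corresponds to p = 0.25 under Jukes-Cantor
        from ratecon.saturation import p_distance
        d = 0.30435
        tree = TimeTree(["a", "b"], [2, 2, -1], [[-1, -1], [-1, -1], [0, 1]],
                        [0.0, 0.0, d / 2], np.array([1.0, 1.0, np.nan]))
        aln = simulate_alignment(tree, jc_model, 99_999, seed=5)
        p = p_distance(aln.codes[0], aln.codes[1])
        assert p == pytest.approx(0.25, abs=0.01)

    def test_all_invariant_when_p_inv_one(self):
        truth, _ = simulate_dataset(n_tips=6, n_sites=9, seed=0)
        model = SubstitutionModel.jc(p_inv=1.0)
        aln = simulate_alignment(truth.tree, model, 300, seed=3)
        assert not aln.variable_site_mask().any()

    def test_stationary_frequencies_chi2(self):
        # one sequence's sites are i.i.d. from the stationary distribution
        from scipy.stats import chisquare
        model = SubstitutionModel.coi_like()
        truth, _ = simulate_dataset(n_tips=8, n_sites=9, seed=1)
        aln = simulate_alignment(truth.tree, model, 30_000, seed=4)
        row = aln.base_indices()[0]
        counts = np.bincount(row[row >= 0], minlength=4)
        _, p = chisquare(counts, counts.sum() * model.freqs)
        assert p > 1e-3

    def test_requires_rates(self):
        tree = simulate_yule_tree(4, 1.0, seed=0)
        with pytest.raises(InvalidStateError):
            simulate_alignment(tree, SubstitutionModel.jc(), 30, seed=0)

    def test_sites_multiple_of_three(self):
        truth, _ = simulate_dataset(n_tips=4, n_sites=9, seed=0)
        with pytest.raises(InvalidArgumentError):
            simulate_alignment(truth.tree, SubstitutionModel.jc(), 100, seed=0)


def test_strict_clock_distances_recover_path_lengths():
    """ML pairwise distances track patristic rate x time path lengths."""
    from ratecon.saturation import gtr_distance
    model = SubstitutionModel.jc()
    truth, _ = simulate_dataset(n_tips=6, n_sites=9, seed=9, birth_rate=2.0)
    tree = truth.tree
    aln = __import__("ratecon.synthetic", fromlist=["simulate_alignment"]) \
        .simulate_alignment(tree, model, 30_000, seed=10)
    # patristic distance between first two tips in the tree
    a, b = 0, 1
    m = tree.mrca([tree.labels[a], tree.labels[b]])
    expect = 2 * tree.heights[m]
    got = gtr_distance(aln.codes[a], aln.codes[b], model)
    assert got == pytest.approx(expect, rel=0.05)


def test_partition_multiplier_normalization():
    m = normalize_partition_multipliers((1.0, 1.0, 4.0))
    assert m.mean() == pytest.approx(1.0)
    with pytest.raises(InvalidArgumentError):
        normalize_partition_multipliers((1.0, -1.0, 1.0))


def test_truth_round_trip(tmp_path):
    truth, _ = simulate_dataset(n_tips=10, n_sites=30, ucld_stdev=0.4,
                                clade_multipliers=None, seed=13)
    path = tmp_path / "truth.txt"
    truth.to_file(path)
    back = SimTruth.from_file(path)
    assert back.seed == truth.seed
    assert back.ucld_stdev == truth.ucld_stdev
    assert np.array_equal(back.partition_multipliers,
                          truth.partition_multipliers)
    assert np.array_equal(back.model.exchangeabilities,
                          truth.model.exchangeabilities)
    assert back.tree.newick(include_rates=True) == \
        truth.tree.newick(include_rates=True)
    assert back.tree.clades == truth.tree.clades


def test_study_replicate_returns_disjoint_deep_clades():
    truth, aln, dev, focal = study_replicate(123, n_sites=30, multiplier=3.0)
    tree = truth.tree
    assert not (tree.clades[dev] & tree.clades[focal])
    crown = tree.clade_edges(tree.clades[dev])
    assert np.allclose(tree.rates[crown], 3.0)
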