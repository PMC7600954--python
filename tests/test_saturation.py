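import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratecon.alignment import Alignment
from ratecon.errors import (DegenerateModelError, InvalidArgumentError,
                            UndefinedDistanceError)
from ratecon.models import SubstitutionModel
from ratecon.saturation import (estimate_gtr, expected_saturation_entropy,
                                gtr_distance, iss, iss_jackknife,
                                iss_sites_used, p_distance,
                                regression_through_origin,
                                saturation_regression, site_entropy)
from ratecon.synthetic import simulate_alignment, simulate_dataset


class TestPDistance:
    @pytest.mark.parametrize("a,b,want", [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("AC-T", "ACGA", 1 / 3),          # pairwise deletion
        ("ACNT", "ACGA", 1 / 3),          # ambiguity treated as missing
    ])
    def test_examples(self, a, b, want):
        assert p_distance(a, b) == pytest.approx(want)

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("----", "ACGT")

    @given(st.text(alphabet="ACGT-N", min_size=4, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetric_and_zero_on_self(self, s):
        t = s[::-1]
        try:
            d1 = p_distance(s, t)
            d2 = p_distance(t, s)
        except UndefinedDistanceError:
            return
        assert d1 == d2
        if any(c in "ACGT" for c in s):
            assert p_distance(s, s) == 0.0


class TestGTRDistance:
    def test_identical(self, jc_model):
        assert gtr_distance("ACGTACGT", "ACGTACGT", jc_model) == 0.0

    def test_jc_closed_form_grid(self, jc_model):
        # JC special case: d = -(3/4) ln(1 - 4p/3)
        for p in np.arange(0.05, 0.71, 0.05):
            n = 10_000
            k = int(round(p * n))
            a = "A" * n
            b = "C" * k + "A" * (n - k)
            want = -0.75 * np.log(1 - 4 * (k / n) / 3)
            got = gtr_distance(a, b, jc_model)
            assert got == pytest.approx(want, abs=1e-6)

    def test_monotone_in_p_distance(self, jc_model):
        n = 3000
        ds = []
        for k in (100, 400, 900, 1500):
            a = "A" * n
            b = "G" * k + "A" * (n - k)
            ds.append(gtr_distance(a, b, jc_model))
        assert all(x < y for x, y in zip(ds, ds[1:]))

    def test_saturated_pair_capped(self, jc_model):
        # ~75% differences saturate the JC correction
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 4000))
        b = "".join(rng.choice(list("ACGT"), 4000))
        with pytest.warns(UserWarning):
            d = gtr_distance(a, b, jc_model, max_distance=8.0)
        assert d == 8.0


class TestEstimateGTR:
    def test_recovers_exchangeabilities(self):
        model = SubstitutionModel.coi_like()
        truth, _ = simulate_dataset(n_tips=8, n_sites=9, seed=121,
                                    birth_rate=8.0)
        aln = simulate_alignment(truth.tree, model, 30_000, seed=122)
        est = estimate_gtr(aln)
        ratio = est.exchangeabilities / model.exchangeabilities
        assert np.all(np.abs(ratio - 1) < 0.10)

    def test_jc_data_gives_flat_exchangeabilities(self):
        truth, _ = simulate_dataset(n_tips=8, n_sites=9, seed=23)
        aln = simulate_alignment(truth.tree, SubstitutionModel.jc(), 30_000,
                                 seed=24)
        est = estimate_gtr(aln)
        assert np.all(np.abs(est.exchangeabilities - 1) < 0.15)

    def test_invariant_alignment_rejected(self):
        aln = Alignment.from_strings(["a", "b", "c"],
                                     ["ACGTAC", "ACGTAC", "ACGTAC"])
        with pytest.raises(DegenerateModelError):
            estimate_gtr(aln)


class TestRegressionThroughOrigin:
    def test_exact_line(self):
        slope, r2 = regression_through_origin([1, 2, 3], [2, 4, 6])
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # slope = sum(xy)/sum(x^2) = 17/14; R2 = 1 - RSS/sum(y^2)
        slope, r2 = regression_through_origin([1, 2, 3], [1, 2, 4])
        assert slope == pytest.approx(17 / 14, abs=1e-12)
        resid = np.array([1, 2, 4]) - 17 / 14 * np.array([1, 2, 3])
        want_r2 = 1 - (resid @ resid) / 21
        assert r2 == pytest.approx(want_r2, abs=1e-12)
        assert r2 == pytest.approx(0.9830, abs=5e-4)

    def test_invariant_to_common_rescaling(self):
        x = np.array([0.3, 0.8, 1.9, 2.2])
        y = np.array([0.2, 0.9, 1.5, 2.5])
        s1, r1 = regression_through_origin(x, y)
        s2, r2 = regression_through_origin(3.7 * x, 3.7 * y)
        assert s2 == pytest.approx(s1)
        assert r2 == pytest.approx(r1)

    def test_all_zero_x_rejected(self):
        with pytest.raises(InvalidArgumentError):
            regression_through_origin([0, 0, 0], [1, 2, 3])


class TestSaturationRegression:
    def test_unsaturated_all_partitions_linear(self):
        truth, aln = simulate_dataset(n_tips=10, n_sites=1200, seed=31,
                                      birth_rate=20.0,
                                      partition_multipliers=(1, 1, 1))
        rep = saturation_regression(aln)
        for r in rep.regressions:
            assert r.r2 > 0.99
        assert rep.include_codon3

    def test_codon3_saturation_detected(self):
        # deep tree + 10x faster codon 3 saturates that partition only;
        # homogeneous site rates so the plateau is attributable to
        # multiple hits rather than frozen sites
        truth, aln = simulate_dataset(
            n_tips=12, n_sites=1500, seed=32, birth_rate=2.0,
            partition_multipliers=(0.25, 0.25, 2.5),
            model=SubstitutionModel.coi_like(gamma_shape=None, p_inv=0.0))
        rep = saturation_regression(aln)
        assert rep.r2("3") < rep.r2("12") - 0.10
        assert rep.r2("12") > 0.9


class TestTwoTaxonRegression:
    def test_single_pair_is_flagged_low_information(self, jc_model):
        import warnings as _w
        aln = Alignment.from_strings(["a", "b"],
                                     ["ACGTACGTAC", "ACGTACGAAC"])
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            rep = saturation_regression(aln, model=jc_model)
        assert all(r.low_information for r in rep.regressions)
        informative = [r for r in rep.regressions if np.isfinite(r.r2)]
        assert informative and all(r.r2 == 1.0 for r in informative)


class TestEntropyAndIss:
    @pytest.mark.parametrize("counts,want", [
        ((5, 0, 0, 0), 0.0),
        ((2, 2, 2, 2), 2.0),
        ((2, 1, 1, 0), 1.5),
    ])
    def test_site_entropy(self, counts, want):
        assert site_entropy(counts) == pytest.approx(want)

    def test_empty_column_rejected(self):
        with pytest.raises(InvalidArgumentError):
            site_entropy((0, 0, 0, 0))

    def test_invariant_alignment_iss_zero(self):
        aln = Alignment.from_strings(["a", "b", "c", "d"],
                                     ["ACGTAC"] * 4)
        assert iss(aln, p_inv=0.0) == 0.0

    def test_random_alignment_iss_near_one(self):
        # columns of 4 i.i.d. uniform bases: mean entropy equals the
        # full-saturation expectation, so Iss ~ 1
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT"), 10_000)) for _ in range(4)]
        aln = Alignment.from_strings(list("abcd"), rows)
        assert iss(aln, p_inv=0.0) == pytest.approx(1.0, abs=0.02)

    def test_expected_entropy_monte_carlo(self):
        # exact enumeration vs Monte-Carlo for multinomial(6, skewed)
        p = np.array([0.4, 0.3, 0.2, 0.1])
        rng = np.random.default_rng(7)
        draws = rng.multinomial(6, p, size=40_000)
        hs = []
        for c in draws:
            f = c[c > 0] / 6
            hs.append(-(f * np.log2(f)).sum())
        assert expected_saturation_entropy(6, p) == pytest.approx(
            np.mean(hs), abs=0.01)

    def test_sites_used_df_rule(self):
        # the df bookkeeping reproduces round((1-p_inv) * n_sites) - 1
        assert iss_sites_used(1491, 0.21) - 1 == 1177


class TestIssCritical:
    def test_asym_below_sym_and_decreasing(self):
        """Caterpillar topologies lose recoverability earlier than
        balanced ones, and larger subsets tolerate less saturation."""
        from ratecon.saturation import iss_critical
        freqs = np.full(4, 0.25)
        crits = {}
        for k in (8, 16):
            crits[k, "sym"] = iss_critical(k, 600, freqs, "sym", seed=5,
                                           replicates=10)
            crits[k, "asym"] = iss_critical(k, 600, freqs, "asym", seed=6,
                                            replicates=10)
        assert crits[8, "asym"] <= crits[8, "sym"]
        assert crits[16, "asym"] <= crits[16, "sym"]
        assert crits[16, "asym"] <= crits[8, "asym"]

    def test_shallow_simulations_recover(self):
        """Benign (shallow) data sits well below the critical index."""
        from ratecon.saturation import iss, iss_critical
        truth, aln = simulate_dataset(n_tips=8, n_sites=600, seed=71,
                                      birth_rate=20.0,
                                      partition_multipliers=(1, 1, 1))
        c = iss_critical(8, 600, aln.base_frequencies(), "sym", seed=7,
                         replicates=10)
        observed = iss(aln, p_inv=aln.proportion_invariant())
        assert observed < c


class TestIssJackknife:
    def test_identical_sequences(self):
        aln = Alignment.from_strings([f"t{i}" for i in range(8)],
                                     ["ACGTAC"] * 8)
        mean, se = iss_jackknife(aln, 4, 20, 0.0, seed=1)
        assert mean == 0.0 and se == 0.0

    def test_deterministic_under_seed(self):
        truth, aln = simulate_dataset(n_tips=10, n_sites=300, seed=41)
        a = iss_jackknife(aln, 4, 30, 0.1, seed=9)
        b = iss_jackknife(aln, 4, 30, 0.1, seed=9)
        assert a == b

    def test_matches_exhaustive_subsets(self):
        truth, aln = simulate_dataset(n_tips=8, n_sites=300, seed=43)
        mean, se = iss_jackknife(aln, 4, 100, 0.0, seed=11)
        exact = np.mean([
            iss(aln.subset_taxa([aln.taxa[i] for i in combo]), 0.0)
            for combo in itertools.combinations(range(8), 4)])
        assert abs(mean - exact) < 3 * max(se, 1e-9)

    def test_num_otu_too_large(self):
        truth, aln = simulate_dataset(n_tips=6, n_sites=30, seed=44)
        with pytest.raises(InvalidArgumentError):
            iss_jackknife(aln, 7, 10, 0.0, seed=0)
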