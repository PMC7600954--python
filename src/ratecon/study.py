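"""Desk-scale validation studies.

Every stage of the pipeline is checked by simulation at sizes a single
CPU handles in minutes: oracle equivalences against closed forms and
exhaustive enumeration, prior recovery of the likelihood-off sampler,
parameter recovery (HPD coverage under a strict clock; detection of a
3x-rate clade), and the behavior of the saturation screen on benign and
deliberately saturated data.  The same functions drive the validation
tests and the reproduction script, so the numbers they print are always
recomputed from scratch.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .likelihood import LikelihoodEngine, pruning_loglik
from .mcmc import MCMCConfig, mcmc_run
from .models import SubstitutionModel
from .priors import lognormal_mean1_draws
from .saturation import gtr_distance, iss_test, saturation_regression
from .summary import hpd_interval, rate_constancy_report
from .synthetic import simulate_dataset, study_replicate

# default desk-scale study conditions (see docs/methods.md)
COVERAGE_REPLICATES = 20
FLAGGING_REPLICATES = 20
STUDY_N_TIPS = 16
STUDY_N_SITES = 1500
COVERAGE_GENERATIONS = 30_000
FLAGGING_GENERATIONS = 60_000
SAMPLE_EVERY = 60


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


# -- oracle equivalence ---------------------------------------

def brute_force_loglik(tree, model, aln) -> float:
    """Likelihood by exhaustive enumeration of internal states."""
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
                        continue
                    pr *= P[n][amap[tree.parent[n]], x]
                acc += pr
            site += (1 - model.p_inv) * cw * acc
        total += np.log(site)
    return total


def brute_force_hpd(samples, prob: float) -> tuple[float, float]:
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    k = int(np.ceil(prob * n))
    best = None
    for i in range(n - k + 1):
        w = x[i + k - 1] - x[i]
        if best is None or w < best[0]:
            best = (w, x[i], x[i + k - 1])
    return best[1], best[2]


def oracle_checks(seed: int) -> dict[str, float]:
    """Max deviations of the fast implementations from independent oracles."""
    rng = np.random.default_rng(seed)
    # pruning vs enumeration on 4- and 5-taxon trees
    lik_err = 0.0
    for n_tips, s in ((4, _sub_seed(seed, 1)), (5, _sub_seed(seed, 2))):
        truth, aln = simulate_dataset(n_tips=n_tips, n_sites=30,
                                      ucld_stdev=0.3, seed=s)
        got = pruning_loglik(truth.tree, truth.model, aln)
        want = brute_force_loglik(truth.tree, truth.model, aln)
        lik_err = max(lik_err, abs(got - want))
    # GTR distance vs Jukes-Cantor closed form
    jc = SubstitutionModel.jc()
    dist_err = 0.0
    for p in np.arange(0.05, 0.71, 0.05):
        n = 10_000
        k = int(round(p * n))
        a = "A" * n
        b = "C" * k + "A" * (n - k)
        want = -0.75 * np.log(1 - 4 * (k / n) / 3)
        dist_err = max(dist_err, abs(gtr_distance(a, b, jc) - want))
    # HPD vs exhaustive window search
    hpd_err = 0.0
    for n in (50, 200, 500):
        x = rng.gamma(2.0, 1.0, size=n)
        got = hpd_interval(x, 0.95)
        want = brute_force_hpd(x, 0.95)
        hpd_err = max(hpd_err, abs(got[0] - want[0]), abs(got[1] - want[1]))
    return {"pruning_vs_enumeration_max_abs_err": lik_err,
            "gtr_vs_jc_closed_form_max_abs_err": dist_err,
            "hpd_vs_bruteforce_max_abs_err": hpd_err}


# -- prior recovery -------------------------------------------

def prior_recovery(seed: int, generations: int = 600_000,
                   thin: int = 120) -> dict[str, float]:
    """Likelihood-off chain vs direct Monte-Carlo draws from the priors.

    Returns two-sample Kolmogorov-Smirnov p-values for the clock
    standard deviation and for one branch rate (whose prior marginal is
    the sigma-mixture of mean-1 lognormals).
    """
    truth, _ = simulate_dataset(n_tips=STUDY_N_TIPS, n_sites=3,
                                seed=_sub_seed(seed, 3))
    cfg = MCMCConfig(generations=generations, sample_every=thin,
                     seed=_sub_seed(seed, 4), likelihood_on=False)
    trace = mcmc_run(None, truth.tree, cfg).burned(0.2)
    rng = np.random.default_rng(_sub_seed(seed, 5))
    n_direct = 50_000
    sig_direct = rng.exponential(cfg.ucld_prior_mean, size=n_direct)
    rate_direct = np.array([
        lognormal_mean1_draws(s, 1, rng)[0] for s in sig_direct[:20_000]])
    sig_chain = trace.scalars["ucld_stdev"].to_numpy()
    branch = int(trace.topology.branch_ids()[0])
    rate_chain = trace.rates[:, branch]
    return {
        "prior_recovery_ucld_ks_pvalue": float(
            ks_2samp(sig_chain, sig_direct).pvalue),
        "prior_recovery_rate_ks_pvalue": float(
            ks_2samp(rate_chain, rate_direct).pvalue),
        "prior_recovery_rate_mean": float(rate_chain.mean()),
        "n_chain_samples": trace.n_samples,
    }


# -- parameter recovery ---------------------------------------

@dataclass
class RecoveryResult:
    hpds_total: int
    hpds_containing_one: int
    flagged: int
    replicates: int
    hpd_excludes_one: int = 0

    @property
    def coverage(self) -> float:
        return self.hpds_containing_one / self.hpds_total


def strict_clock_coverage(seed: int, replicates: int = COVERAGE_REPLICATES,
                          n_sites: int = STUDY_N_SITES,
                          generations: int = COVERAGE_GENERATIONS
                          ) -> RecoveryResult:
    """Fraction of clade-rate 95% HPDs containing 1 under a strict clock."""
    total = hit = 0
    for rep in range(replicates):
        s = _sub_seed(seed, 100 + rep)
        truth, aln = simulate_dataset(n_tips=STUDY_N_TIPS, n_sites=n_sites,
                                      ucld_stdev=0.0, seed=s)
        tree = truth.tree
        cfg = MCMCConfig(generations=generations, sample_every=SAMPLE_EVERY,
                         seed=s)
        trace = mcmc_run(aln, tree, cfg).burned()
        focal = sorted(tree.clades)[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = rate_constancy_report(trace, tree.clades, focal=focal)
        for summ in report.summaries:
            total += 1
            hit += int(summ.hpd_low <= 1.0 <= summ.hpd_high)
    return RecoveryResult(total, hit, 0, replicates)


def deviant_clade_flagging(seed: int, replicates: int = FLAGGING_REPLICATES,
                           n_sites: int = STUDY_N_SITES,
                           generations: int = FLAGGING_GENERATIONS,
                           multiplier: float = 3.0) -> RecoveryResult:
    """How often a 3x-rate clade is flagged (HPD excludes 1 AND is
    disjoint from a neutral focal clade's HPD) across replicates."""
    flagged = excludes = 0
    for rep in range(replicates):
        s = _sub_seed(seed, 200 + rep)
        truth, aln, deviant, focal = study_replicate(
            s, n_tips=STUDY_N_TIPS, n_sites=n_sites, multiplier=multiplier)
        cfg = MCMCConfig(generations=generations, sample_every=SAMPLE_EVERY,
                         seed=s)
        trace = mcmc_run(aln, truth.tree, cfg).burned()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = rate_constancy_report(trace, truth.tree.clades,
                                           focal=focal)
        summ = report.summary(deviant)
        excludes += int(summ.deviates_from_mean)
        flagged += int(summ.deviates_from_mean and summ.differs_from_focal)
    return RecoveryResult(0, 0, flagged, replicates,
                          hpd_excludes_one=excludes)


# -- saturation gate ------------------------------------------

def saturation_study(seed: int) -> dict[str, float]:
    """R^2 behavior on benign vs codon-3-saturated data, plus the Iss
    verdict on the benign alignment."""
    out: dict[str, float] = {}
    # benign: shallow tree, homogeneous codon rates
    truth, aln = simulate_dataset(n_tips=10, n_sites=1200,
                                  seed=_sub_seed(seed, 6), birth_rate=20.0,
                                  partition_multipliers=(1, 1, 1))
    rep = saturation_regression(aln)
    out["r2_min_unsaturated"] = min(r.r2 for r in rep.regressions)
    out["codon3_included_unsaturated"] = float(rep.include_codon3)
    # saturated: deep tree, codon 3 ten times faster than codons 1-2,
    # homogeneous site rates so multiple hits drive the plateau
    truth2, aln2 = simulate_dataset(
        n_tips=12, n_sites=1500, seed=_sub_seed(seed, 7), birth_rate=2.0,
        partition_multipliers=(0.25, 0.25, 2.5),
        model=SubstitutionModel.coi_like(gamma_shape=None, p_inv=0.0))
    rep2 = saturation_regression(aln2)
    out["r2_codon3_saturated"] = rep2.r2("3")
    out["r2_codons12_saturated"] = rep2.r2("12")
    # Iss battery on a benign 17-taxon alignment (NumOTU 4, 8, 16; the
    # 32-OTU caterpillar needs more sites than desk scale to define a
    # 95%-reliability critical value)
    truth3, aln3 = simulate_dataset(n_tips=17, n_sites=900,
                                    seed=_sub_seed(seed, 8), birth_rate=20.0,
                                    partition_multipliers=(1, 1, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = iss_test(aln3, p_inv=aln3.proportion_invariant(),
                           seed=_sub_seed(seed, 9), replicates=60,
                           critical_kwargs={"replicates": 12})
    out["iss_max_p_unsaturated"] = max(max(r.p_sym, r.p_asym)
                                       for r in results)
    out["iss_below_critical_all"] = float(all(
        r.iss_mean < r.iss_c_sym and r.iss_mean < r.iss_c_asym
        for r in results))
    return out


# -- Iss arithmetic -------------------------------------------

def iss_arithmetic(seed: int) -> dict[str, float]:
    from .alignment import Alignment
    from .saturation import iss, iss_sites_used

    out: dict[str, float] = {}
    out["iss_df_1491_sites_pinv_021"] = iss_sites_used(1491, 0.21) - 1
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), 300))
    invariant = Alignment.from_strings([f"t{i}" for i in range(6)], [base] * 6)
    out["iss_invariant_alignment"] = iss(invariant, p_inv=0.0)
    rows = ["".join(rng.choice(list("ACGT"), 10_000)) for _ in range(4)]
    randomized = Alignment.from_strings(list("abcd"), rows)
    out["iss_randomized_columns"] = iss(randomized, p_inv=0.0)
    return out
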