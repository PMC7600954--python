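# Methods

## The question

Secondary ("universal") molecular-clock calibrations transfer a
substitution rate estimated in one taxon (for insects, typically a COI
rate of a few percent divergence per million years) to another taxon
that lacks fossils or biogeographic calibrations.  The transfer is only
defensible if the focal group's rate matches the calibration rate —
rate constancy.  `ratecon` tests that assumption without any absolute
timing information by estimating *relative* branch rates: a Bayesian
relaxed-clock analysis on a fixed topology in which the tree-wide mean
rate is anchored to 1, so each clade's posterior rate is a
dimensionless multiple of the average and "deviates from the
calibration regime" reduces to "95% HPD excludes 1".

## Pipeline

1. **Saturation screen.**  Protein-coding mitochondrial alignments
   spanning deep divergences risk substitution saturation, especially
   at codon position 3.  Two diagnostics decide whether position 3 is
   usable:
   * *Distance linearity.*  Uncorrected p-distances are regressed
     through the origin on GTR model-corrected maximum-likelihood
     pairwise distances, separately for codon partitions {1}, {2}, {3},
     {1,2}, {1,2,3}.  The uncentered R² (1 − Σ(y−bx)²/Σy², b = Σxy/Σx²)
     is the statistic; saturation makes uncorrected distances plateau
     and drags R² down.  Codon 3 is kept iff R²(1,2,3) ≥ R²(1,2) − t
     with t = 0.01 by default (configurable; the underlying empirical
     criterion is qualitative).
   * *Entropy index (Iss).*  For random taxon subsets of size 4, 8, 16,
     32 (100 jackknife replicates each), the mean per-site entropy of
     the most variable (1 − p_inv) fraction of sites is divided by the
     expected entropy of a fully saturated column, E[H(multinomial(m,
     π̂))] computed exactly by enumeration for subset size m and
     empirical frequencies π̂.  The critical value Iss.c is estimated by
     simulation: alignments are evolved on a balanced ultrametric
     topology ("sym") and an equal-branch-length caterpillar ("asym" —
     the classic asymmetric test tree; an ultrametric caterpillar's
     nested short pendants cap neighbor-joining recovery well below any
     useful threshold) over a grid of depths.  Recovery rises with
     depth as signal accumulates, then falls as saturation erases it;
     Iss.c is interpolated at the post-peak depth where whole-topology
     neighbor-joining recovery crosses 0.95 (threshold and
     reconstruction method configurable).  A two-sided one-sample t
     statistic t = |Iss.c − Iss|/SE with df = round((1−p_inv)·sites) − 1
     gives the verdict.  The p_inv used defaults to the fraction of
     constant columns; a posterior estimate can be supplied instead.

2. **Relative-rate MCMC.**  Metropolis-Hastings over node heights,
   per-branch rates, GTR exchangeabilities (GT fixed at 1), base
   frequencies, gamma shape (4 discrete categories, mean-per-category
   discretization), proportion of invariant sites, the clock standard
   deviation σ, and the Yule birth rate, on a fully resolved, fixed
   topology.  The likelihood is the standard pruning algorithm under
   GTR+Γ(4)+I with per-branch expected substitutions = rate × time
   span.  Branch rates are i.i.d. lognormal with real-space mean fixed
   to 1 (μ = −σ²/2) — continuous per-branch rates, not the discretized
   quantile scheme some samplers use; the prior mean and variance are
   the same and the continuous form is simpler.

3. **Clade summaries.**  Per posterior sample, a clade's rate is the
   time-weighted mean over its crown branches (Σ rᵢtᵢ/Σ tᵢ); the stem
   and deeper connecting branches are excluded because they are the
   oldest and most saturation-affected.  Across samples this gives a
   posterior mean, a 95% HPD (shortest window over sorted samples
   containing ⌈0.95N⌉ of them), and an ESS.  Flags: *deviates from
   mean* = HPD excludes 1; *differs from focal* = HPD disjoint from the
   focal clade's HPD (disjointness is the conservative reading of
   "comparing HPD intervals"; whether the original comparison used
   interval disjointness or the HPD of the rate difference is not
   documented).  A maximum-clade-credibility tree with median node
   heights and median branch rates summarizes the tree log.

## Priors and moves

* Node heights: pure-birth (Yule) prior conditioned on the tip count.
  Convention: looking backward with k extant lineages the next
  coalescence is Exponential((k−1)λ), so a two-tip tree's root height
  is Exponential(λ) with mean 1/λ.  The simulator and the prior use the
  same convention, which is what parameter-recovery tests require.
* σ (ucld_stdev) ~ Exponential(mean 1/3); gamma shape ~ Exponential(1);
  p_inv ~ Uniform(0,1); free exchangeabilities ~ LogNormal(0, 1.5);
  birth rate ~ log-uniform on [1e−6, 1e3]; frequencies ~ flat Dirichlet.
  These are weakly informative declared defaults (the empirical
  analysis this emulates left its priors at software defaults without
  enumerating them); all are configurable.
* Moves: multiplicative scale moves (positive scalars, single branch
  rates, root height, whole-height vector), uniform node-height slide,
  frequency delta-exchange, and three joint moves that matter for
  mixing: σ-with-rates (scales σ and stretches all log-rate deviations
  with it, walking the funnel), heights-up/rates-down (likelihood
  invariant), and a subtree stretch (clade heights × f, crown rates
  ÷ f) that traverses the rate-versus-time ridge for one clade at a
  time.  Step sizes self-tune toward 20–40% acceptance during burn-in
  and are frozen afterwards, so the post-burn-in kernel is fixed and
  runs are bit-reproducible under a fixed seed.
* Defaults: 5×10⁵ generations, sampling every 100, 10% burn-in.  The
  empirical-scale setting (3×10⁸ generations, sampling every 5000) is
  reachable through the same configuration fields.

## Synthetic data

The generator is the exact probabilistic counterpart of the inference
model: Yule tree (default 16 tips, birth rate 8 — crown depth around
0.4 substitutions/site, a moderately divergent arthropod mitochondrial
scale), i.i.d. mean-1 lognormal branch rates with optional per-clade
multipliers applied to crown branches only, GTR+Γ+I site evolution with
an AT-rich transition-biased model (exchangeabilities 1, 8, 1.5, 0.8,
10, 1; frequencies 0.30/0.17/0.14/0.39; shape 0.3; p_inv 0.2), and
codon-position rate multipliers (default 0.6/0.3/2.1, normalized to
mean 1) making position 3 the fastest.  What it does **not** emulate:
alignment error, ambiguous-homology columns, indels, selection
(dN/dS), base-composition heterogeneity among lineages, and
among-gene rate variation — so green recovery tests certify the
inference machinery, not robustness to those real-data pathologies.

### Which clade carries the rate multiplier

Relative rates and node times are partially confounded.  A clade's k-fold
rate elevation can be absorbed by stretching its node heights k-fold
whenever the surrounding time structure is elastic; the likelihood is
identical and only the Yule and rate priors arbitrate.  Pilot
simulations show absorption wins for young clades and for clades
hanging directly off the root (stretching the root costs only two stem
branches).  A deviation is identifiable when the clade is old (crown
≥ ~45% of the root age), attaches inside the backbone (parent below the
root), and has little headroom (parent height ≤ ~1.2 × crown height),
so that stretched heights collide with a pinned parent and the
distortion propagates.  The study-replicate generator therefore places
the multiplier on such clades — which is also the empirically relevant
situation: the taxonomic groups whose rates one screens are old,
order-level clades nested in a densely sampled phylogeny.  Even then
the posterior splits the signal between rates and times (posterior
clade rates land well below the simulated 3× and the tree-wide
anchoring pulls neutral clades slightly below 1), exactly the "low
precision" caveat the empirical analysis itself reports.  This
confounding is a property of the model class, not of this
implementation.

## Desk-scale study sizes

Validation studies default to 16 taxa × 1500 sites; 20 strict-clock
replicates at 3×10⁴ generations for HPD calibration and 20
deviant-clade replicates at 6×10⁴ generations for detection, sampling
every 60 with 10% burn-in; the prior-recovery chain runs 6×10⁵
likelihood-off generations thinned to 5001 samples; the benign Iss
battery uses a 17-taxon, 900-site alignment (NumOTU 4/8/16 — a 32-OTU
caterpillar needs more sites than desk scale for its critical value to
be defined at 95% reliability) with critical-value simulations over 8
depths × 12 replicates.  These sizes keep the full battery in the tens
of minutes on one core while leaving each check statistically
decisive; all are arguments, not constants.

## Numerical choices

* Site patterns are compressed once; partial likelihoods are rescaled
  per node only when the column maximum drops below 1e−140, and the
  per-pattern log-scale sum is maintained incrementally.  Single-branch
  moves recompute only the edited branch's transition matrices and the
  partials on the path to the root.
* Transition matrices come from the symmetrized eigendecomposition of
  the normalized GTR generator (unit expected substitutions at
  stationarity); tiny negative entries from round-off are clipped at 0.
* Pairwise ML distances use bounded Brent optimization on [1e−9, 20]
  substitutions/site; a pair whose optimum hits the cap is returned at
  the cap with a warning.  GTR parameters for distances are estimated
  once on the full alignment (empirical frequencies; exchangeabilities
  and guide-tree branch lengths by L-BFGS-B on a p-distance
  neighbor-joining tree) and reused for every partition.
* ESS uses FFT autocorrelations truncated at the first non-positive
  term; a zero-variance series has ESS = N by convention.
* Ambiguous IUPAC codes are treated as missing for distances and
  entropy, and as partial observations (unions of states) in the
  likelihood.
* Degenerate inputs raise typed errors: invariant alignments cannot fit
  a GTR; single-base compositions have no defined saturation entropy;
  polytomous or unrooted constraint trees are rejected with a message
  naming the offending structure.

## Known limitations

* Fully fixed topology: partially resolved constraints (letting the
  MCMC resolve poorly supported nodes) are not supported; the effect of
  this simplification on clade rate summaries is unquantified.
* The rate/time confounding above means absolute multipliers are
  under-recovered; calls are reliable for deep, well-nested clades and
  conservative elsewhere.
* Single-locus, single-partition inference; no model averaging over
  substitution models (fixed GTR+Γ+I is the upper envelope of the
  usual averaged space), no codon or amino-acid models, no
  path-sampling model comparison.
* The Iss critical value is a fresh simulation estimate, not a lookup
  of any published table; with the default grid it is reproducible but
  carries Monte-Carlo noise of a few hundredths.
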