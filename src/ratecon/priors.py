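"""Prior densities for the relaxed-clock model.

The Yule (pure-birth) prior on node heights is conditioned on the number
of tips: looking backward from the present with ``k`` lineages, the
waiting time to the next coalescence of the pure-birth process is
Exponential((k-1) * birth_rate), so a two-tip tree has root height
~ Exponential(birth_rate).  The branch-rate prior is i.i.d. lognormal
with its real-space mean anchored to 1 (mu = -sigma^2 / 2), which is
what makes inferred rates interpretable as multiples of the tree-wide
mean rate.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import lognorm

from .errors import InvalidArgumentError
from .trees import TimeTree


def yule_log_prior(tree: TimeTree, birth_rate: float) -> float:
    """Log density of the internal node heights under a Yule prior."""
    if birth_rate <= 0:
        raise InvalidArgumentError("birth rate must be > 0")
    if not tree.is_ultrametric(tol=1e-6):
        raise InvalidArgumentError("Yule prior requires an ultrametric tree")
    heights = np.sort(tree.heights[tree.n_tips:])  # ascending, h[-1] = root
    return yule_log_prior_heights(heights, birth_rate)


def yule_log_prior_heights(sorted_heights: np.ndarray, birth_rate: float) -> float:
    """Yule log density given ascending internal node heights (tips at 0)."""
    h = np.asarray(sorted_heights, dtype=float)
    n = h.size + 1  # tips
    if np.any(h < 0) or np.any(np.diff(h) < 0):
        return -np.inf
    # intervals, youngest first: k = n, n-1, ..., 2 lineages
    gaps = np.diff(np.concatenate(([0.0], h)))
    ks = np.arange(n, 1, -1)
    rates = (ks - 1) * birth_rate
    return float(np.sum(np.log(rates) - rates * gaps))


def rate_prior_logdensity(rates: np.ndarray, ucld_stdev: float) -> float:
    """Sum of log lognormal(mean 1) densities of per-branch rates.

    At ``ucld_stdev == 0`` the prior degenerates to a point mass at 1:
    returns 0 if every rate equals 1, else -inf.
    """
    if ucld_stdev < 0:
        raise InvalidArgumentError("ucld_stdev must be >= 0")
    r = np.asarray(rates, dtype=float)
    if np.any(r <= 0):
        return -np.inf
    if ucld_stdev == 0.0:
        return 0.0 if np.allclose(r, 1.0, rtol=0, atol=1e-12) else -np.inf
    mu = -0.5 * ucld_stdev ** 2
    return float(np.sum(lognorm.logpdf(r, s=ucld_stdev, scale=np.exp(mu))))


def lognormal_mean1_draws(ucld_stdev: float, size: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Direct draws from the mean-1 lognormal branch-rate prior."""
    if ucld_stdev == 0:
        return np.ones(size)
    mu = -0.5 * ucld_stdev ** 2
    return np.exp(rng.normal(mu, ucld_stdev, size=size))
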