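"""GTR-family substitution models with discrete-gamma rates and invariant sites.

The general time reversible (GTR) model is parameterized by six symmetric
exchangeabilities (order AC, AG, AT, CG, CT, GT, with GT fixed to 1) and the
stationary base frequencies.  The instantaneous rate matrix is rescaled so
that one unit of branch length equals one expected substitution per site at
stationarity.  Among-site rate variation uses the standard 4-category
discrete gamma (mean-per-category discretization) plus an invariant-site
mixture class.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma

from .errors import InvalidArgumentError

EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def discrete_gamma_rates(shape: float, n_cat: int) -> np.ndarray:
    """Mean rate of each of ``n_cat`` equal-probability gamma classes.

    The gamma has mean 1 (shape ``alpha``, rate ``alpha``); the returned
    rates average exactly 1.
    """
    if shape <= 0:
        raise InvalidArgumentError("gamma shape must be > 0")
    if n_cat < 1:
        raise InvalidArgumentError("need at least one rate category")
    bounds = _gamma.ppf(np.arange(1, n_cat) / n_cat, a=shape, scale=1.0 / shape)
    # E[X; X < b] for mean-1 gamma = regularized incomplete gamma at shape+1
    cum = gammainc(shape + 1.0, shape * bounds)
    full = np.concatenate(([0.0], cum, [1.0]))
    return n_cat * np.diff(full)


@dataclass
class SubstitutionModel:
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    gamma_shape: float | None = None
    p_inv: float = 0.0
    n_cat: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities <= 0).any():
            raise InvalidArgumentError("need 6 positive exchangeabilities")
        if self.freqs.shape != (4,) or (self.freqs <= 0).any():
            raise InvalidArgumentError("need 4 positive base frequencies")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("base frequencies must sum to 1")
        self.freqs = self.freqs / self.freqs.sum()
        if not 0.0 <= self.p_inv <= 1.0:
            raise InvalidArgumentError("p_inv must be in [0, 1]")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise InvalidArgumentError("gamma shape must be > 0")

    # -- core matrices ---------------------------------------------------
    def rate_matrix(self) -> np.ndarray:
        """Normalized GTR generator Q (rows sum to 0, mean rate 1)."""
        q = np.zeros((4, 4))
        for r, (i, j) in zip(self.exchangeabilities, _PAIRS):
            q[i, j] = r * self.freqs[j]
            q[j, i] = r * self.freqs[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(self.freqs * np.diag(q)).sum()
        return q / scale

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigen-decomposition Q = U diag(lam) U^-1 via the symmetrized form."""
        q = self.rate_matrix()
        sq = np.sqrt(self.freqs)
        s = (q * sq[:, None]) / sq[None, :]
        lam, v = np.linalg.eigh((s + s.T) / 2.0)
        u = v / sq[:, None]
        uinv = v.T * sq[None, :]
        return lam, u, uinv

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the discrete-gamma mixture (excluding +I)."""
        if self.gamma_shape is None:
            return np.ones(1), np.ones(1)
        rates = discrete_gamma_rates(self.gamma_shape, self.n_cat)
        return rates, np.full(self.n_cat, 1.0 / self.n_cat)

    def transition_matrix(self, t: float | np.ndarray) -> np.ndarray:
        """P(t) = exp(Qt); broadcasts over an array of branch lengths."""
        lam, u, uinv = self.eigensystem()
        t = np.asarray(t, dtype=float)
        e = np.exp(np.multiply.outer(t, lam))
        p = (u * e[..., None, :]) @ uinv
        return np.clip(p, 0.0, None)

    # -- conveniences ------------------------------------------------------
    def with_(self, **kw) -> "SubstitutionModel":
        return replace(self, **kw)

    @classmethod
    def jc(cls, **kw) -> "SubstitutionModel":
        """Equal frequencies and exchangeabilities (Jukes-Cantor)."""
        return cls(np.ones(6), np.full(4, 0.25), **kw)

    @classmethod
    def coi_like(cls, **kw) -> "SubstitutionModel":
        """An AT-rich, transition-biased parameterization typical of
        arthropod mitochondrial protein-coding genes."""
        defaults = dict(
            exchangeabilities=np.array([1.0, 8.0, 1.5, 0.8, 10.0, 1.0]),
            freqs=np.array([0.30, 0.17, 0.14, 0.39]),
        )
        defaults.update(kw)
        return cls(**defaults)
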