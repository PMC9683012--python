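"""Nucleotide substitution models shared by the simulator and the dating engine.

Implements the general time-reversible (GTR) rate matrix with discrete-gamma
rate variation (Yang 1994 style, category means, mean rate 1).  Transition
probabilities are obtained by spectral decomposition of the symmetrised rate
matrix, which is numerically stable for reversible models.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

NUCLEOTIDES = "ACGT"
#: order of GTR exchangeability parameters
EXCHANGE_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of the equal-probability discrete-gamma categories.

    The gamma has shape ``shape`` and mean 1.  Category boundaries are the
    quantiles i/k; the rate of a category is the conditional mean of the
    distribution inside its bin, so the average over categories is exactly 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    k = int(n_categories)
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X ; X <= b] for Gamma(shape, scale=1/shape) equals gammainc(shape+1, shape*b)
    partial = gammainc(shape + 1, shape * bounds[1:-1])
    partial = np.concatenate([[0.0], partial, [1.0]])
    rates = k * np.diff(partial)
    return rates


@dataclass
class GTRModel:
    """GTR+Gamma nucleotide model.

    Parameters
    ----------
    exchangeabilities:
        Six symmetric exchange rates in the order AC, AG, AT, CG, CT, GT.
    base_freqs:
        Stationary frequencies of A, C, G, T (must sum to 1).
    gamma_shape:
        Shape of the discrete-gamma distribution of site rates; ``None``
        disables rate variation.
    n_categories:
        Number of discrete-gamma categories (ignored when shape is None).
    """

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_categories: int = 4
    _eigen: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValueError("need 6 strictly positive exchangeabilities")
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must be 4 positive values summing to 1")

    @property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def rate_matrix(self) -> np.ndarray:
        """Q normalised to one expected substitution per site per unit time."""
        pi = np.asarray(self.base_freqs, dtype=float)
        q = np.zeros((4, 4))
        for s, (a, b) in zip(self.exchangeabilities, EXCHANGE_PAIRS):
            i, j = NUCLEOTIDES.index(a), NUCLEOTIDES.index(b)
            q[i, j] = s * pi[j]
            q[j, i] = s * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(pi, np.diag(q))
        return q / scale

    def eigen(self):
        """Spectral decomposition (eigenvalues, right vectors, inverse)."""
        if self._eigen is None:
            pi = np.asarray(self.base_freqs, dtype=float)
            sp = np.sqrt(pi)
            q = self.rate_matrix()
            sym = (sp[:, None] * q) / sp[None, :]
            w, u = np.linalg.eigh((sym + sym.T) / 2.0)
            right = u / sp[:, None]
            inv = u.T * sp[None, :]
            self._eigen = (w, right, inv)
        return self._eigen

    def transition_matrices(self, distances) -> np.ndarray:
        """P(t) for an array of branch lengths; shape (len(t), 4, 4)."""
        w, right, inv = self.eigen()
        t = np.atleast_1d(np.asarray(distances, dtype=float))
        if np.any(t < 0):
            raise ValueError("branch lengths must be nonnegative")
        expwt = np.exp(np.multiply.outer(t, w))
        p = np.einsum("ij,tj,jk->tik", right, expwt, inv)
        np.clip(p, 0.0, 1.0, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def jc_p_distance_expectation(rate: float, divergence_my: float) -> float:
    """Closed-form expected p-distance between two tips whose common
    ancestor lived ``divergence_my`` million years ago (tip-to-tip path
    2*T) under Jukes-Cantor at ``rate`` substitutions/site/My."""
    return 0.75 * (1.0 - np.exp(-(8.0 / 3.0) * rate * divergence_my))
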