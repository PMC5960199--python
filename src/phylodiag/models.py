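"""Time-reversible substitution models (GTR, LG, JC) with discrete-gamma
rate heterogeneity.

The instantaneous rate matrix is built as ``q_ij = s_ij * pi_j`` from a
symmetric exchangeability matrix S and stationary frequencies pi, then
rescaled so one unit of branch length equals one expected substitution per
site (``-sum_i pi_i q_ii = 1``).  Because Q is reversible it is similar to a
symmetric matrix; transition matrices are computed from its eigensystem.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._lg import AA_ORDER, LG_FREQUENCIES, LG_LOWER_TRIANGLE


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability bins of a
    Gamma(shape, mean 1) distribution; the rates average to exactly 1."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    k = n_categories
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape)
    # E[X; X in bin] for X ~ Gamma(a, 1/a) via the regularized lower
    # incomplete gamma with shifted shape a+1
    upper = gammainc(shape + 1.0, np.concatenate([bounds * shape, [np.inf]]))
    lower = gammainc(shape + 1.0, np.concatenate([[0.0], bounds * shape]))
    rates = k * (upper - lower)
    return rates / rates.mean()


class SubstitutionModel:
    """A reversible CTMC over ``k`` states plus a discrete-gamma layer.

    Parameters
    ----------
    name
        ``"GTR"``, ``"LG"`` or ``"JC"`` (informational).
    alphabet
        ``"nucleotide"`` or ``"amino_acid"``.
    exchangeabilities
        Symmetric non-negative ``k x k`` matrix (diagonal ignored).
    frequencies
        Stationary distribution, length ``k``.
    gamma_shape, n_categories
        Discrete-gamma rate heterogeneity; ``n_categories=1`` disables it.
    """

    def __init__(self, name, alphabet, exchangeabilities, frequencies,
                 gamma_shape: float = 1.0, n_categories: int = 4):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        k = pi.size
        if S.shape != (k, k):
            raise ValueError(f"exchangeability matrix shape {S.shape} != ({k},{k})")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if (S < 0).any() or (pi < 0).any():
            raise ValueError("exchangeabilities and frequencies must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {pi.sum()!r}, not 1")
        self.name = name
        self.alphabet = alphabet
        self.exchangeabilities = S
        self.frequencies = pi
        self.gamma_shape = float(gamma_shape)
        self.n_categories = int(n_categories)
        self.k = k

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(pi, np.diag(Q))
        if scale <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        self.Q = Q / scale

        # symmetrize: B = D^{1/2} Q D^{-1/2} with D = diag(pi); eigh(B)
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        B = (self.Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = w
        self._left = U / sqrt_pi[:, None]     # D^{-1/2} U
        self._right = (U * sqrt_pi[:, None]).T  # U^T D^{1/2}

        self.category_rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * rate * t); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        P = (self._left * np.exp(self._eigval * rate * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t * r_c) over the gamma categories, shape (C, k, k)."""
        return np.stack([self.transition_matrix(t, r) for r in self.category_rates])

    def with_frequencies(self, frequencies) -> "SubstitutionModel":
        """Same exchangeabilities and gamma layer, new stationary frequencies."""
        return SubstitutionModel(self.name, self.alphabet, self.exchangeabilities,
                                 frequencies, self.gamma_shape, self.n_categories)

    def __repr__(self):
        g = f"+G{self.n_categories}(a={self.gamma_shape:g})" if self.n_categories > 1 else ""
        return f"<SubstitutionModel {self.name}{g} k={self.k}>"


# -- constructors --------------------------------------------------------


def jc(alphabet: str = "nucleotide", gamma_shape: float = 1.0,
       n_categories: int = 1) -> SubstitutionModel:
    k = 4 if alphabet == "nucleotide" else 20
    S = np.ones((k, k))
    return SubstitutionModel("JC", alphabet, S, np.full(k, 1.0 / k),
                             gamma_shape, n_categories)


def gtr(rates, frequencies, gamma_shape: float = 1.0,
        n_categories: int = 4) -> SubstitutionModel:
    """GTR from the six upper-triangle rates in order
    (AC, AG, AT, CG, CT, GT)."""
    rates = np.asarray(rates, dtype=float)
    if rates.size != 6:
        raise ValueError("GTR takes 6 exchangeability rates (AC, AG, AT, CG, CT, GT)")
    S = np.zeros((4, 4))
    S[np.triu_indices(4, k=1)] = rates
    S = S + S.T
    return SubstitutionModel("GTR", "nucleotide", S, frequencies, gamma_shape, n_categories)


def lg_exchangeabilities() -> np.ndarray:
    S = np.zeros((20, 20))
    S[np.tril_indices(20, k=-1)] = LG_LOWER_TRIANGLE
    return S + S.T


def lg(frequencies=None, gamma_shape: float = 1.0, n_categories: int = 4) -> SubstitutionModel:
    """The LG amino acid model; pass ``frequencies`` for the +F variant."""
    pi = np.asarray(LG_FREQUENCIES if frequencies is None else frequencies, dtype=float)
    pi = pi / pi.sum()
    return SubstitutionModel("LG", "amino_acid", lg_exchangeabilities(), pi,
                             gamma_shape, n_categories)


def lg_frequencies() -> np.ndarray:
    return np.asarray(LG_FREQUENCIES) / np.sum(LG_FREQUENCIES)


def random_gtr(rng: np.random.Generator, gamma_shape: float = 1.0,
               n_categories: int = 4) -> SubstitutionModel:
    """A random GTR draw (for property tests and simulations)."""
    rates = rng.uniform(0.2, 3.0, size=6)
    freqs = rng.dirichlet(np.full(4, 10.0))
    return gtr(rates, freqs, gamma_shape, n_categories)


STATE_ORDER = {"nucleotide": "ACGT", "amino_acid": AA_ORDER}
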