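"""Reversible nucleotide substitution models with discrete-gamma rates.

Implements HKY and GTR rate matrices and the four-category discrete gamma
approximation of among-site rate heterogeneity (equal-probability categories,
each represented by its mean rate, overall mean rate 1).  Used both to
simulate sequences and to compute pruning likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# unordered pairs in the canonical GTR exchangeability order
_GTR_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of *ncat* equal-probability gamma(alpha, 1/alpha) categories.

    The discretization of Yang (1994): category boundaries are gamma
    quantiles, each category's rate is its conditional mean, so the rates
    average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    bounds = gamma_dist.ppf(np.arange(ncat + 1) / ncat, a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = ncat * (upper - lower)
    return rates / rates.mean()  # exact renormalization against roundoff


@dataclass
class SubstModel:
    """HKY or GTR + discrete gamma.

    Parameters
    ----------
    freqs : stationary base frequencies in A, C, G, T order.
    kappa : transition/transversion rate ratio (HKY).
    exchangeabilities : six GTR rates (AC, AG, AT, CG, CT, GT); overrides kappa.
    alpha : gamma shape; ``None`` disables rate heterogeneity.
    ncat : number of discrete gamma categories.
    """

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 1.0
    exchangeabilities: tuple[float, ...] | None = None
    alpha: float | None = None
    ncat: int = 4

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0):
            raise ValueError("need four positive base frequencies")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.exchangeabilities is not None:
            ex = np.asarray(self.exchangeabilities, dtype=float)
            if ex.shape != (6,) or np.any(ex <= 0):
                raise ValueError("need six positive exchangeabilities")

    # -- rate matrix ---------------------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        """Instantaneous rate matrix Q, scaled to one expected change/site."""
        pi = np.asarray(self.freqs, dtype=float)
        Q = np.zeros((4, 4))
        for k, (i, j) in enumerate(_GTR_PAIRS):
            if self.exchangeabilities is not None:
                s = self.exchangeabilities[k]
            else:
                s = self.kappa if (i, j) in _TRANSITIONS else 1.0
            Q[i, j] = s * pi[j]
            Q[j, i] = s * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale

    def _eigensystem(self):
        cached = getattr(self, "_eig", None)
        if cached is not None:
            return cached
        pi = np.asarray(self.freqs, dtype=float)
        sqrt_pi = np.sqrt(pi)
        # S = D Q D^-1 with D = diag(sqrt pi) is symmetric for reversible Q
        B = self.rate_matrix() * sqrt_pi[:, None] / sqrt_pi[None, :]
        w, U = eigh((B + B.T) / 2.0)
        right = U / sqrt_pi[:, None]
        left = U.T * sqrt_pi[None, :]
        object.__setattr__(self, "_eig", (w, right, left))
        return w, right, left

    def gamma_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.ncat)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rate * t) for one rate category."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        w, right, left = self._eigensystem()
        P = (right * np.exp(w * rate * t)[None, :]) @ left
        return np.clip(P, 0.0, None)

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stacked P matrices, one per gamma category; shape (ncat, 4, 4)."""
        rates = self.gamma_rates()
        w, right, left = self._eigensystem()
        out = np.empty((len(rates), 4, 4))
        for k, r in enumerate(rates):
            out[k] = np.clip((right * np.exp(w * r * t)[None, :]) @ left,
                             0.0, None)
        return out


def hky_at_rich(kappa: float = 4.0, alpha: float = 0.5) -> SubstModel:
    """Default model for insect mtDNA: HKY with AT-rich frequencies."""
    return SubstModel(freqs=(0.40, 0.10, 0.10, 0.40), kappa=kappa, alpha=alpha)


def empirical_model(sequences, kappa: float = 4.0,
                    alpha: float | None = 0.5) -> SubstModel:
    """HKY+G with base frequencies estimated from (possibly gapped) sequences."""
    counts = np.ones(4)  # +1 pseudocount keeps frequencies positive
    for seq in sequences:
        for ch in seq.upper():
            i = BASE_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
    freqs = counts / counts.sum()
    return SubstModel(freqs=tuple(freqs), kappa=kappa, alpha=alpha)
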