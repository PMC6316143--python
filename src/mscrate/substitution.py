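"""Nucleotide substitution models (JC69, HKY85, GTR) with +G and +I rate mixtures.

All rate matrices are normalized to one expected substitution per site per
unit time, so branch lengths are in substitutions/site (s/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
N_BASES = 4

# exchangeability order for GTR: AC, AG, AT, CG, CT, GT
_GTR_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible nucleotide model with optional discrete-gamma and
    invariant-sites rate heterogeneity.

    Parameters
    ----------
    name
        One of ``JC69``, ``HKY85``, ``GTR``.
    base_freqs
        Stationary base frequencies (A, C, G, T); must sum to 1.
    exchangeabilities
        Six GTR exchangeabilities in order AC, AG, AT, CG, CT, GT.  For
        HKY85 these are derived from ``kappa``; ignored for JC69.
    kappa
        Transition/transversion rate ratio (HKY85 only).
    gamma_shape
        Shape of the discrete-gamma rate distribution; ``None`` disables it.
    n_categories
        Number of discrete-gamma categories (4 is the common convention).
    p_inv
        Proportion of invariant sites, ``0 <= p_inv < 1``.
    """

    name: str = "JC69"
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    kappa: float = 2.0
    gamma_shape: float | None = None
    n_categories: int = 4
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("JC69", "HKY85", "GTR"):
            raise ValueError(f"unknown model {self.name!r}")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0) or (freqs <= 0).any():
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        if self.name == "GTR":
            rates = np.asarray(self.exchangeabilities, dtype=float)
            if rates.shape != (6,) or (rates <= 0).any():
                raise ValueError("GTR needs 6 positive exchangeabilities")
        if self.name == "HKY85" and self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    # -- rate matrix -------------------------------------------------------

    @property
    def is_jc69(self) -> bool:
        return (
            self.name == "JC69"
            and tuple(self.base_freqs) == (0.25, 0.25, 0.25, 0.25)
        )

    def rate_matrix(self) -> np.ndarray:
        """Instantaneous rate matrix Q, scaled to mean rate 1."""
        pi = np.asarray(self.base_freqs, dtype=float)
        if self.name == "JC69":
            s = np.ones(6)
            pi = np.full(4, 0.25)
        elif self.name == "HKY85":
            # transitions: AG and CT
            s = np.array([1.0, self.kappa, 1.0, 1.0, self.kappa, 1.0])
        else:
            s = np.asarray(self.exchangeabilities, dtype=float)
        q = np.zeros((4, 4))
        for (i, j), rate in zip(_GTR_PAIRS, s):
            q[i, j] = rate * pi[j]
            q[j, i] = rate * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(pi * np.diag(q)).sum()
        return q / mean_rate

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); closed form for JC69, expm otherwise."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if self.is_jc69:
            e = np.exp(-4.0 * t / 3.0)
            p_same = 0.25 + 0.75 * e
            p_diff = 0.25 - 0.25 * e
            p = np.full((4, 4), p_diff)
            np.fill_diagonal(p, p_same)
            return p
        return expm(self.rate_matrix() * t)

    # -- among-site rate variation ----------------------------------------

    def site_rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (rates, weights) of the discrete rate mixture.

        Discrete gamma uses equal-probability categories with the bin-mean
        rates; combined with an invariant class the mixture keeps mean 1.
        """
        if self.gamma_shape is None:
            var_rates = np.array([1.0])
            var_weights = np.array([1.0])
        else:
            var_rates = _discrete_gamma_rates(self.gamma_shape, self.n_categories)
            var_weights = np.full(self.n_categories, 1.0 / self.n_categories)
        if self.p_inv > 0:
            scale = 1.0 / (1.0 - self.p_inv)  # keep overall mean rate at 1
            rates = np.concatenate([[0.0], var_rates * scale])
            weights = np.concatenate([[self.p_inv], var_weights * (1.0 - self.p_inv)])
        else:
            rates, weights = var_rates, var_weights
        return rates, weights


@lru_cache(maxsize=64)
def _discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean rate of each of k equal-probability bins of Gamma(shape, mean 1)."""
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape)
    bounds = np.concatenate([[0.0], cuts * shape, [np.inf]])
    # E[r | bin] * P(bin) = I(a+1, upper) - I(a+1, lower) with mean-1 scaling
    mass = gammainc(shape + 1.0, bounds[1:]) - gammainc(shape + 1.0, bounds[:-1])
    rates = mass * k
    return rates


def jc69() -> SubstitutionModel:
    return SubstitutionModel(name="JC69")


def gtr_gi(
    base_freqs: tuple[float, float, float, float],
    exchangeabilities: tuple[float, ...],
    gamma_shape: float,
    p_inv: float,
) -> SubstitutionModel:
    """Convenience constructor for GTR+G+I."""
    return SubstitutionModel(
        name="GTR",
        base_freqs=base_freqs,
        exchangeabilities=tuple(exchangeabilities),
        gamma_shape=gamma_shape,
        p_inv=p_inv,
    )


def jc69_mismatch_probability(d: float | np.ndarray) -> float | np.ndarray:
    """Expected fraction of differing sites at JC69 distance d."""
    return 0.75 * (1.0 - np.exp(-4.0 * np.asarray(d, dtype=float) / 3.0))


def jc69_distance_from_mismatch(p: float) -> float:
    """Closed-form JC69 ML distance from a mismatch fraction; inf if saturated."""
    if p < 0:
        raise ValueError("mismatch fraction must be non-negative")
    if p >= 0.75:
        return float("inf")
    return -0.75 * np.log1p(-4.0 * p / 3.0)
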