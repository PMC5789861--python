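"""Output priors for the error-gated Hebbian rule.

The ICA part of the learning rule assumes the outputs follow a factorized
prior p0(u) = prod_i p0(u_i) and uses three quantities derived from it:

* the global error ``E(u) = -log p0(u)``,
* the activation function ``g(u) = dE/du`` (elementwise), and
* its derivative ``g'(u)`` (needed only by the stability theory).

The priors implemented here are the generalized Gaussian family
``p0(s) ∝ exp(-b |s|^a)`` with shape ``a > 0`` and scale ``b > 0``, which
covers the Gaussian (a = 2, b = 1/2) and Laplace (a = 1) cases.  A hard
uniform prior has infinite E off-support and an undefined g, so source
separation aimed at uniform (sub-Gaussian) sources uses a smooth
sub-Gaussian surrogate from the same family (a = 4 by default, with b tuned
to unit variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = ["PriorSpec", "gaussian_prior", "uniform_surrogate_prior", "gen_gaussian_prior"]


def _unit_variance_scale(a: float) -> float:
    # b such that exp(-b|s|^a), normalized, has unit variance.
    return (special.gamma(3.0 / a) / special.gamma(1.0 / a)) ** (a / 2.0)


@dataclass(frozen=True)
class PriorSpec:
    """Factorized generalized-Gaussian output prior p0(u_i) ∝ exp(-b |u_i|^a).

    Parameters
    ----------
    family : str
        One of ``"gaussian"``, ``"gen_gaussian"``, ``"uniform_surrogate"``.
        The family tag is descriptive; the math is fully determined by
        ``a`` and ``b``.
    a : float
        Shape exponent (> 0).  a = 2 is Gaussian, a > 2 sub-Gaussian,
        a < 2 super-Gaussian.
    b : float
        Scale (> 0).  ``None`` selects the unit-variance scale.
    """

    family: str = "gaussian"
    a: float = 2.0
    b: float = field(default=0.5)

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"shape exponent a must be positive, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"scale b must be positive, got {self.b}")

    # -- normalization ---------------------------------------------------
    @property
    def log_norm(self) -> float:
        """log Z with Z = ∫ exp(-b|s|^a) ds = (2/a) Γ(1/a) b^{-1/a}."""
        a, b = self.a, self.b
        return np.log(2.0 / a) + special.gammaln(1.0 / a) - np.log(b) / a

    # -- elementwise quantities ------------------------------------------
    def energy1(self, u):
        """-log p0 of a scalar output, including the normalization constant."""
        return self.b * np.abs(u) ** self.a + self.log_norm

    def g(self, u):
        """Activation g(u) = dE/du = a b |u|^{a-1} sign(u)."""
        u = np.asarray(u, dtype=float)
        return self.a * self.b * np.abs(u) ** (self.a - 1.0) * np.sign(u)

    def g_prime(self, u):
        """g'(u) = a (a-1) b |u|^{a-2} (diverges at 0 for a < 2)."""
        u = np.asarray(u, dtype=float)
        with np.errstate(divide="ignore"):
            return self.a * (self.a - 1.0) * self.b * np.abs(u) ** (self.a - 2.0)

    # -- vector quantities -----------------------------------------------
    def energy(self, U):
        """E(u) = -log p0(u) summed over output channels.

        ``U`` may be a single output vector or an (n, N) batch; the result
        is a scalar or length-n array.
        """
        U = np.asarray(U, dtype=float)
        return self.energy1(U).sum(axis=-1)

    def logpdf1(self, u):
        return -self.energy1(u)

    def sample(self, size, rng):
        """Draw from the prior (used by theory cross-checks)."""
        from scipy import stats

        return stats.gennorm.rvs(self.a, scale=self.b ** (-1.0 / self.a), size=size, random_state=rng)


def gaussian_prior() -> PriorSpec:
    """Unit Gaussian prior: E(u) = |u|^2/2 + const, g(u) = u."""
    return PriorSpec("gaussian", a=2.0, b=0.5)


def gen_gaussian_prior(a: float, b: float | None = None) -> PriorSpec:
    """Generalized Gaussian prior; ``b=None`` tunes the scale to unit variance."""
    if b is None:
        b = _unit_variance_scale(a)
    return PriorSpec("gen_gaussian", a=a, b=b)


def uniform_surrogate_prior(a: float = 4.0) -> PriorSpec:
    """Smooth sub-Gaussian surrogate for a hard uniform prior.

    −log p0 of a uniform density is infinite off-support and its derivative
    is not a usable activation, so runs that target uniform sources use the
    unit-variance generalized Gaussian with shape ``a`` (default 4,
    excess kurtosis ≈ −0.81) instead.
    """
    return PriorSpec("uniform_surrogate", a=a, b=_unit_variance_scale(a))
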