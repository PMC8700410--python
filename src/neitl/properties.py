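"""Moments, inequality curves, quantile shape measures and entropies.

The production route for every integral quantity is adaptive quadrature of
the closed-form density; the series expansions in :mod:`neitl.series` are
cross-check oracles only.  The NEITL right tail behaves like
``x**-(theta*delta + 1)``, so the r-th raw moment exists iff
``r < theta*delta``; this analytic guard backs up the quadrature
convergence check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .distributions import (
    NEITLParams,
    neitl_cdf,
    neitl_logpdf,
    neitl_pdf,
    neitl_quantile,
)

__all__ = [
    "MomentSummary",
    "EntropyValue",
    "MomentExistenceError",
    "raw_moment",
    "moment_summary",
    "incomplete_moment",
    "lorenz",
    "bonferroni",
    "bowley_skewness",
    "moors_kurtosis",
    "renyi_entropy",
    "rho_entropy",
]


class MomentExistenceError(ValueError):
    """The requested moment (or entropy integral) does not converge."""


@dataclass(frozen=True)
class MomentSummary:
    """Mean, variance and the moment-based shape measures.

    Kurtosis is reported raw (beta_2 = mu_4 / sigma^4), not in excess form;
    skewness is mu_3 / sigma^3.
    """

    mean: float
    variance: float
    skewness: float
    kurtosis: float
    order_max: int = 4


@dataclass(frozen=True)
class EntropyValue:
    order: float
    value: float

    def __post_init__(self):
        if not self.order > 0 or self.order == 1:
            raise ValueError("entropy order must be positive and != 1")


def _tail_index(p: NEITLParams) -> float:
    return p.theta * p.delta


def _quad_split(f, p: NEITLParams) -> tuple[float, float]:
    """Integrate f over (0, inf), splitting at the median to help quad."""
    split = neitl_quantile(0.5, p)
    v1, e1 = integrate.quad(f, 0.0, split, limit=200)
    v2, e2 = integrate.quad(f, split, np.inf, limit=200)
    return v1 + v2, e1 + e2


def raw_moment(p: NEITLParams, r: int, cfg=None) -> float:
    """E[X^r] by adaptive quadrature of x^r f(x).

    Raises :class:`MomentExistenceError` when r >= theta*delta (divergent
    tail) or when the quadrature fails to converge.
    """
    if r < 0:
        raise ValueError("r must be a non-negative integer")
    if r == 0:
        return 1.0
    if r >= _tail_index(p):
        raise MomentExistenceError(
            f"E[X^{r}] diverges: tail index theta*delta = {_tail_index(p):g} <= {r}"
        )
    value, err = _quad_split(lambda x: x**r * neitl_pdf(x, p), p)
    if not np.isfinite(value) or err > 1e-6 * max(1.0, abs(value)):
        raise MomentExistenceError(
            f"quadrature for E[X^{r}] did not converge (err={err:g})"
        )
    return value


def moment_summary(p: NEITLParams) -> MomentSummary:
    """Mean, variance, skewness (mu3/sigma^3) and raw kurtosis (mu4/sigma^4)."""
    m = [raw_moment(p, r) for r in range(1, 5)]
    mean = m[0]
    var = m[1] - mean**2
    mu3 = m[2] - 3 * mean * m[1] + 2 * mean**3
    mu4 = m[3] - 4 * mean * m[2] + 6 * mean**2 * m[1] - 3 * mean**4
    return MomentSummary(
        mean=mean,
        variance=var,
        skewness=mu3 / var**1.5,
        kurtosis=mu4 / var**2,
    )


def incomplete_moment(p: NEITLParams, r: int, y: float, cfg=None) -> float:
    """eta_r(y) = int_0^y x^r f(x) dx by quadrature."""
    if y <= 0:
        raise ValueError("y must be positive")
    if r < 0:
        raise ValueError("r must be a non-negative integer")
    # integrate on the probability scale: eta_r(y) = int_0^F(y) Q(u)^r du.
    # This keeps the integrand well scaled however large y is (in the x
    # domain a huge upper limit hides the density's mass from the adaptive
    # subdivision).
    Fy = float(neitl_cdf(y, p))
    if Fy == 0.0:
        return 0.0
    value, err = integrate.quad(
        lambda u: neitl_quantile(u, p) ** r, 0.0, Fy, limit=200
    )
    if not np.isfinite(value) or err > 1e-7 * max(1.0, abs(value)):
        raise MomentExistenceError("incomplete-moment quadrature did not converge")
    return value


def lorenz(p: NEITLParams, m: float) -> float:
    """Lorenz curve Lz(m) = eta_1(m) / E[X]."""
    if m <= 0:
        raise ValueError("m must be positive")
    return incomplete_moment(p, 1, m) / raw_moment(p, 1)


def bonferroni(p: NEITLParams, m: float) -> float:
    """Bonferroni curve Bu(m) = Lz(m) / F(m); undefined where F(m) = 0."""
    Fm = neitl_cdf(m, p)
    if Fm == 0.0:
        raise ZeroDivisionError("Bonferroni curve undefined where F(m) = 0")
    return lorenz(p, m) / Fm


def bowley_skewness(p: NEITLParams) -> float:
    """Quartile-based (Bowley) skewness (Q3 - 2 Q2 + Q1) / (Q3 - Q1)."""
    q1, q2, q3 = (neitl_quantile(u, p) for u in (0.25, 0.5, 0.75))
    return (q3 - 2 * q2 + q1) / (q3 - q1)


def moors_kurtosis(p: NEITLParams) -> float:
    """Octile-based (Moors) kurtosis (E7 - E5 + E3 - E1) / (E6 - E2)."""
    e = {k: neitl_quantile(k / 8.0, p) for k in (1, 2, 3, 5, 6, 7)}
    return (e[7] - e[5] + e[3] - e[1]) / (e[6] - e[2])


def _f_power_integral(p: NEITLParams, b: float) -> float:
    """int f^b dx with existence checks at both ends of the support.

    Near 0 the integrand behaves like x^b (integrable for b > 0); in the
    tail like x^(-b (theta*delta + 1)), integrable iff b(theta*delta+1) > 1.
    """
    if b * (_tail_index(p) + 1.0) <= 1.0:
        raise MomentExistenceError(
            "integral of f^b diverges in the tail for these parameters"
        )
    value, err = _quad_split(lambda x: np.exp(b * neitl_logpdf(x, p)), p)
    if not np.isfinite(value) or err > 1e-8 * max(1.0, abs(value)):
        raise MomentExistenceError("quadrature for int f^b did not converge")
    return value


def renyi_entropy(p: NEITLParams, b: float, cfg=None) -> float:
    """Renyi entropy Xi(b) = log(int f^b) / (1 - b), b > 0, b != 1."""
    if not b > 0 or b == 1:
        raise ValueError("Renyi order b must be positive and != 1")
    return float(np.log(_f_power_integral(p, b)) / (1.0 - b))


def rho_entropy(p: NEITLParams, rho: float, cfg=None) -> float:
    """The rho-entropy E(rho) = log(1 - int f^rho) / (rho - 1).

    Defined only where int f^rho < 1 (peaked densities with rho > 1 can
    push the integral above 1, in which case a domain error is raised).
    """
    if not rho > 0 or rho == 1:
        raise ValueError("rho must be positive and != 1")
    integral = _f_power_integral(p, rho)
    if integral >= 1.0:
        raise ValueError(
            f"rho-entropy undefined: int f^rho = {integral:g} >= 1 for these parameters"
        )
    return float(np.log1p(-integral) / (rho - 1.0))
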