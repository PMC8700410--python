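"""Truncated series expansions used as independent cross-check oracles.

The NE-X transform admits a linear representation from the two binomial
expansions

    (1 - z)^(-k) = sum_i C(i+k-1, i) z^i          (|z| < 1),
    (1 - w)^v    = sum_j C(v, j) (-w)^j           (|w| < 1),

with z = (1-theta) G^2 and w = G^2, where G is the ITL baseline CDF.  The
result is a power series in G whose coefficients multiply *baseline-only*
functionals (powers of G against the baseline density or quantile), so
every term can be evaluated without ever touching the closed-form NEITL
density -- which is exactly what makes these sums useful as independent
oracles for it.

Convergence: the z-series needs |(1-theta) G^2| < 1 for all x, i.e. theta
in (0, 2); outside that region the closed forms are authoritative and the
series functions raise :class:`SeriesConvergenceError`.  (Re-expanding the
G-powers once more into powers of the tail ratio A = 1 - G, as is
sometimes done to reach pure beta-function formulas, produces a formally
divergent rearrangement -- binomial growth 4^(i+j) against polynomially
decaying coefficients -- and is deliberately avoided here.)

These expansions are *not* the production evaluation path: they exist so
tests can compare two independent routes to the same number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .distributions import NEITLParams, itl_cdf, itl_pdf, itl_ppf

__all__ = [
    "SeriesConfig",
    "SeriesConvergenceError",
    "neitl_cdf_series",
    "neitl_pdf_series",
    "raw_moment_series",
    "incomplete_moment_series",
    "renyi_entropy_series",
    "ss_reliability_series",
]


class SeriesConvergenceError(ValueError):
    """The requested series does not converge (or failed to, within budget)."""


@dataclass(frozen=True)
class SeriesConfig:
    """Truncation policy: max_terms bounds each index, tol is the absolute
    tail tolerance at which a sum is declared converged."""

    max_terms: int = 200
    tol: float = 1e-10

    def __post_init__(self):
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")


_DEFAULT = SeriesConfig()
_QUIET = 8  # consecutive sub-tol blocks before declaring convergence


def _require_converging_theta(theta: float):
    if not 0 < theta < 2:
        raise SeriesConvergenceError(
            "the (1-theta)^i binomial series requires theta in (0, 2); "
            f"got theta={theta}"
        )


def _sum_power_series(coef, z: float, cfg: SeriesConfig) -> float:
    """sum_i coef(i) z^i with a tail-quiet stop; raises if the budget runs out."""
    total = 0.0
    quiet = 0
    zi = 1.0
    for i in range(cfg.max_terms):
        t = coef(i) * zi
        total += t
        zi *= z
        quiet = quiet + 1 if abs(t) < cfg.tol else 0
        if quiet >= _QUIET:
            return total
    raise SeriesConvergenceError("series did not converge within max_terms")


def _sum_single_series(term, coef, cfg: SeriesConfig) -> float:
    """sum_i coef(i) term(i) with a tail-quiet stop (geometric coefficient decay)."""
    total = 0.0
    quiet = 0
    for i in range(cfg.max_terms):
        t = coef(i) * term(i)
        total += t
        quiet = quiet + 1 if abs(t) < cfg.tol else 0
        if quiet >= _QUIET:
            return total
    raise SeriesConvergenceError("series did not converge within max_terms")


def neitl_cdf_series(x: float, p: NEITLParams, cfg: SeriesConfig = _DEFAULT) -> float:
    """CDF as 1 - sum C(i+theta-1,i)(1-theta)^i C(theta,j)(-1)^j G^(2(i+j))."""
    theta = p.theta
    _require_converging_theta(theta)
    G = itl_cdf(float(x), p.delta)
    G2 = G * G
    # the double sum over (i, j) factorises into two 1-D power series in G^2
    si = _sum_power_series(
        lambda i: special.binom(i + theta - 1, i) * (1.0 - theta) ** i, G2, cfg
    )
    sj = _sum_power_series(
        lambda j: special.binom(theta, j) * (-1.0) ** j, G2, cfg
    )
    return 1.0 - si * sj


def neitl_pdf_series(x: float, p: NEITLParams, cfg: SeriesConfig = _DEFAULT) -> float:
    """PDF as 2 theta^2 g(x) sum C(i+theta,i)(1-theta)^i C(theta-1,j)(-1)^j G^(u+1)."""
    theta, delta = p.theta, p.delta
    _require_converging_theta(theta)
    G = itl_cdf(float(x), delta)
    g = itl_pdf(float(x), delta)
    G2 = G * G
    si = _sum_power_series(
        lambda i: special.binom(i + theta, i) * (1.0 - theta) ** i, G2, cfg
    )
    sj = _sum_power_series(
        lambda j: special.binom(theta - 1.0, j) * (-1.0) ** j, G2, cfg
    )
    return 2.0 * theta**2 * g * G * si * sj


def raw_moment_series(p: NEITLParams, r: int, cfg: SeriesConfig = _DEFAULT) -> float:
    """E[X^r] through the single binomial expansion of the density.

    Expanding only the negative-power factor (1-(1-theta)G^2)^-(theta+1)
    (geometric term decay |1-theta|^i) and keeping the rest in a
    baseline-only coefficient integral:

        E[X^r] = 2 theta^2 sum_i C(i+theta, i) (1-theta)^i M_i,
        M_i = int_0^1 Q_ITL(v; delta)^r v^(2i+1) (1-v^2)^(theta-1) dv.

    The v -> 1 endpoint is integrable iff r < theta*delta, the moment
    existence condition.
    """
    theta, delta = p.theta, p.delta
    _require_converging_theta(theta)
    if r >= theta * delta:
        raise SeriesConvergenceError("moment series needs r < theta*delta")

    def M(i: int) -> float:
        def f(v):
            return itl_ppf(v, delta) ** r * v ** (2 * i + 1) * (1.0 - v * v) ** (theta - 1.0)

        split = 1.0 - 1.0 / (2 * i + 2)
        v1, _ = integrate.quad(f, 0.0, split, limit=200)
        v2, _ = integrate.quad(f, split, 1.0, limit=200)
        return v1 + v2

    s = _sum_single_series(
        M, lambda i: special.binom(i + theta, i) * (1.0 - theta) ** i, cfg
    )
    return 2.0 * theta**2 * s


def incomplete_moment_series(
    p: NEITLParams, r: int, y: float, cfg: SeriesConfig = _DEFAULT
) -> float:
    """eta_r(y) via the same expansion, truncating the integral at G(y)."""
    if y <= 0:
        raise ValueError("y must be positive")
    theta, delta = p.theta, p.delta
    _require_converging_theta(theta)
    Gy = itl_cdf(y, delta)

    def M(i: int) -> float:
        val, _ = integrate.quad(
            lambda v: itl_ppf(v, delta) ** r
            * v ** (2 * i + 1)
            * (1.0 - v * v) ** (theta - 1.0),
            0.0,
            Gy,
            limit=200,
        )
        return val

    s = _sum_single_series(
        M, lambda i: special.binom(i + theta, i) * (1.0 - theta) ** i, cfg
    )
    return 2.0 * theta**2 * s


def renyi_entropy_series(p: NEITLParams, b: float, cfg: SeriesConfig = _DEFAULT) -> float:
    """Renyi entropy of order b via the expansion of f^b.

    Only the factor (1-(1-theta)G^2)^(-b(theta+1)) is expanded:

        int f^b = (2 theta^2)^b sum_i C(b(theta+1)+i-1, i) (1-theta)^i N_i,
        N_i = int g^b G^(b+2i) (1-G^2)^(b(theta-1)) dx.
    """
    theta, delta = p.theta, p.delta
    _require_converging_theta(theta)
    if not b > 0 or b == 1:
        raise ValueError("order b must be positive and != 1")
    if b * (theta * delta + 1.0) <= 1.0:
        raise SeriesConvergenceError("int f^b diverges in the tail")

    def N(i: int) -> float:
        def f(x):
            G = itl_cdf(x, delta)
            return (
                itl_pdf(x, delta) ** b
                * G ** (b + 2 * i)
                * ((1.0 - G) * (1.0 + G)) ** (b * (theta - 1.0))
            )

        val1, _ = integrate.quad(f, 0.0, 1.0, limit=200)
        val2, _ = integrate.quad(f, 1.0, np.inf, limit=200)
        return val1 + val2

    s = _sum_single_series(
        N,
        lambda i: special.binom(b * (theta + 1.0) + i - 1, i) * (1.0 - theta) ** i,
        cfg,
    )
    integral = (2.0 * theta**2) ** b * s
    if integral <= 0:
        raise SeriesConvergenceError("truncated series gave a non-positive integral")
    return float(np.log(integral) / (1.0 - b))


def ss_reliability_series(
    p1: NEITLParams, p2: NEITLParams, cfg: SeriesConfig = _DEFAULT
) -> float:
    """Stress-strength R = P(X2 < X1) via the series expansion of F2.

    On the strength's baseline scale V = G1(X1) (density h1 = the NE-X
    transform density), expanding F2's negative-power factor gives

        R = 1 - sum_i C(i+theta2-1, i) (1-theta2)^i U_i,
        U_i = int_0^1 (1 - G2^2)^theta2 G2^(2i) h1(v) dv,

    with G2(v) = 1 - (1-v)^(delta2/delta1).  Only theta2 must lie in
    (0, 2); theta1 is unrestricted and theta1 = theta2 is not required.
    """
    _require_converging_theta(p2.theta)
    th1, th2 = p1.theta, p2.theta
    c = p2.delta / p1.delta

    def h1(v):
        return (
            2.0
            * th1**2
            * v
            * (1.0 - v * v) ** (th1 - 1.0)
            / (1.0 + (th1 - 1.0) * v * v) ** (th1 + 1.0)
        )

    def U(i: int) -> float:
        def f(v):
            G2 = -np.expm1(c * np.log1p(-v))
            return ((1.0 - G2) * (1.0 + G2)) ** th2 * G2 ** (2 * i) * h1(v)

        split = 0.5 if i == 0 else 1.0 - 1.0 / (2 * i + 2)
        v1, _ = integrate.quad(f, 0.0, split, limit=200)
        v2, _ = integrate.quad(f, split, 1.0, limit=200)
        return v1 + v2

    s = _sum_single_series(
        U, lambda i: special.binom(i + th2 - 1, i) * (1.0 - th2) ** i, cfg
    )
    return 1.0 - s
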