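"""Goodness-of-fit statistics and multi-model comparison reports.

Three classical EDF statistics are computed on the probability-integral
transforms u_i = F(x_(i)) of the fitted CDF:

* Kolmogorov-Smirnov: ``max_i max(i/n - u_i, u_i - (i-1)/n)``
* Cramer-von Mises:   ``1/(12n) + sum (u_i - (2i-1)/(2n))^2``
* Anderson-Darling:   ``-n - (1/n) sum (2i-1)[log u_i + log(1 - u_{n+1-i})]``

plus the likelihood criteria AIC = 2k - 2l and BIC = k log n - 2l.  All
statistics are evaluated at the ML estimate, uncorrected for parameter
estimation (no p-values).

The comparison set covers the NEITL model, its one-parameter ITL baseline
(closed-form MLE), and the Weibull and exponentiated-exponential lifetime
workhorses via scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import LifetimeSample
from .distributions import NEITLParams, neitl_cdf
from .estimation import FitResult, fit_mle

__all__ = [
    "GofReport",
    "ks_stat",
    "cvm_stat",
    "ad_stat",
    "information_criteria",
    "compare_models",
    "SUPPORTED_MODELS",
]


def _pit(s, cdf) -> np.ndarray:
    x = s.values if isinstance(s, LifetimeSample) else np.asarray(s, dtype=float)
    return np.asarray(cdf(np.sort(x)), dtype=float)


def ks_stat(s, cdf) -> float:
    """Two-sided one-sample Kolmogorov-Smirnov sup-distance."""
    u = _pit(s, cdf)
    n = u.size
    i = np.arange(1, n + 1)
    return float(max((i / n - u).max(), (u - (i - 1) / n).max()))


def cvm_stat(s, cdf) -> float:
    """Cramer-von Mises W^2."""
    u = _pit(s, cdf)
    n = u.size
    i = np.arange(1, n + 1)
    return float(1.0 / (12 * n) + np.sum((u - (2 * i - 1) / (2 * n)) ** 2))


def ad_stat(s, cdf) -> float:
    """Anderson-Darling A^2; requires 0 < u_i < 1 for every order statistic."""
    u = _pit(s, cdf)
    n = u.size
    bad = np.flatnonzero((u <= 0) | (u >= 1))
    if bad.size:
        raise ValueError(
            f"probability integral transform hits {{0,1}} at sorted index {bad[0]}"
        )
    i = np.arange(1, n + 1)
    return float(-n - np.sum((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))) / n)


def information_criteria(fit) -> dict:
    """AIC and BIC from a fit carrying (k, loglik, n)."""
    if isinstance(fit, FitResult):
        k, loglik, n = 2, fit.objective, fit.n
    else:
        k, loglik, n = fit["k"], fit["loglik"], fit["n"]
    return {"AIC": 2 * k - 2 * loglik, "BIC": k * np.log(n) - 2 * loglik}


# ---------------------------------------------------------------------------
# Model registry


def _fit_neitl(x: np.ndarray):
    res = fit_mle(x)
    return {
        "params": dict(zip(("theta", "delta"), res.params.as_tuple())),
        "se": dict(zip(("theta", "delta"), res.std_errors)),
        "k": 2,
        "loglik": res.objective,
        "n": int(res.n),
        "cdf": lambda t, p=res.params: neitl_cdf(t, p),
    }


def _fit_itl(x: np.ndarray):
    # closed-form MLE: dl/ddelta = n/delta + sum log(1+2x) - 2 sum log(1+x) = 0
    n = x.size
    denom = 2 * np.log1p(x).sum() - np.log1p(2 * x).sum()
    delta = n / denom
    loglik = (
        n * np.log(2 * delta)
        + np.log(x).sum()
        + (delta - 1) * np.log1p(2 * x).sum()
        - (2 * delta + 1) * np.log1p(x).sum()
    )
    return {
        "params": {"delta": delta},
        "se": {"delta": delta / np.sqrt(n)},  # observed information n/delta^2
        "k": 1,
        "loglik": float(loglik),
        "n": int(n),
        "cdf": lambda t, d=delta: -np.expm1(d * np.log1p(2 * np.asarray(t, float)) - 2 * d * np.log1p(np.asarray(t, float))),
    }


def _fit_weibull(x: np.ndarray):
    shape, loc, scale = sps.weibull_min.fit(x, floc=0)
    loglik = float(np.sum(sps.weibull_min.logpdf(x, shape, 0, scale)))
    return {
        "params": {"shape": shape, "scale": scale},
        "se": {},
        "k": 2,
        "loglik": loglik,
        "n": int(x.size),
        "cdf": lambda t: sps.weibull_min.cdf(t, shape, 0, scale),
    }


def _fit_expexp(x: np.ndarray):
    # exponentiated exponential: CDF (1 - exp(-x/scale))^a == exponweib with c=1
    a, c, loc, scale = sps.exponweib.fit(x, fc=1, floc=0)
    loglik = float(np.sum(sps.exponweib.logpdf(x, a, 1, 0, scale)))
    return {
        "params": {"alpha": a, "rate": 1.0 / scale},
        "se": {},
        "k": 2,
        "loglik": loglik,
        "n": int(x.size),
        "cdf": lambda t: sps.exponweib.cdf(t, a, 1, 0, scale),
    }


SUPPORTED_MODELS = {
    "neitl": _fit_neitl,
    "itl": _fit_itl,
    "weibull": _fit_weibull,
    "expexp": _fit_expexp,
}


@dataclass
class GofReport:
    """Per-model statistics table with per-criterion winners."""

    label: str
    table: pd.DataFrame
    best_model: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def to_csv(self, path):
        self.table.to_csv(path)

    def __str__(self):
        lines = [f"Goodness of fit: {self.label}", self.table.to_string()]
        if self.best_model:
            lines.append(
                "best per criterion: "
                + ", ".join(f"{k}={v}" for k, v in self.best_model.items())
            )
        if self.failures:
            lines.append(f"failed fits: {sorted(self.failures)}")
        return "\n".join(lines)


def compare_models(s, models=("neitl", "itl", "weibull", "expexp")) -> GofReport:
    """Fit each model by ML and assemble the statistics table.

    Per-model failures are recorded in the report rather than raised.
    """
    if not models:
        raise ValueError("need at least one model")
    sample = s if isinstance(s, LifetimeSample) else LifetimeSample(s)
    x = sample.values
    rows = {}
    failures = {}
    for name in models:
        try:
            fitinfo = SUPPORTED_MODELS[name](x)
        except KeyError:
            raise ValueError(
                f"unsupported model {name!r}; choose from {sorted(SUPPORTED_MODELS)}"
            ) from None
        except Exception as exc:  # registry fit failures are reported, not fatal
            failures[name] = repr(exc)
            continue
        ic = information_criteria(fitinfo)
        rows[name] = {
            "params": "; ".join(f"{k}={v:.4f}" for k, v in fitinfo["params"].items()),
            "KS": ks_stat(sample, fitinfo["cdf"]),
            "CVM": cvm_stat(sample, fitinfo["cdf"]),
            "AD": ad_stat(sample, fitinfo["cdf"]),
            "AIC": ic["AIC"],
            "BIC": ic["BIC"],
            "loglik": fitinfo["loglik"],
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    best = {}
    if len(table):
        for crit in ("KS", "CVM", "AD", "AIC", "BIC"):
            best[crit] = table[crit].idxmin()
    return GofReport(label=sample.label, table=table, best_model=best, failures=failures)
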