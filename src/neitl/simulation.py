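"""Monte Carlo harness for bias/MSE/interval-length studies.

Each cell draws ``n_rep`` samples from a known NEITL truth, fits them by
the requested methods, and aggregates per quantity:

* ``mean_estimate`` (the "AE" column in the average-estimate reading),
* ``bias`` (the average-bias reading; both are emitted),
* ``mse``,
* ``mean_ci_length`` (Wald for ML/MPS, equal-tailed credible for Bayes).

Fits inside a cell are *local*, started from the data-generating values
(``start_at_truth=True``, the default): the reference study design this
harness reproduces measures the performance of locally optimised
estimators, which matters here because weakly identified corners of the
parameter space (small theta*delta) carry long likelihood ridges on which
a global search would wander arbitrarily far.  Set ``start_at_truth=False``
to use the production multi-start fits instead.

Besides the two shape parameters, the survival and hazard functions are
tracked at the *true quantiles* of the levels in ``q_levels``: the time
grid is x_q = Q(q; truth), so the true survival value at level q is
exactly 1 - q.  (Evaluating at a literal time q instead would make the
tracked survival values pile up near 1 for diffuse parameter settings and
would not reproduce the reference study's reliability columns.)

Replicates whose fits fail are dropped and counted; a cell with more than
5% failures is flagged.  Bayes cells run shortened chains (2000 draws, 500
burn-in) to keep a desk-scale grid affordable; chain length is a knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import LifetimeSample
from .distributions import NEITLParams, _neitl_rvs_array, neitl_quantile
from .estimation import (
    NonConvergenceError,
    PriorSpec,
    asymptotic_ci,
    bayes_fit,
    fit_mle,
    fit_mps,
    sf_hf_at_time,
)
from .stress_strength import SSDesign, fit_ss, ss_reliability

__all__ = ["SimCell", "SimSummary", "run_cell", "run_ss_cell", "format_table"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class SimCell:
    """One simulation configuration.

    For single-sample cells ``true_params`` is one NEITLParams and ``m`` is
    None; for stress-strength cells it is a (strength, stress) pair and
    ``m`` is the stress-sample size.
    """

    true_params: NEITLParams | tuple[NEITLParams, NEITLParams]
    n: int
    n_rep: int = 500
    m: int | None = None
    methods: tuple[str, ...] = ("ML", "MPS", "Bayes")
    q_levels: tuple[float, ...] = (0.25, 0.35)
    seed: int = 0
    bayes_iter: int = 2_000
    bayes_burn: int = 500
    prior: PriorSpec | None = None
    start_at_truth: bool = True

    def __post_init__(self):
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        for q in self.q_levels:
            if not 0 < q < 1:
                raise ValueError("q_levels must lie in (0, 1)")


@dataclass
class SimSummary:
    """Aggregated results: records[method][quantity] -> summary dict."""

    cell: SimCell
    true_values: dict
    records: dict
    n_failed: dict
    flagged: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, quants in self.records.items():
            for qty, rec in quants.items():
                rows.append(
                    {
                        "n": self.cell.n,
                        "m": np.nan if self.cell.m is None else self.cell.m,
                        "method": method,
                        "quantity": qty,
                        "true": self.true_values.get(qty, np.nan),
                        **rec,
                    }
                )
        return pd.DataFrame(rows)


def _sf_hf_many(x: float, thetas: np.ndarray, deltas: np.ndarray):
    """Vectorised SF/HF at scalar time x over arrays of parameters."""
    k = np.log1p(2 * x) - 2 * np.log1p(x)
    la = deltas * k
    A = np.exp(la)
    G = -np.expm1(la)
    logsf = thetas * (la + np.log(2 - A) - np.log1p((thetas - 1) * G * G))
    logpdf = (
        np.log(4 * thetas**2 * deltas)
        + np.log(x)
        + (deltas - 1) * np.log1p(2 * x)
        - (2 * deltas + 1) * np.log1p(x)
        + np.log(G)
        + (thetas - 1) * (la + np.log(2 - A))
        - (thetas + 1) * np.log1p((thetas - 1) * G * G)
    )
    return np.exp(logsf), np.exp(logpdf - logsf)


def _aggregate(est: np.ndarray, lengths: np.ndarray, truth: float) -> dict:
    errs = est - truth
    sq = errs**2
    mse = float(sq.mean())
    mc_se = float(sq.std(ddof=1) / np.sqrt(sq.size)) if sq.size > 1 else np.nan
    ok = lengths[np.isfinite(lengths)]
    return {
        "mean_estimate": float(est.mean()),
        "bias": float(errs.mean()),
        "mse": mse,
        "mse_mc_se": mc_se,
        "mean_ci_length": float(ok.mean()) if ok.size else np.nan,
    }


def run_cell(cell: SimCell) -> SimSummary:
    """Run a single-sample cell; deterministic given ``cell.seed``."""
    truth = cell.true_params
    if not isinstance(truth, NEITLParams):
        raise TypeError("run_cell expects a single NEITLParams truth; see run_ss_cell")
    x_eval = {q: neitl_quantile(q, truth) for q in cell.q_levels}
    true_vals = {"theta": truth.theta, "delta": truth.delta}
    for q, xq in x_eval.items():
        sf, hf = _sf_hf_many(xq, np.array([truth.theta]), np.array([truth.delta]))
        true_vals[f"R@{q:g}"] = float(sf[0])
        true_vals[f"H@{q:g}"] = float(hf[0])

    quantities = list(true_vals)
    store = {
        method: {qty: ([], []) for qty in quantities} for method in cell.methods
    }
    n_failed = {method: 0 for method in cell.methods}
    children = np.random.SeedSequence(cell.seed).spawn(cell.n_rep)
    for child in children:
        rng = np.random.default_rng(child)
        sample = LifetimeSample(_neitl_rvs_array(cell.n, truth, rng))
        ml = None
        for method in cell.methods:
            try:
                est, lengths = _one_fit(
                    method, sample, x_eval, cell, rng, truth=truth, ml_hint=ml
                )
                if method == "ML":
                    ml = est.get("_fit")
            except (NonConvergenceError, FloatingPointError, ValueError):
                n_failed[method] += 1
                continue
            for qty in quantities:
                store[method][qty][0].append(est[qty])
                store[method][qty][1].append(lengths.get(qty, np.nan))

    records = {}
    for method in cell.methods:
        records[method] = {}
        for qty in quantities:
            vals, lens = store[method][qty]
            if not vals:
                continue
            records[method][qty] = _aggregate(
                np.asarray(vals), np.asarray(lens), true_vals[qty]
            )
    flagged = any(k > 0.05 * cell.n_rep for k in n_failed.values())
    return SimSummary(cell, true_vals, records, n_failed, flagged)


def _one_fit(method, sample, x_eval, cell, rng, truth=None, ml_hint=None):
    """Fit one replicate by one method; returns (estimates, ci_lengths)."""
    est, lengths = {}, {}
    local = cell.start_at_truth and truth is not None
    if method in ("ML", "MPS"):
        if method == "ML":
            if local:
                fit = fit_mle(sample, starts=[truth], include_default_starts=False)
            else:
                fit = fit_mle(sample, n_grid=3)
        else:
            if local:
                fit = fit_mps(sample, starts=[truth], include_ml_seed=False)
            else:
                fit = fit_mps(sample, ml_result=ml_hint)
        est["theta"], est["delta"] = fit.params.as_tuple()
        est["_fit"] = fit
        try:
            ci_t, ci_d = asymptotic_ci(fit)
            lengths["theta"], lengths["delta"] = ci_t.length, ci_d.length
        except NonConvergenceError:
            pass
        for q, xq in x_eval.items():
            rec = sf_hf_at_time(fit, xq)
            est[f"R@{q:g}"], est[f"H@{q:g}"] = rec["R"], rec["H"]
            if rec["ci_R"] is not None:
                lengths[f"R@{q:g}"] = rec["ci_R"].length
            if rec["ci_H"] is not None:
                lengths[f"H@{q:g}"] = rec["ci_H"].length
        return est, lengths
    if method.upper() == "BAYES":
        if local:
            start = truth
        else:
            start = ml_hint.params if ml_hint is not None else None
        prior = cell.prior
        if prior is None and local:
            # study convention: gamma priors centred on the data-generating
            # values with unit coefficient of variation (shape 1, rate 1/truth)
            prior = PriorSpec(1.0, 1.0 / truth.theta, 1.0, 1.0 / truth.delta)
        draws = bayes_fit(
            sample,
            prior=prior,
            n_iter=cell.bayes_iter,
            burn_in=cell.bayes_burn,
            seed=rng,
            start=start,
        )
        th, de = draws.theta, draws.delta
        est["theta"], est["delta"] = float(th.mean()), float(de.mean())
        ci_t, ci_d = draws.credible_interval()
        lengths["theta"], lengths["delta"] = ci_t.length, ci_d.length
        for q, xq in x_eval.items():
            sf, hf = _sf_hf_many(xq, th, de)
            est[f"R@{q:g}"], est[f"H@{q:g}"] = float(sf.mean()), float(hf.mean())
            lengths[f"R@{q:g}"] = float(np.diff(np.quantile(sf, [0.025, 0.975]))[0])
            lengths[f"H@{q:g}"] = float(np.diff(np.quantile(hf, [0.025, 0.975]))[0])
        return est, lengths
    raise ValueError(f"unknown method {method!r}")


def run_ss_cell(cell: SimCell) -> SimSummary:
    """Run a stress-strength cell with truth (params1, params2) and sizes (n, m)."""
    if isinstance(cell.true_params, NEITLParams) or len(cell.true_params) != 2:
        raise TypeError("run_ss_cell expects a (strength, stress) parameter pair")
    if cell.m is None:
        raise ValueError("stress-strength cells need the stress sample size m")
    p1, p2 = cell.true_params
    true_R = ss_reliability(p1, p2)
    true_vals = {
        "theta1": p1.theta, "delta1": p1.delta,
        "theta2": p2.theta, "delta2": p2.delta,
        "R": true_R,
    }
    quantities = list(true_vals)
    store = {m: {q: ([], []) for q in quantities} for m in cell.methods}
    n_failed = {m: 0 for m in cell.methods}
    children = np.random.SeedSequence(cell.seed).spawn(cell.n_rep)
    for child in children:
        rng = np.random.default_rng(child)
        s1 = LifetimeSample(_neitl_rvs_array(cell.n, p1, rng))
        s2 = LifetimeSample(_neitl_rvs_array(cell.m, p2, rng))
        design = SSDesign(s1, s2)
        for method in cell.methods:
            try:
                if cell.start_at_truth and method in ("ML", "MPS"):
                    ss = _local_ss_fit(design, method, (p1, p2))
                else:
                    ss = fit_ss(
                        design,
                        method=method,
                        prior=cell.prior,
                        n_iter=cell.bayes_iter,
                        burn_in=cell.bayes_burn,
                        seed=rng,
                    )
            except (NonConvergenceError, FloatingPointError, ValueError):
                n_failed[method] += 1
                continue
            est = {
                "theta1": ss.fit1.params.theta, "delta1": ss.fit1.params.delta,
                "theta2": ss.fit2.params.theta, "delta2": ss.fit2.params.delta,
                "R": ss.R_hat,
            }
            lengths = {"R": ss.interval.length if ss.interval else np.nan}
            for fit, names in ((ss.fit1, ("theta1", "delta1")), (ss.fit2, ("theta2", "delta2"))):
                try:
                    ci_t, ci_d = asymptotic_ci(fit)
                    lengths[names[0]], lengths[names[1]] = ci_t.length, ci_d.length
                except NonConvergenceError:
                    pass
            for qty in quantities:
                store[method][qty][0].append(est[qty])
                store[method][qty][1].append(lengths.get(qty, np.nan))
    records = {}
    for method in cell.methods:
        records[method] = {}
        for qty in quantities:
            vals, lens = store[method][qty]
            if not vals:
                continue
            records[method][qty] = _aggregate(
                np.asarray(vals), np.asarray(lens), true_vals[qty]
            )
    flagged = any(k > 0.05 * cell.n_rep for k in n_failed.values())
    return SimSummary(cell, true_vals, records, n_failed, flagged)


def _local_ss_fit(design, method, truths):
    """Truth-started local two-sample fit (simulation design; see module docs)."""
    from .stress_strength import SSFit, _delta_method_interval

    fits = []
    for sample, truth in zip((design.strength_sample, design.stress_sample), truths):
        if method == "ML":
            fits.append(fit_mle(sample, starts=[truth], include_default_starts=False))
        else:
            fits.append(fit_mps(sample, starts=[truth], include_ml_seed=False))
    R = ss_reliability(fits[0].params, fits[1].params)
    interval = _delta_method_interval(fits[0], fits[1], R, 0.95)
    return SSFit(method, R, fits[0], fits[1], interval)


def format_table(summaries) -> pd.DataFrame:
    """Long-format table (one row per cell x method x quantity).

    An empty collection yields a header-only frame; the result round-trips
    through CSV.
    """
    frames = [s.to_frame() for s in summaries]
    columns = [
        "n", "m", "method", "quantity", "true",
        "mean_estimate", "bias", "mse", "mse_mc_se", "mean_ci_length",
    ]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]
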