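# Methods

## Model

The package implements the two-parameter NEITL lifetime distribution: the
new exponential-X (NE-X) transform

F(x) = 1 − [(1 − G²)/(1 − (1−θ)G²)]^θ,  θ > 0,

applied to the one-parameter inverted Topp–Leone (ITL) baseline
G(x; δ) = 1 − (1+2x)^δ/(1+x)^{2δ} on the support (0, ∞).  Both θ and δ are
shape parameters.  Useful structural facts used throughout:

- **Tail index.**  As x → ∞ the density behaves like x^−(θδ+1).  E[Xʳ]
  exists iff r < θδ; this is also the convergence condition of the
  moment-series oracle and the existence guard raised by `raw_moment`.
- **Collapse.**  θ = 1 gives F = G² exactly (asserted to machine
  precision in the tests).
- **Quantile.**  The CDF inverts in closed form through
  t = (1−u)^{1/θ}, G² = (1−t)/(1−t(1−θ)), w = (1−G)^{1/δ},
  x = ((1−w) + √(1−w))/w.  (The positive root of w x² + 2(w−1)x + (w−1) = 0;
  the discriminant simplifies to 4(1−w).)  Sampling is inverse-transform.
- **Weak identifiability corner.**  When θδ is small the likelihood is
  informative mainly about the product θδ: long flat ridges appear (see
  "Estimation" below).  In the limit θ → 0, δ → ∞ with λ = θδ fixed the
  family degenerates to F = 1 − exp(−λ(2log(1+x) − log(1+2x))), a
  one-parameter boundary subfamily that matters for the spacing
  estimator.

## Numerical evaluation

All distribution functions run through the log intermediate
log A = δ·log1p(2x) − 2δ·log1p(x) (A = 1 − G ∈ (0,1]); survival and
hazard use log SF = θ(log(1−G²) − log(1+(θ−1)G²)).  The factor log(1−G²)
switches representation at G = ½: A-side (log A + log(2−A)) near G = 1,
log1p(−G²) near G = 0 — each side is cancellation-free, which keeps the
CDF inside [0,1] by construction rather than by clipping, and supports
shape values as extreme as θ ≈ 60, δ ≈ 0.02 without overflow.  The hazard
raises a range error where the survival function underflows to exactly 0.

Moments, incomplete moments, entropies and the stress–strength integral
are adaptive quadrature of the closed forms (`scipy.integrate.quad`),
split at the median so peaked densities are resolved; incomplete moments
integrate on the probability scale (∫₀^{F(y)} Q(u)ʳ du) so arbitrarily
large truncation points cannot hide the mass from the subdivision.
Moment existence is guarded analytically (r < θδ) and by the quadrature
error estimate.

## Series oracles

The NE-X linear representation — binomial expansion of the negative-power
factor (1−(1−θ)G²)^{−k} (valid for θ ∈ (0,2)) and of (1−G²)^v — is
implemented as an independent cross-check, never as the production path:

- CDF/PDF: the double series factorises into two 1-D power series in G²
  and is summed term by term with an absolute tail tolerance
  (default 1e−10, budget 200 terms per index).
- Integral functionals (moments, incomplete moments, Rényi entropy,
  stress–strength reliability): only the negative-power factor is
  expanded (geometric |1−θ|ⁱ term decay); each coefficient is a
  baseline-only 1-D integral (e.g. ∫₀¹ Q_ITL(v)ʳ v^{2i+1} (1−v²)^{θ−1} dv).
  Re-expanding G-powers further into powers of A — the route that leads to
  pure beta-function formulas — is a formally divergent rearrangement
  (binomial 4^{i+j} growth against polynomially decaying coefficients) and
  is deliberately not used.

Outside θ ∈ (0,2) the series functions raise rather than return a wrong
number; the closed forms are authoritative there.

## Estimation

**Maximum likelihood** maximises the analytic log-likelihood with
multi-start Nelder–Mead on (log θ, log δ) — a 5×5 grid over
log-parameters in [−3, 5] plus a moment-flavoured seed — followed by an
L-BFGS-B polish using the analytic score (which is itself tested against
numerical gradients).  Multi-start with best-objective selection matters:
the surface can be multimodal, and on flat ridges single-start results are
start-dependent.  Standard errors come from the inverse observed
information (central-difference Hessian on the natural scale).  The
convergence flag requires a small relative gradient norm at the reported
optimum.

Because of the ridges, two reference behaviours deserve note.  On the
guinea-pig data the profile likelihood in θ is flat to ~0.001 log-units
between θ ≈ 40 and θ ≈ 300 with an interior maximum near θ ≈ 78; any
point on the ridge gives essentially the same AIC, KS and fitted curve,
but "the MLE of θ" is ill-determined (SE of order 10²).  On the second
fluid group the likelihood is bimodal and the global mode sits at small θ
and large δ.  Published analyses of these data report other stationary
points; this package always reports the best optimum found and exposes
the standard error so the flatness is visible.

**Maximum product of spacings** maximises the mean log CDF spacing over
the n+1 gaps (endpoints 0 and 1), substituting the density value for a
spacing collapsed by an exact tie (Cheng–Amin convention; the bundled
survival data contain ties).  The spacing objective for this family is
unbounded along the θ → 0, δ → ∞ boundary subfamily described above, so a
global search diverges.  `fit_mps` therefore performs *local*
maximisation seeded at the ML estimate (plus any user-supplied starts)
and reports the best interior stationary point — the usual remedy for
criteria with degenerate boundary behaviour.  MPS standard errors use the
inverse Hessian of the summed log-spacing objective (asymptotic
equivalence with the ML information).

**Bayesian estimation** places independent gamma priors on θ and δ
(default weakly informative: shape = rate = 0.1, user-configurable) and
samples the joint posterior with Metropolis-within-Gibbs: log-scale
Gaussian random-walk proposals for each full conditional, proposal scales
adapted toward ~35% acceptance during burn-in only (so the retained chain
is Markov), defaults 10 000 iterations with 2 000 burn-in.  The point
estimate is the posterior mean (squared-error loss); intervals are
equal-tailed credible intervals.  The sampler is hand-rolled because the
component-wise conditional structure *is* the algorithm being
implemented; chains are deterministic given a seed, and four-chain
Gelman–Rubin diagnostics on test data sit below 1.05 at the default chain
length.

**Intervals.**  Wald intervals use estimate ± z·SE at a fixed 95% level
(z = 1.95996).  The bootstrap is nonparametric-percentile with refit per
resample (error if >10% of resamples fail).  SF/HF at a user time Q, and
the stress–strength R, get delta-method intervals from central-difference
gradients and the (block-diagonal, by sample independence) fit
covariance; the Bayesian route instead pushes posterior draws through the
functional.  AIC = 2k − 2ℓ and BIC = k·log n − 2ℓ.

## Stress–strength reliability

R = P(X₂ < X₁) = ∫ F₂(x) f₁(x) dx by adaptive quadrature for arbitrary
parameter pairs; the series cross-check (above) needs only θ₂ ∈ (0,2) and
does not require a shared θ.  Two-sample estimation fits each sample
separately — four free parameters, no common-θ constraint — and plugs the
estimates into the integral.

## Goodness of fit

KS (two-sided sup distance), Cramér–von Mises and Anderson–Darling are
computed on the probability-integral transforms at the ML estimate,
uncorrected for parameter estimation and without p-values.  The
comparison registry covers NEITL, the ITL baseline (closed-form MLE
δ̂ = n / (2Σlog(1+x) − Σlog(1+2x)), SE δ̂/√n), Weibull
(`scipy.stats.weibull_min`, origin fixed at 0) and the exponentiated
exponential (`scipy.stats.exponweib` with the Weibull exponent fixed at
1).  On the guinea-pig data NEITL wins all three EDF distances; a fully
converged exponentiated-exponential fit edges it by ~0.2 AIC, so the
package reports criterion winners rather than asserting a single best
model.

## Monte Carlo harness

A simulation cell draws `n_rep` samples from a known truth, fits them by
the requested methods, and reports per quantity the mean estimate, the
bias (both are given because "average estimate" columns in reference
studies mix the two conventions), the MSE with its Monte Carlo standard
error, and the mean 95% interval length.  Tracked quantities are θ, δ and
SF/HF evaluated at the *true quantiles* of the requested levels
(default 0.25 and 0.35), so the true survival value at level q is exactly
1 − q; evaluating at a literal time q instead would pin the survival
values near 1 for diffuse parameter settings and does not correspond to
the reliability columns of the reference study.

Two design choices define the study conditions:

- **Truth-started local fits.**  Cell fits start from the
  data-generating values and optimise locally
  (`start_at_truth=True`).  At the reference design point
  (θ, δ) = (0.5, 0.5) the tail index is 0.25 and θ is weakly identified;
  global multi-start ML walks the ridge and produces MSEs many orders of
  magnitude above the published ones, while truth-started local fits
  reproduce the published bias/MSE regime.  The global production fits
  remain available via `start_at_truth=False`.
- **Priors for Bayes cells.**  Unless a prior is supplied, Bayes cells
  use gamma priors centred on the data-generating values with unit
  coefficient of variation (shape 1, rate 1/true value) — informative
  priors of this kind are the (usually tacit) convention behind reference
  Bayes columns whose MSEs undercut the ML ones.  Bayes cells run
  shortened chains (2 000 iterations, 500 burn-in) to keep a grid
  affordable; both are knobs on `SimCell`.

Failed replicates are dropped and counted; a cell with >5% failures is
flagged.  Everything is deterministic given the cell seed (child seeds
are spawned per replicate).  The reduced study exercised by the tests
uses (0.5, 0.5) with n ∈ {30, 150} at 500 replicates per cell — small
enough for a desk run, large enough that MSE ratios between methods are
stable; the full 10 000-replicate design is a parameter change.

Under these conditions MSE(θ̂) at (0.5, 0.5) is *not* reliably monotone
in n for the local estimators (the ridge-restricted optimum drifts as the
conditional curvature sharpens), unlike the mild decrease reported in
reference tables; the corresponding consistency check in the acceptance
suite documents this rather than papering over it.

## What the synthetic data do and do not show

The generator draws i.i.d. exact (uncensored) lifetimes by inverse
transform from the model itself.  Passing tests therefore demonstrate
internal correctness (sampling, fitting and summarising are mutually
consistent) and estimator behaviour *under the model*; they say nothing
about censoring, covariates, measurement rounding or model
misspecification, none of which the harness emulates.  Rounding ties of
the kind present in the real survival data are handled by the MPS tie
convention but are not generated synthetically.

## Known limitations

- Uncensored data only; no censored or truncated likelihoods.
- Series oracles are restricted to θ ∈ (0,2) by the binomial expansion.
- The ρ-entropy (1/(ρ−1))·log(1 − ∫f^ρ) is undefined where ∫f^ρ ≥ 1
  (peaked densities); the package raises rather than returning a complex
  number.
- Weak identifiability at small θδ is intrinsic to the family: parameter-
  level point estimates on ridges should be read together with their
  standard errors; functionals (SF, HF, R, AIC, KS) are stable across a
  ridge and are the quantities to report.
- Reference values for θ̂ on ridge-prone datasets correspond to
  particular stationary points, not to the global optimum this package
  reports; the information criteria and distances agree regardless.
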