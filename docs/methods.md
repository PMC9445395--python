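# Methods

## Model

A nonnegative variable `y` follows the delta-lognormal distribution
`g(y; p0, mu, sigma2) = p0*delta(y) + (1-p0)*f(y; mu, sigma2)`: exact zeros
with probability `p0`, lognormal positives otherwise. Zeros are structural
observations (an empty tow), not censored small values, so the package
treats a value as zero iff it equals `0.0` exactly. The cumulants follow
from `alpha = exp(mu + sigma2/2)`, `beta = exp(sigma2)`:

    kappa1 = q*alpha                      q = 1 - p0
    kappa2 = q*alpha^2*(beta - q)
    kappa3 = q*alpha^3*(beta^3 - 3q*beta + 2q^2)
    gamma1 = kappa3 / kappa2^(3/2)

`gamma1` grows explosively in `sigma2` (about 64.5 already at `p0 = 0.9`,
`sigma2 = 2`), which is why plain sample means are noisy and the UMVU
route pays off.

Two inferential settings share the same estimator. *Estimation*: the data
are an iid sample from the (super)population and the target is `kappa1`.
*Prediction*: a finite population of `N` units is itself a draw from the
superpopulation; a sample of `n` units is observed through an ignorable
selection mechanism, and the target is the realised total `t_U` (or mean),
predicted by `sum_s y + (N-n)*Ehat(y)` under the homogeneous mean model
(equal means and variances, no correlation). Because the predictor uses
sampled units only, prediction error variances decompose with zero
covariance.

## Estimators

With `n1` positives, `ybar_ln`, `s2_ln` the mean/unbiased variance of the
log positives, `a = (n1-1)/2` and `qhat = n1/n`:

    kappa1_hat = qhat * exp(ybar_ln) * 0F1(a; (n1-1)^2 s2_ln/(4 n1))
    kappa2_hat = qhat * exp(2 ybar_ln) * [0F1(a; (n1-1)^2 s2_ln/n1)
                  - (n1-1)/(n-1) * 0F1(a; (n1-1)(n1-2) s2_ln/(2 n1))]
    Vhat       = kappa1_hat^2 - qhat * exp(2 ybar_ln)
                  * (n1-1)/(n-1) * 0F1(a; (n1-1)(n1-2) s2_ln/(2 n1))

with branches `y_s1/n`, `y_s1^2/n`, `(y_s1/n)^2` at `n1 = 1` and zeros at
`n1 = 0`. The `0F1` form is algebraically identical to the older Finney
`g_m(t)` form (`g_m(t) = 0F1(m/2; m^2 t/(2(m+1)))`); both are implemented
and the suite checks they agree to 1e-10.

The exact variance of `kappa1_hat` conditions on the binomial count of
positives:

    V = alpha^2 * [ (1/n^2) * sum_{j=2}^{n} C(n,j) q^j p0^(n-j)
        * j^2 * exp(sigma2/j) * 0F1((j-1)/2; ((j-1)^2/(4j^2)) sigma2^2)
        - q^2 ]

Reading notes that matter: the factor is `exp(sigma2/j)` (not
`exp(sigma2*j)`), and the first-order `1/n` expansion of this sum is
exactly the closed-form approximation

    Vapp = (1/n) * q * [p0 + sigma2*(sigma2+2)/2] * exp(2 mu + sigma2),

which the package also provides (`approx_variance_umvue`).

**The `j = 1` term.** The standard printed form of the sum starts at
`j = 2`, omitting the contribution of samples with a single positive (whose
conditional second moment is `exp(2 mu + 2 sigma2)/n^2`, i.e. the `j = 1`
term with the `0F1(0;0) = 1` convention). The omission only matters when
`p0^(n-1)` is non-negligible: at `p0 = 0.9`, `n = 50` it shifts `V` from
61.8555 to 62.54 (about 1.1%), elsewhere on the studied grids it is
invisible. The default is the printed `j >= 2` form, which reproduces the
published reference table to 4 d.p.; `include_singleton_term=True` adds the
term, and the flag is plumbed through `eff1`, `eff2` and `GridSpec`.

Relative efficiencies: `eff1 = n*V/kappa2` and
`eff2 = n*((N-n)*V + kappa2)/(N*kappa2)`; both are invariant to `mu`
(`alpha^2` cancels) and `eff2 -> eff1` as `N -> infinity`. Since the UMVUE
is the minimum-variance unbiased estimator, `eff1 < 1`, which also forces
`eff2 > eff1` for finite `N`.

## Series evaluation

`0F1(a; z)` and `g_m(t)` are evaluated by their term-by-term recurrences
(`A_j = A_{j-1} * (1/(a+j-1)) * (z/j)` etc.) in ordinary double precision,
stopping at the first `j` with `|A_j| < epsilon`. Defaults:
`epsilon = 1e-10` (absolute, on the term), `max_terms = 10000` — on the
domain the UMVU formulas need (`0.5 <= a <= 500`, `0 <= z <= 1000`)
convergence takes at most ~100 terms, and exceeding the cap raises a
`SeriesConvergenceError` naming `(a, z)`. Validation anchors: the closed
form `0F1(0.5; z) = cosh(2 sqrt(z))` (absolute error < 1e-12 on
`z = 0.01(0.01)1`, relative error < 1e-12 up to `z = 1000`, where the value
is ~1.4661e27) and a 50-digit mpmath partial-sum oracle for larger `a`.
No log-domain summation is used: double precision suffices on this domain,
and partial sums up to ~1e27 are exact to their last ulp in relative terms.
A vectorised evaluator (`hyp0f1_array`) applies the identical recurrence
element-wise (same multiplication grouping, so scalar and array paths
return bit-identical doubles); it backs the exact-variance sum and the
Monte-Carlo engine. The `a = z = 0` corner returns 1 by the empty-product
convention, which is what the optional `j = 1` variance term needs.

The binomial weights `C(n,j) q^j p0^(n-j)` of the exact-variance sum are
accumulated in log domain via `gammaln` and exponentiated per term — the
direct product overflows near `n = 1000` — and a test pins the two routes
together to 1e-12 for `n <= 60`. `p0 = 0` is handled explicitly (only
`j = n` survives, by the `0^0 = 1` convention). The final subtraction
`inner - q^2` cancels; with the 1e-10 series tolerance the computed `V` is
reliable to roughly 1e-6 in `eff1` units in the worst corner (tiny `sigma`,
where `V` itself is tiny), which is the slack the surface tests use.

## Sampler and Monte-Carlo engine

Each sampled unit consumes exactly two consecutive uniforms from a single
seeded `numpy` Generator stream: a zero indicator (`u < p0`) and a normal
deviate obtained by the inverse CDF (`ndtri`). Consequences: a fixed seed
reproduces any prefix of a sample, and the vectorised Monte-Carlo engine —
which draws `(replicates, n, 2)` blocks — consumes the stream exactly like
repeated scalar `sample()` calls, a property the suite asserts replicate by
replicate. The sampler draws per-unit Bernoulli indicators rather than a
binomial `n1` followed by positives; the two schemes are distributionally
identical.

`mc_validate(params, n, K, seed)` reports the Monte-Carlo mean and variance
of `kappa1_hat` over `K` replicates against `kappa1` and the exact `V`,
plus the same for the per-replicate sample mean (a joint check of the
sampler and of `V(ybar_s) = kappa2/n`). Replicate counts: the full
published protocol uses `K = 1e7-1e8`; the package's tests run the scaled
protocol at `K = 1e6` for the six `(p0, n)` study configurations and
`K = 1e4-2e5` for the remaining unbiasedness checks, sizes chosen so the
whole suite completes in about a minute while leaving comfortable margins
at the tolerances below.

Tolerance policy for stochastic checks: means within 4 Monte-Carlo standard
errors; variances within the wider of 5% or 4 standard errors of the
variance estimate, where that standard error is taken from the fourth
central moment of the replicate stream (`vmc_se`) — these distributions are
skewed enough that the 5% band alone would be too tight at `p0 = 0.9`,
`n = 50` and far too loose elsewhere. One caveat discovered while sizing
the bands: plug-in fourth moments from a *single* sample badly underestimate
the true ones at `sigma = 2`, so the `S^2`-recovery test derives its band
from the model's moments instead.

The prediction harness generates iid populations and takes the first `n`
units as the sample: under an exchangeable iid superpopulation this is
distributionally identical to simple random sampling without replacement
and is an ignorable design.

## What the generator does and does not emulate

The synthetic generator produces exactly the study conditions: iid
delta-lognormal values, exact zeros, parameters in the validated domain
(`p0 <= 0.9`, `sigma <= 2`, i.e. `sigma2 <= 4`, `n <= 1000`; grids beyond
warn). Real survey data violate these assumptions in ways the passing tests
say nothing about: spatial/temporal correlation between tows, catch
heterogeneity (`p0` or `mu` varying with covariates), measurement error in
small catches recorded as zeros, and positive values that are only
approximately lognormal. The UMVUE's optimality and the efficiency surfaces
are statements *within* the model.

## Design choices and known limitations

- **Truncated vs. full variance in the surface studies.** The figure-level
  claims "eff1 decreases in `sigma` and in `n`" and "Vapp/V is closer to 1
  at `n = 1000` than at `n = 50`" are checked on the full (`j >= 1`)
  variance, where they hold everywhere on the studied grids. Under the
  truncated printed sum they fail in the `p0 >= 0.825`, small-`sigma`/`n=50`
  corner (by up to ~6e-3 in eff units) — an artifact of dropping the
  singleton term, not a property of the estimator.
- **Negative variance estimates.** `kappa2_hat` and `Vhat` are unbiased and
  are returned as computed (truncating at zero would destroy unbiasedness),
  with a `negative_variance_warning` flag. Empirically the flag never
  fires: the subtracted `0F1` term always has the smaller argument and
  weight, and no negative value appeared in 72k random samples across wide
  parameter ranges. The flag is kept as a defensive contract.
- **Estimation requires `p0_hat < 1` information content**: all-zero
  samples yield the (unbiased) estimate 0 with zero variance estimate —
  correct but uninformative; users should check `n1`.
- **No maximum-likelihood fitting, confidence intervals, or robustness
  analysis** — the package estimates means and variances, not full
  parametric fits, and assumes the model holds.
- **Iteration counts** of the series depend on where one starts counting;
  the suite only asserts the sane bound (<= 100 terms on the validated
  domain) rather than exact counts.
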