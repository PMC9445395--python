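# deltalognorm

UMVU estimation and finite-population prediction of the mean for
**delta-lognormal** (zero-inflated lognormal) data.

Ecological and fishery survey data — catch per tow, counts per station,
biomass per plot — often contain a large fraction of exact zeros while the
positive values are strongly right-skewed. The standard model for such data
is the delta-lognormal distribution: a value is zero with probability `p0`
and otherwise lognormal,

    g(y; p0, mu, sigma2) = p0 * delta(y) + (1 - p0) * f(y; mu, sigma2),

with `f` the lognormal density of log-location `mu` and log-variance
`sigma2`. Writing `alpha = exp(mu + sigma2/2)` and `beta = exp(sigma2)`,
the mean and variance are

    kappa1 = (1 - p0) * alpha,
    kappa2 = (1 - p0) * alpha^2 * (beta - (1 - p0)).

For such skewed data the sample mean is unbiased but noisy. When the
delta-lognormal shape is known, the **uniformly minimum-variance unbiased
estimator** (UMVUE) of `kappa1` exploits it: with `n1` positive values out
of `n`, log-statistics `ybar_ln` and `s2_ln` over the positives, and the
confluent hypergeometric limit function `0F1(a; z) = sum_j z^j / (j! (a)_j)`,

    kappa1_hat = (1 - n0/n) * exp(ybar_ln)
                 * 0F1( (n1-1)/2 ; (n1-1)^2 s2_ln / (4 n1) )     (n1 > 1),

with the natural conventions `y_s1/n` when `n1 = 1` and `0` when `n1 = 0`.
The package provides, all in terms of hand-evaluated `0F1` series
(equivalently Finney's `g_m(t)`):

- the UMVU estimators of the mean, the variance, and of the estimator's own
  variance;
- the **exact variance** `V(kappa1_hat)` as a binomial mixture of `0F1`
  values, stable up to `n = 10^4`, plus its `O(1/n^2)` closed-form
  approximation;
- model-based **prediction of a finite-population total or mean** (expansion
  predictor `N*ybar_s` vs. UMVU predictor) with prediction-error variances;
- the **relative efficiencies** `eff1 = V(kappa1_hat)/V(ybar_s)` and
  `eff2` (the prediction-error-variance ratio), with grid runners for
  efficiency surfaces over `(p0, sigma, n, N)`;
- a vectorised **Monte-Carlo validation** harness and a reproducible
  delta-lognormal sampler.

Estimators are also exposed as scikit-learn-style classes
(`DeltaLognormalMeanEstimator`, `FinitePopulationTotalPredictor`) with
`fit`, `get_params` and trailing-underscore fitted attributes.

## Worked example

Simulate a survey of 100 stations where 60% of tows are empty and positive
catches are lognormal with `mu = 1.5`, `sigma = 2` (true mean
`kappa1 = 13.25`), then estimate the mean and predict the total over a
1000-station frame:

```sh
$ deltalognorm simulate --p0 0.6 --mu 1.5 --sigma 2 --n 100 --seed 42 --out catch.csv
$ deltalognorm estimate --input catch.csv --digits 6
kappa1_hat = 7.06138
kappa2_hat = 945.611
var_hat_kappa1 = 6.64705
ybar_s = 6.24887
var_hat_ybar_s = 4.25713
$ deltalognorm predict --input catch.csv --pop-size 1000 --digits 6
total_pred = 6980.13
mean_pred = 6.98013
pev_hat_total = 6.23516e+06
pev_hat_mean = 6.23516
```

`kappa1_hat` is the UMVU estimate of the mean with unbiased variance
estimate `var_hat_kappa1`; `ybar_s` is the nonparametric benchmark with its
estimated variance `var_hat_ybar_s`. Both estimates sit below the true mean
13.25: with `sigma = 2` the sampling distributions are themselves strongly
right-skewed, so typical samples undershoot and occasional large catches
compensate — exactly the behaviour that makes variance, not bias, the issue
here. `total_pred` keeps the observed catches and
predicts the unsampled stations by `kappa1_hat`; `pev_hat_*` are estimated
prediction-error variances on the total and mean scales.

How much precision does the distributional shape buy? The efficiency ratio
`eff1` (UMVU variance over sample-mean variance, `mu`-invariant):

```sh
$ deltalognorm efficiency --p0 0.1,0.5,0.9 --sigma 2 --n 50 --digits 6
p0,sigma,n,eff
0.1,2,50,0.252944
0.5,2,50,0.281909
0.9,2,50,0.517494
```

At `p0 = 0.1`, `sigma = 2`, `n = 50` the UMVUE needs a quarter of the
sample-mean variance — equivalently a fourfold smaller sample for the same
precision. The same grids can be run over ranges
(`--p0 0:0.025:0.9 --sigma 0.05:0.05:2`), in the prediction context
(`--context prediction --N 125,250,500,1000`), and for the
exact-vs-approximate variance ratio (`vapp-ratio`). A seeded Monte-Carlo
check of the theory (`deltalognorm validate --p0 0.5 --mu 1.5 --sigma 2
--n 50 --K 100000 --seed 1`) reproduces `kappa1` and `V(kappa1_hat)`
within Monte-Carlo error.

From Python:

```python
from deltalognorm import DeltaLognormalMeanEstimator, read_values

est = DeltaLognormalMeanEstimator().fit(read_values("catch.csv"))
est.kappa1_, est.var_kappa1_
```

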