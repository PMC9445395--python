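"""Superpopulation mean estimation for delta-lognormal data.

Two estimators of the mean kappa1 are provided.

*Sample mean* (shape of the distribution unknown): ybar_s, with sampling
variance kappa2 / n estimated without bias by S^2_s / n.

*UMVUE* (delta-lognormal shape known): partition the sample into the n0
zeros and the n1 positives; with ybar_ln and s2_ln the mean and unbiased
variance of the log positives, the uniformly minimum-variance unbiased
estimator of kappa1 is

    kappa1_hat = (1 - p0_hat) exp(ybar_ln)
                 * 0F1((n1-1)/2; (n1-1)^2 s2_ln / (4 n1))        n1 > 1
               = y_s1 / n                                        n1 = 1
               = 0                                               n1 = 0

(equivalently, via Finney's series, (1 - p0_hat) exp(ybar_ln)
g_{n1-1}(s2_ln / 2)).  Companion UMVU estimators of kappa2 and of the
estimator variance V(kappa1_hat) are single 0F1 combinations with the
same branch structure; they are unbiased but not guaranteed nonnegative
in finite samples, and are returned as computed with a warning flag.

The exact variance of the UMVUE is the binomial mixture sum

    V(kappa1_hat) = alpha^2 [ (1/n^2) sum_{j=2}^{n} C(n,j) (1-p0)^j p0^{n-j}
                    * j^2 exp(sigma2 / j)
                    * 0F1((j-1)/2; ((j-1)^2 / (4 j^2)) sigma2^2)
                    - (1 - p0)^2 ]

whose first-order expansion in 1/n is the closed-form approximation

    Vapp(kappa1_hat) = (1/n) (1-p0) [p0 + sigma2 (sigma2 + 2) / 2]
                       * exp(2 mu + sigma2).

Binomial weights are accumulated in log domain, so the sum is stable up to
n = 10^4 at least.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .distribution import ModelParams, cumulants
from .special import DEFAULT_SETTINGS, SeriesSettings, hyp0f1, hyp0f1_array

__all__ = [
    "SampleSummary",
    "EstimateResult",
    "summarize",
    "sample_mean_estimate",
    "umvue_estimate",
    "exact_variance_umvue",
    "approx_variance_umvue",
    "exact_variance_sample_mean",
    "DeltaLognormalMeanEstimator",
]


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient statistics of a nonnegative sample.

    Log-scale statistics (ybar_ln, s2_ln) are defined only when the sample
    contains at least two positive values; y_singleton holds the unique
    positive value when n1 = 1.
    """

    n: int
    n0: int
    n1: int
    ybar_s: float
    S2_s: float  # raw unbiased sample variance; NaN when n = 1
    ybar_ln: float | None
    s2_ln: float | None
    y_singleton: float | None

    @property
    def p0_hat(self) -> float:
        return self.n0 / self.n


@dataclass(frozen=True)
class EstimateResult:
    """Point estimate of the mean with companion variance estimates.

    kappa2_hat and var_hat_kappa1 are unbiased, not nonnegative: either can
    be negative in finite samples, in which case ``negative_variance_warning``
    is set (values are never truncated, which would destroy unbiasedness).
    """

    kappa1_hat: float
    kappa2_hat: float
    var_hat_kappa1: float
    negative_variance_warning: bool = False


def summarize(values) -> SampleSummary:
    """Compute the sufficient statistics of a sample of nonnegative values."""
    y = np.asarray(values, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty sample")
    neg = np.flatnonzero(y < 0)
    if neg.size:
        raise ValueError(f"negative value {y[neg[0]]} at index {int(neg[0])}")
    n = int(y.size)
    pos = y[y > 0]
    n1 = int(pos.size)
    n0 = n - n1
    ybar_s = float(y.mean())
    S2_s = float(y.var(ddof=1)) if n >= 2 else float("nan")
    ybar_ln = s2_ln = y_singleton = None
    if n1 >= 2:
        logs = np.log(pos)
        ybar_ln = float(logs.mean())
        s2_ln = float(logs.var(ddof=1))
    elif n1 == 1:
        y_singleton = float(pos[0])
    return SampleSummary(
        n=n, n0=n0, n1=n1, ybar_s=ybar_s, S2_s=S2_s,
        ybar_ln=ybar_ln, s2_ln=s2_ln, y_singleton=y_singleton,
    )


def sample_mean_estimate(summary: SampleSummary) -> EstimateResult:
    """Nonparametric estimate: ybar_s with unbiased variance S^2_s / n.

    For n = 1 the point estimate is returned with NaN variance estimates.
    """
    if summary.n < 2:
        return EstimateResult(summary.ybar_s, float("nan"), float("nan"))
    return EstimateResult(
        kappa1_hat=summary.ybar_s,
        kappa2_hat=summary.S2_s,
        var_hat_kappa1=summary.S2_s / summary.n,
    )


def umvue_estimate(
    summary: SampleSummary, settings: SeriesSettings = DEFAULT_SETTINGS
) -> EstimateResult:
    """UMVU estimates of kappa1, kappa2 and V(kappa1_hat) from a summary."""
    n, n1 = summary.n, summary.n1
    if n1 == 0:
        return EstimateResult(0.0, 0.0, 0.0)
    if n1 == 1:
        y1 = summary.y_singleton
        k1 = y1 / n
        return EstimateResult(k1, y1 * y1 / n, k1 * k1)
    q_hat = 1.0 - summary.p0_hat
    ybar, s2 = summary.ybar_ln, summary.s2_ln
    a = (n1 - 1) / 2.0
    f1 = hyp0f1(a, (n1 - 1) ** 2 * s2 / (4.0 * n1), settings)
    f2 = hyp0f1(a, (n1 - 1) ** 2 * s2 / n1, settings)
    f3 = hyp0f1(a, (n1 - 1) * (n1 - 2) * s2 / (2.0 * n1), settings)
    ratio = (n1 - 1) / (n - 1)
    e2y = math.exp(2.0 * ybar)
    k1 = q_hat * math.exp(ybar) * f1
    k2 = q_hat * e2y * (f2 - ratio * f3)
    v1 = q_hat * e2y * (q_hat * f1 * f1 - ratio * f3)
    return EstimateResult(
        kappa1_hat=k1,
        kappa2_hat=k2,
        var_hat_kappa1=v1,
        negative_variance_warning=(k2 < 0) or (v1 < 0),
    )


def _log_binomial_weights(n: int, j: np.ndarray, p0: float) -> np.ndarray:
    """log of C(n, j) (1 - p0)^j p0^{n - j}, with the 0^0 = 1 convention.

    For p0 = 0 only j = n survives; computed explicitly rather than through
    floating-point 0^0.
    """
    if p0 == 0.0:
        return np.where(j == n, 0.0, -np.inf)
    log_comb = gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
    return log_comb + j * math.log1p(-p0) + (n - j) * math.log(p0)


def _binomial_weights_direct(n: int, j: np.ndarray, p0: float) -> np.ndarray:
    """Binomial weights by the iterative product C(n,j) = C(n,j-1)(n-j+1)/j.

    Direct (non-log) route, overflow-prone for large n; kept as an
    independent cross-check of the log-domain weights.
    """
    out = np.empty(j.size)
    comb = 1.0
    k = 0
    for idx, jj in enumerate(j):
        while k < jj:
            k += 1
            comb *= (n - k + 1) / k
        out[idx] = comb * (1.0 - p0) ** jj * p0 ** (n - jj)
    return out


def exact_variance_umvue(
    params: ModelParams,
    n: int,
    settings: SeriesSettings = DEFAULT_SETTINGS,
    include_singleton_term: bool = False,
) -> float:
    """Exact variance of the UMVUE of the mean, via the binomial 0F1 sum.

    The sum runs from j = 2 as printed in the standard formula;
    ``include_singleton_term`` optionally adds the j = 1 contribution
    ``n (1-p0) p0^{n-1} exp(sigma2)`` (using the 0F1(0; 0) = 1 convention),
    which is negligible unless p0^{n-1} is non-tiny.
    """
    if n < 2:
        raise ValueError(f"exact variance requires n >= 2, got n={n}")
    if not (0.0 <= params.p0 < 1.0):
        raise ValueError(f"exact variance requires p0 in [0, 1), got {params.p0}")
    p0, sigma2 = params.p0, params.sigma2
    j = np.arange(2, n + 1, dtype=float)
    logw = _log_binomial_weights(n, j, p0)
    a = (j - 1.0) / 2.0
    z = ((j - 1.0) ** 2 / (4.0 * j * j)) * sigma2 * sigma2
    f = hyp0f1_array(a, z, settings)
    inner = float(np.sum(np.exp(logw + sigma2 / j + 2.0 * np.log(j)) * f)) / (n * n)
    if include_singleton_term and p0 > 0.0:
        inner += math.exp(
            math.log(n) + math.log1p(-p0) + (n - 1) * math.log(p0) + sigma2
        ) / (n * n)
    alpha2 = math.exp(2.0 * params.mu + sigma2)
    return alpha2 * (inner - (1.0 - p0) ** 2)


def approx_variance_umvue(params: ModelParams, n: int) -> float:
    """O(1/n^2)-accurate closed-form approximation of V(kappa1_hat)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p0, sigma2 = params.p0, params.sigma2
    return (
        (1.0 - p0)
        * (p0 + 0.5 * sigma2 * (sigma2 + 2.0))
        * math.exp(2.0 * params.mu + sigma2)
        / n
    )


def exact_variance_sample_mean(params: ModelParams, n: int) -> float:
    """Sampling variance of the sample mean, kappa2 / n."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return cumulants(params).kappa2 / n


class DeltaLognormalMeanEstimator(BaseEstimator):
    """Estimator of the mean of a delta-lognormal superpopulation.

    scikit-learn-style wrapper around :func:`umvue_estimate` /
    :func:`sample_mean_estimate`: ``fit(X)`` consumes a one-dimensional
    sample of nonnegative values (or a single-column 2-D array) and exposes
    the point estimate and its unbiased variance estimate as fitted
    attributes.

    Parameters
    ----------
    method : {"umvu", "sample_mean"}
        "umvu" exploits the delta-lognormal shape; "sample_mean" is the
        nonparametric benchmark.
    epsilon, max_terms :
        Series convergence control, see :class:`SeriesSettings`.

    Attributes
    ----------
    summary_ : SampleSummary
        Sufficient statistics of the fitted sample.
    kappa1_ : float
        Point estimate of the mean.
    kappa2_ : float
        Unbiased estimate of the variance kappa2.
    var_kappa1_ : float
        Unbiased estimate of the variance of ``kappa1_``.
    negative_variance_warning_ : bool
        True when an unbiased variance estimate came out negative.

    Examples
    --------
    >>> est = DeltaLognormalMeanEstimator().fit([0.0, 0.0, 0.0, 7.0])
    >>> est.kappa1_
    1.75
    """

    def __init__(
        self,
        method: str = "umvu",
        epsilon: float = 1e-10,
        max_terms: int = 10_000,
    ):
        self.method = method
        self.epsilon = epsilon
        self.max_terms = max_terms

    def _settings(self) -> SeriesSettings:
        return SeriesSettings(epsilon=self.epsilon, max_terms=self.max_terms)

    def fit(self, X, y=None) -> "DeltaLognormalMeanEstimator":
        if self.method not in ("umvu", "sample_mean"):
            raise ValueError(f"unknown method {self.method!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        if X.ndim != 1:
            raise ValueError("expected a 1-d sample or a single-column array")
        self.summary_ = summarize(X)
        if self.method == "umvu":
            result = umvue_estimate(self.summary_, self._settings())
        else:
            result = sample_mean_estimate(self.summary_)
        self.kappa1_ = result.kappa1_hat
        self.kappa2_ = result.kappa2_hat
        self.var_kappa1_ = result.var_hat_kappa1
        self.negative_variance_warning_ = result.negative_variance_warning
        self.n_features_in_ = 1
        return self

    def estimate_(self) -> EstimateResult:
        """The fitted estimates bundled as an :class:`EstimateResult`."""
        check_is_fitted(self, "kappa1_")
        return EstimateResult(
            self.kappa1_, self.kappa2_, self.var_kappa1_,
            self.negative_variance_warning_,
        )
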