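"""Model-based prediction of a finite-population total or mean.

A finite population U of size N is regarded as drawn from a delta-lognormal
superpopulation under the homogeneous mean model: the y_i share the same
mean kappa1 and variance kappa2 and are uncorrelated.  From a sample s of
size n (selected by an ignorable mechanism) the total t_U = sum_U y_i is
predicted by

    t_tilde = sum_s y_i + (N - n) * Ehat(y)

with Ehat(y) either the sample mean (*expansion predictor*, t = N ybar_s)
or the UMVUE kappa1_hat.  Both predictors are model-unbiased, and because
the predictor depends on the sampled units only, the prediction error
decomposes with zero covariance, giving prediction-error variances (PEV)

    expansion : N^2 (1 - n/N) kappa2 / n
    umvu      : (N - n) [ (N - n) V(kappa1_hat) + kappa2 ].

PEV estimates substitute the UMVU estimators kappa2_hat and
Vhat(kappa1_hat); they inherit the possible negativity of those unbiased
estimators and are returned as computed with a warning flag.  As N grows
with n fixed, the mean-scale umvu PEV tends to V(kappa1_hat) and the mean
predictor to kappa1_hat, recovering the infinite-population case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .distribution import ModelParams, cumulants
from .estimation import exact_variance_umvue, summarize, umvue_estimate
from .special import DEFAULT_SETTINGS, SeriesSettings

__all__ = [
    "PopulationFrame",
    "PredictionResult",
    "predict_total",
    "pev_theoretical",
    "FinitePopulationTotalPredictor",
]

_METHODS = ("expansion", "umvu")


@dataclass(frozen=True)
class PopulationFrame:
    """Finite-population bookkeeping: sizes N, n and sampling fraction f."""

    N: int
    n: int

    def __post_init__(self) -> None:
        if not (1 <= self.n <= self.N):
            raise ValueError(f"need 1 <= n <= N, got n={self.n}, N={self.N}")

    @property
    def f(self) -> float:
        return self.n / self.N


@dataclass(frozen=True)
class PredictionResult:
    """Predicted total/mean with estimated prediction-error variance."""

    total_pred: float
    mean_pred: float
    pev_hat_total: float
    pev_hat_mean: float
    method: str
    negative_variance_warning: bool = False


def predict_total(
    values,
    N: int,
    method: str = "umvu",
    settings: SeriesSettings = DEFAULT_SETTINGS,
) -> PredictionResult:
    """Predict the finite-population total from a sample of n <= N values.

    In the census case n = N the total is observed: both methods return the
    observed total with zero PEV.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    y = np.asarray(values, dtype=float).ravel()
    summary = summarize(y)
    n = summary.n
    if n > N:
        raise ValueError(f"sample size n={n} exceeds population size N={N}")
    sample_total = float(y.sum())
    if n == N:
        return PredictionResult(sample_total, sample_total / N, 0.0, 0.0, method)
    umvu = umvue_estimate(summary, settings)
    if method == "expansion":
        total = N * summary.ybar_s
        pev = N * N * (1.0 - n / N) * umvu.kappa2_hat / n
    else:
        total = sample_total + (N - n) * umvu.kappa1_hat
        pev = (N - n) * ((N - n) * umvu.var_hat_kappa1 + umvu.kappa2_hat)
    return PredictionResult(
        total_pred=total,
        mean_pred=total / N,
        pev_hat_total=pev,
        pev_hat_mean=pev / N**2,
        method=method,
        negative_variance_warning=pev < 0,
    )


def pev_theoretical(
    params: ModelParams,
    frame: PopulationFrame,
    method: str = "umvu",
    settings: SeriesSettings = DEFAULT_SETTINGS,
    scale: str = "total",
) -> float:
    """Theoretical prediction-error variance of a predictor of the total.

    ``scale="mean"`` divides by N^2 (PEV of the mean predictor).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if scale not in ("total", "mean"):
        raise ValueError(f"scale must be 'total' or 'mean', got {scale!r}")
    N, n = frame.N, frame.n
    kappa2 = cumulants(params).kappa2
    if n == N:
        pev = 0.0
    elif method == "expansion":
        pev = N * N * (1.0 - n / N) * kappa2 / n
    else:
        v = exact_variance_umvue(params, n, settings)
        pev = (N - n) * ((N - n) * v + kappa2)
    return pev / N**2 if scale == "mean" else pev


class FinitePopulationTotalPredictor(BaseEstimator):
    """Predictor of a finite-population total from a delta-lognormal sample.

    ``fit(X)`` consumes the sampled values and exposes the predicted total
    and mean and their estimated prediction-error variances as fitted
    attributes.

    Parameters
    ----------
    population_size : int
        Finite-population size N (must be >= the sample size).
    method : {"umvu", "expansion"}
    epsilon, max_terms :
        Series convergence control.

    Attributes
    ----------
    total_ : float
        Predicted population total.
    mean_ : float
        Predicted population mean, ``total_ / N``.
    pev_total_, pev_mean_ : float
        Estimated prediction-error variance on each scale.
    negative_variance_warning_ : bool
    """

    def __init__(
        self,
        population_size: int = None,
        method: str = "umvu",
        epsilon: float = 1e-10,
        max_terms: int = 10_000,
    ):
        self.population_size = population_size
        self.method = method
        self.epsilon = epsilon
        self.max_terms = max_terms

    def fit(self, X, y=None) -> "FinitePopulationTotalPredictor":
        if self.population_size is None:
            raise ValueError("population_size must be set before fitting")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        if X.ndim != 1:
            raise ValueError("expected a 1-d sample or a single-column array")
        result = predict_total(
            X,
            N=self.population_size,
            method=self.method,
            settings=SeriesSettings(self.epsilon, self.max_terms),
        )
        self.result_ = result
        self.total_ = result.total_pred
        self.mean_ = result.mean_pred
        self.pev_total_ = result.pev_hat_total
        self.pev_mean_ = result.pev_hat_mean
        self.negative_variance_warning_ = result.negative_variance_warning
        self.n_features_in_ = 1
        return self
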