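"""Relative efficiency of the UMVU estimator and predictor of the mean.

The gain from exploiting the delta-lognormal shape is quantified by two
variance ratios (values below 1 mean the UMVU route is more precise):

    eff1 = V(kappa1_hat) / V(ybar_s)                    (estimation)
    eff2 = V(t_umvu - t_U) / V(t_exp - t_U)             (prediction)

eff2 simplifies to ``n [ (N - n) V(kappa1_hat) + kappa2 ] / (N kappa2)``
and tends to eff1 as the population size N grows with n fixed.  Both
ratios are invariant to the log-location mu (the alpha^2 factor cancels).

Grid runners evaluate the ratios over Cartesian grids of (p0, sigma, n[, N])
— the grids step in sigma, the log-scale standard deviation — and return
long-format tables, one row per grid point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .distribution import ModelParams, cumulants
from .estimation import exact_variance_umvue
from .special import DEFAULT_SETTINGS, SeriesSettings

__all__ = ["GridSpec", "eff1", "eff2", "efficiency_grid"]


def eff1(
    params: ModelParams,
    n: int,
    settings: SeriesSettings = DEFAULT_SETTINGS,
    include_singleton_term: bool = False,
) -> float:
    """Estimation-context relative efficiency V(kappa1_hat) / (kappa2 / n).

    ``include_singleton_term`` selects the j = 1 contribution of the exact
    variance sum (see :func:`exact_variance_umvue`); off by default for
    fidelity to the printed formula, which only matters for p0 near 1 with
    small n.
    """
    if n < 2:
        raise ValueError(f"eff1 requires n >= 2, got n={n}")
    kappa2 = cumulants(params).kappa2
    v = exact_variance_umvue(params, n, settings, include_singleton_term)
    return n * v / kappa2


def eff2(
    params: ModelParams,
    n: int,
    N: int,
    settings: SeriesSettings = DEFAULT_SETTINGS,
    include_singleton_term: bool = False,
) -> float:
    """Prediction-context relative efficiency; equals the PEV ratio on both
    the total and the mean scale."""
    if not (2 <= n < N):
        raise ValueError(f"eff2 requires 2 <= n < N, got n={n}, N={N}")
    kappa2 = cumulants(params).kappa2
    v = exact_variance_umvue(params, n, settings, include_singleton_term)
    return n * ((N - n) * v + kappa2) / (N * kappa2)


@dataclass(frozen=True)
class GridSpec:
    """Cartesian grid over (p0, sigma, n[, N]) for the efficiency surfaces.

    sigma values are log-scale standard deviations.  Values outside the
    validated domain (p0 <= 0.9, sigma <= 2, n <= 1000) are allowed with a
    warning.
    """

    p0_values: Sequence[float]
    sigma_values: Sequence[float]
    n_values: Sequence[int]
    N_values: Sequence[int] | None = None
    settings: SeriesSettings = field(default=DEFAULT_SETTINGS)
    include_singleton_term: bool = False

    def __post_init__(self) -> None:
        for name, vals in (
            ("p0_values", self.p0_values),
            ("sigma_values", self.sigma_values),
            ("n_values", self.n_values),
        ):
            if len(vals) == 0:
                raise ValueError(f"{name} must be nonempty")
        if self.N_values is not None and len(self.N_values) == 0:
            raise ValueError("N_values must be nonempty when given")
        if any(not (0.0 <= p < 1.0) for p in self.p0_values):
            raise ValueError("p0 grid values must lie in [0, 1)")
        if any(s <= 0 for s in self.sigma_values):
            raise ValueError("sigma grid values must be positive")
        if any(n < 2 for n in self.n_values):
            raise ValueError("n grid values must be >= 2")
        if max(self.p0_values) > 0.9 or max(self.sigma_values) > 2.0 or max(
            self.n_values
        ) > 1000:
            warnings.warn(
                "grid extends beyond the validated domain "
                "(p0 <= 0.9, sigma <= 2, n <= 1000)",
                stacklevel=2,
            )


def efficiency_grid(spec: GridSpec, context: str = "estimation") -> pd.DataFrame:
    """Evaluate eff1 or eff2 over the full Cartesian grid.

    Returns a long-format DataFrame, one row per grid point, ordered with
    p0 outermost, then sigma, then n, then N.  Columns: p0, sigma, n
    [, N, f], eff.  mu is fixed at 0; the ratios do not depend on it.
    """
    if context not in ("estimation", "prediction"):
        raise ValueError(f"context must be 'estimation' or 'prediction', got {context!r}")
    if context == "prediction" and spec.N_values is None:
        raise ValueError("prediction context requires N_values")
    rows = []
    for p0 in spec.p0_values:
        for sigma in spec.sigma_values:
            params = ModelParams.from_sigma(p0, 0.0, sigma)
            kappa2 = cumulants(params).kappa2
            for n in spec.n_values:
                v = exact_variance_umvue(
                    params, n, spec.settings, spec.include_singleton_term
                )
                if context == "estimation":
                    rows.append((p0, sigma, n, n * v / kappa2))
                else:
                    for N in spec.N_values:
                        if n >= N:
                            raise ValueError(
                                f"grid point n={n}, N={N} violates n < N"
                            )
                        e2 = n * ((N - n) * v + kappa2) / (N * kappa2)
                        rows.append((p0, sigma, n, N, n / N, e2))
    if context == "estimation":
        return pd.DataFrame(rows, columns=["p0", "sigma", "n", "eff"])
    return pd.DataFrame(rows, columns=["p0", "sigma", "n", "N", "f", "eff"])
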