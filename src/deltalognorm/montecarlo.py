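"""Monte-Carlo validation of the UMVUE and of the variance approximation.

The protocol: simulate K independent samples of size n from a
delta-lognormal distribution, compute the UMVUE of the mean on each, and
compare the Monte-Carlo mean E_MC(kappa1_hat) and variance V_MC(kappa1_hat)
of the K estimates with their theoretical values kappa1 (the estimator is
unbiased) and the exact variance V(kappa1_hat).

The replicate loop is vectorised: samples are generated chunk-wise from a
single seeded stream, consuming two uniforms per unit exactly like
:func:`deltalognorm.distribution.sample`, so replicate r of a report equals
the r-th consecutive call of the scalar sampler on the same stream.  The
0F1 factor of each replicate's UMVUE is evaluated by the vectorised series
recurrence.

A second runner tabulates the ratio Vapp/V of the closed-form variance
approximation to the exact variance over (p0, sigma, n) grids; the ratio is
mu-invariant and approaches 1 as n grows and as p0 and sigma shrink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .distribution import ModelParams, cumulants
from .efficiency import GridSpec
from .estimation import approx_variance_umvue, exact_variance_umvue
from .special import DEFAULT_SETTINGS, SeriesSettings, hyp0f1_array

__all__ = ["MCReport", "mc_validate", "vapp_ratio_grid"]


@dataclass(frozen=True)
class MCReport:
    """Monte-Carlo summary of K replicated UMVU estimates.

    emc/vmc are the Monte-Carlo mean and (K-1)-divisor variance of the K
    kappa1_hat values; emc_se = sqrt(vmc / K).  vmc_se is the standard
    error of vmc itself, estimated from the fourth central moment of the
    replicate stream (the distributions here are heavily skewed, so this
    can be large relative to vmc).  ybar_emc/ybar_vmc track the sample mean
    of each replicate, a joint check of the sampler and of
    V(ybar_s) = kappa2 / n.
    """

    params: ModelParams
    n: int
    K: int
    seed: int
    emc: float
    vmc: float
    emc_se: float
    vmc_se: float
    kappa1_true: float
    v_exact: float
    ybar_emc: float
    ybar_vmc: float
    ybar_vmc_se: float


def _replicate_estimates(
    params: ModelParams,
    n: int,
    K: int,
    rng: np.random.Generator,
    settings: SeriesSettings,
    chunk_rows: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """kappa1_hat and ybar_s for K vectorised replicates of size n."""
    if chunk_rows <= 0:
        chunk_rows = max(1, 2_000_000 // n)
    p0, mu, sigma = params.p0, params.mu, params.sigma
    k1 = np.empty(K)
    ybar = np.empty(K)
    done = 0
    while done < K:
        R = min(chunk_rows, K - done)
        u = rng.random((R, n, 2))
        pos = u[:, :, 0] >= p0
        logs = mu + sigma * ndtri(u[:, :, 1])
        y = np.exp(logs)
        y[~pos] = 0.0
        ybar[done : done + R] = y.sum(axis=1) / n

        n1 = pos.sum(axis=1)
        logs = np.where(pos, logs, 0.0)
        s_log = logs.sum(axis=1)
        s_log2 = (logs * logs).sum(axis=1)

        out = np.zeros(R)
        one = n1 == 1
        out[one] = np.exp(s_log[one]) / n  # the single positive value / n
        many = n1 >= 2
        if many.any():
            m1 = n1[many].astype(float)
            ybar_ln = s_log[many] / m1
            s2_ln = np.maximum(s_log2[many] - m1 * ybar_ln**2, 0.0) / (m1 - 1.0)
            a = (m1 - 1.0) / 2.0
            z = (m1 - 1.0) ** 2 * s2_ln / (4.0 * m1)
            f = hyp0f1_array(a, z, settings)
            out[many] = (m1 / n) * np.exp(ybar_ln) * f
        k1[done : done + R] = out
        done += R
    return k1, ybar


def mc_validate(
    params: ModelParams,
    n: int,
    K: int,
    seed: int,
    settings: SeriesSettings = DEFAULT_SETTINGS,
) -> MCReport:
    """Run the K-replicate validation protocol and summarise it.

    Parameters
    ----------
    params : ModelParams
    n : int
        Sample size per replicate, >= 2.
    K : int
        Number of replicates, >= 100.
    seed : int
        Seed of the single RNG stream; fixed seed gives identical reports.
    """
    if K < 100:
        raise ValueError(f"K must be >= 100 for a meaningful report, got {K}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    k1, ybar = _replicate_estimates(params, n, K, rng, settings)
    emc = float(k1.mean())
    vmc = float(k1.var(ddof=1))
    return MCReport(
        params=params,
        n=n,
        K=K,
        seed=seed,
        emc=emc,
        vmc=vmc,
        emc_se=float(np.sqrt(vmc / K)),
        vmc_se=_variance_se(k1),
        kappa1_true=cumulants(params).kappa1,
        v_exact=exact_variance_umvue(params, n, settings),
        ybar_emc=float(ybar.mean()),
        ybar_vmc=float(ybar.var(ddof=1)),
        ybar_vmc_se=_variance_se(ybar),
    )


def _variance_se(x: np.ndarray) -> float:
    """Standard error of the sample variance, sqrt((m4 - m2^2) / K)."""
    K = x.size
    c = x - x.mean()
    m2 = float(np.mean(c * c))
    m4 = float(np.mean(c**4))
    return float(np.sqrt(max(m4 - m2 * m2, 0.0) / K))


def vapp_ratio_grid(spec: GridSpec) -> pd.DataFrame:
    """Tabulate Vapp(kappa1_hat) / V(kappa1_hat) over a (p0, sigma, n) grid.

    Returns a long-format DataFrame with columns p0, sigma, n, ratio,
    ordered p0 outermost, then sigma, then n.  mu is fixed at 0 (it
    cancels in the ratio).
    """
    rows = []
    for p0 in spec.p0_values:
        for sigma in spec.sigma_values:
            params = ModelParams.from_sigma(p0, 0.0, sigma)
            for n in spec.n_values:
                v = exact_variance_umvue(
                    params, n, spec.settings, spec.include_singleton_term
                )
                rows.append((p0, sigma, n, approx_variance_umvue(params, n) / v))
    return pd.DataFrame(rows, columns=["p0", "sigma", "n", "ratio"])
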