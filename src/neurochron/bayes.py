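"""Bayesian prevalence of within-participant effects and Bayes factors.

Prevalence: given k of n participants individually significant at level
alpha, the population prevalence gamma has likelihood
Binomial(k; n, theta) with theta = alpha + gamma*(1 - alpha) (a true effect
is detected with the test's power folded into gamma; a null participant is
significant with probability alpha). Under a uniform prior the posterior
mode has the closed form max(0, (k/n - alpha)/(1 - alpha)); the highest-
posterior-density interval is found on a fine grid (default step 1e-4) by
shortest-interval search. The conventional reporting level is 96%.

Bayes factors: the default JZS two-sample t-test Bayes factor (Cauchy
prior on the standardized effect, scale rscale) computed by adaptive
quadrature of the Rouder et al. (2009) g-prior mixture integral, and a BIC
approximation for nested regression models, bf10 = exp((BIC0 - BIC1)/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "PrevalenceResult",
    "BayesFactorResult",
    "prevalence_posterior",
    "jzs_ttest_bf10",
    "bic_bf10",
]


@dataclass
class PrevalenceResult:
    k: int
    n: int
    alpha: float
    gamma_map: float
    hpdi_low: float
    hpdi_high: float
    hpdi_level: float
    gamma_grid: np.ndarray
    posterior: np.ndarray  # density over gamma_grid, integrates to 1


@dataclass
class BayesFactorResult:
    bf10: float
    method: str
    inputs: dict

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def prevalence_posterior(
    k: int,
    n: int,
    alpha: float = 0.05,
    hpdi_level: float = 0.96,
    grid_step: float = 1e-4,
) -> PrevalenceResult:
    """Posterior over the population prevalence of a within-participant effect."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    gamma = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    theta = alpha + gamma * (1.0 - alpha)
    with np.errstate(divide="ignore"):
        loglik = k * np.log(theta)
        if n - k > 0:
            loglik = loglik + (n - k) * np.log1p(-theta)
    post = np.exp(loglik - loglik.max())
    post /= np.trapezoid(post, gamma)

    gamma_map = max(0.0, (k / n - alpha) / (1.0 - alpha))

    # shortest interval containing hpdi_level mass: water-level on the grid
    order = np.argsort(post)[::-1]
    cell = grid_step * post
    cell[0] *= 0.5
    cell[-1] *= 0.5
    csum = np.cumsum(cell[order])
    m = np.searchsorted(csum, hpdi_level) + 1
    chosen = order[:m]
    hpdi_low = float(gamma[chosen.min()])
    hpdi_high = float(gamma[chosen.max()])
    return PrevalenceResult(
        k=int(k),
        n=int(n),
        alpha=float(alpha),
        gamma_map=float(gamma_map),
        hpdi_low=hpdi_low,
        hpdi_high=hpdi_high,
        hpdi_level=float(hpdi_level),
        gamma_grid=gamma,
        posterior=post,
    )


def jzs_ttest_bf10(t: float, n1: int, n2: int, rscale: float = np.sqrt(2) / 2) -> BayesFactorResult:
    """Default JZS Bayes factor for a two-sample t statistic.

    Cauchy(0, rscale) prior on the standardized effect size, implemented as
    the scale mixture of a zero-centred normal with an inverse-chi^2 mixing
    density over g; the marginal likelihood ratio is evaluated with
    adaptive quadrature over g in (0, inf).
    """
    if not np.isfinite(t):
        raise ValueError("t statistic must be finite")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    N = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    t = float(t)

    def integrand(g: float) -> float:
        ng = 1.0 + N * g * rscale**2
        return (
            ng ** -0.5
            * (1.0 + t**2 / (ng * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g ** -1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    num, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    den = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return BayesFactorResult(
        bf10=float(num / den),
        method="jzs_ttest",
        inputs={"t": t, "n1": int(n1), "n2": int(n2), "rscale": float(rscale)},
    )


def bic_bf10(
    loglik1: float, k1_params: int, loglik0: float, k0_params: int, n_obs: int
) -> BayesFactorResult:
    """BIC-approximate Bayes factor for nested models (model 1 vs model 0)."""
    if n_obs <= k1_params:
        raise ValueError("n_obs must exceed the larger model's parameter count")
    bic1 = k1_params * np.log(n_obs) - 2.0 * loglik1
    bic0 = k0_params * np.log(n_obs) - 2.0 * loglik0
    return BayesFactorResult(
        bf10=float(np.exp((bic0 - bic1) / 2.0)),
        method="bic_approx",
        inputs={
            "loglik1": float(loglik1),
            "k1": int(k1_params),
            "loglik0": float(loglik0),
            "k0": int(k0_params),
            "n_obs": int(n_obs),
        },
    )
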