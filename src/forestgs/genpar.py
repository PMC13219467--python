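"""Across-site genetic parameters: heritability, dominance ratio, and
approximate standard errors.

Across-site genetic variances are recovered from the two-site CORH fit as

    sigma2_a = r_a * (sigma2_aS1 + sigma2_aS2) / 2
    sigma2_d = r_d * (sigma2_dS1 + sigma2_dS2) / 2

(negative when the type-B correlation is negative), and the individual-level
ratios use a shared denominator of site-mean plot, additive, dominance and
residual variances:

    h2 = sigma2_a / denom,  d2 = sigma2_d / denom,  H2 = (sigma2_a + sigma2_d) / denom

Note the denominator deliberately excludes the block variance: blocks are
treated as coarse environmental strata outside the individual-tree
phenotypic variance.  Standard errors come from the delta method applied to
the inverse average-information matrix of the REML fit; a parametric
bootstrap is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mixedmodel import ModelData, ModelFit, VarianceComponents, reml_fit

__all__ = [
    "HeritabilityEstimates",
    "across_site_variance",
    "heritability_estimates",
    "approx_standard_errors",
    "parametric_bootstrap_se",
]


@dataclass
class HeritabilityEstimates:
    """Across-site variances and the three individual-level ratios."""

    sigma2_a: float
    sigma2_d: float
    h2: float
    d2: float
    H2: float
    se: dict[str, float] | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_d": self.sigma2_d,
            "h2": self.h2,
            "d2": self.d2,
            "H2": self.H2,
        }


def across_site_variance(components: VarianceComponents) -> tuple[float, float]:
    """Across-site additive and dominance variances from the CORH fit."""
    s2a = components.r_a * sum(components.additive) / 2.0
    s2d = components.r_d * sum(components.dominance) / 2.0
    return float(s2a), float(s2d)


def _denominator(components: VarianceComponents) -> float:
    plot = sum(components.plot) / 2.0 if components.plot is not None else 0.0
    return (
        plot
        + sum(components.additive) / 2.0
        + sum(components.dominance) / 2.0
        + sum(components.residual) / 2.0
    )


def heritability_estimates(components: VarianceComponents) -> HeritabilityEstimates:
    """h2, d2 and H2 with the shared site-mean denominator."""
    s2a, s2d = across_site_variance(components)
    denom = _denominator(components)
    if denom <= 0:
        raise ValueError("zero phenotypic-variance denominator")
    h2 = s2a / denom
    d2 = s2d / denom
    # H2 = h2 + d2 holds exactly, by construction
    return HeritabilityEstimates(
        sigma2_a=s2a, sigma2_d=s2d, h2=h2, d2=d2, H2=h2 + d2,
    )


def _estimates_from_theta(theta: np.ndarray, names: list[str]) -> np.ndarray:
    """(sigma2_a, sigma2_d, h2, d2, H2) as a function of the raw parameter
    vector, for delta-method gradients."""
    d = dict(zip(names, theta))
    s2a = d["r_a"] * (d["additive_S1"] + d["additive_S2"]) / 2.0
    s2d = d["r_d"] * (d["dominance_S1"] + d["dominance_S2"]) / 2.0
    plot = (d.get("plot_S1", 0.0) + d.get("plot_S2", 0.0)) / 2.0
    denom = (
        plot
        + (d["additive_S1"] + d["additive_S2"]) / 2.0
        + (d["dominance_S1"] + d["dominance_S2"]) / 2.0
        + (d["residual_S1"] + d["residual_S2"]) / 2.0
    )
    return np.array([s2a, s2d, s2a / denom, s2d / denom, (s2a + s2d) / denom])


def approx_standard_errors(fit: ModelFit) -> dict[str, float]:
    """Delta-method standard errors for sigma2_a, sigma2_d, h2, d2, H2.

    The inverse average-information matrix approximates the covariance of
    the raw variance components; gradients of each ratio are taken
    numerically (central differences).  Components pinned at the boundary
    get SE 0.00; a singular AI matrix yields NaN SEs rather than fabricated
    numbers.
    """
    names = fit.param_names
    theta = np.array([fit.components.as_dict()[n] for n in names])
    labels = ["sigma2_a", "sigma2_d", "h2", "d2", "H2"]
    try:
        cov = np.linalg.inv(fit.ai_matrix)
    except np.linalg.LinAlgError:
        return {k: float("nan") for k in labels}

    pinned_idx = [i for i, n in enumerate(names) if n in fit.pinned]
    free = np.ones(len(names), dtype=bool)
    free[pinned_idx] = False

    grad = np.zeros((5, len(names)))
    for j in range(len(names)):
        if not free[j]:
            continue
        h = max(1e-6, 1e-4 * abs(theta[j]))
        up, down = theta.copy(), theta.copy()
        up[j] += h
        down[j] -= h
        grad[:, j] = (
            _estimates_from_theta(up, names) - _estimates_from_theta(down, names)
        ) / (2 * h)
    var = np.einsum("ij,jk,ik->i", grad, cov, grad)
    se = np.sqrt(np.maximum(var, 0.0))
    # if every contributing component is pinned, the SE is exactly 0.00
    out = dict(zip(labels, (float(s) for s in se)))
    if {"dominance_S1", "dominance_S2"} <= set(fit.pinned):
        out["sigma2_d"] = 0.0
        out["d2"] = 0.0
    if {"additive_S1", "additive_S2"} <= set(fit.pinned):
        out["sigma2_a"] = 0.0
        out["h2"] = 0.0
    return out


def parametric_bootstrap_se(
    fit: ModelFit,
    data: ModelData,
    n_replicates: int = 200,
    seed: int = 0,
    loglik_tol: float = 1e-4,
    grad_tol: float = 0.05,
) -> dict[str, float]:
    """Bootstrap SEs: simulate y* ~ N(X beta, V_hat), refit, recompute the
    ratios; the SD over replicates estimates each SE.  Refits warm-start at
    the fitted components with tolerances loose enough for SD estimation."""
    rng = np.random.default_rng(seed)
    theta = data.components_to_theta(fit.components)
    V = data.build_V(theta)
    L = np.linalg.cholesky(V + 1e-10 * np.eye(data.n))
    mean = data.X @ fit.beta
    y_orig = data.y
    draws = []
    try:
        for _ in range(n_replicates):
            data.y = mean + L @ rng.standard_normal(data.n)
            refit = reml_fit(data, start=fit.components, max_iter=50,
                             restarts=False, loglik_tol=loglik_tol,
                             grad_tol=grad_tol)
            draws.append(
                list(heritability_estimates(refit.components).as_dict().values())
            )
    finally:
        data.y = y_orig
    arr = np.asarray(draws)
    labels = ["sigma2_a", "sigma2_d", "h2", "d2", "H2"]
    return {k: float(arr[:, i].std(ddof=1)) for i, k in enumerate(labels)}


def full_estimates(fit: ModelFit) -> HeritabilityEstimates:
    """Heritability estimates with delta-method SEs attached."""
    est = heritability_estimates(fit.components)
    est.se = approx_standard_errors(fit)
    return est
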