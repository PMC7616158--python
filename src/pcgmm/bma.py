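"""Bayesian model averaging over risk-factor subsets on the PC scale.

When many correlated risk factors (e.g. tissue-specific expression of one
gene) are candidates, a joint multivariable fit is poorly conditioned.
Instead, every non-empty subset of risk factors defines a sub-model

    beta_y_pc = beta_x_pc[:, subset] @ theta_subset + noise,
    noise ~ N(0, omega_yy),   theta_subset ~ N(0, sigma_prior^2 I),

whose Gaussian marginal likelihood is available in closed form through the
marginal covariance B sigma^2 B' + omega_yy.  Subset priors are
prior_p^s (1 - prior_p)^(K - s); each risk factor's marginal inclusion
probability is the summed posterior of all models containing it.  All
subsets are enumerated exactly (feasible up to K = 20).
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .datatypes import BMAResult, PCReduction, ValidationError

__all__ = ["model_evidence", "enumerate_bma"]

_MAX_K = 20


def _gaussian_loglik(y: np.ndarray, cov: np.ndarray) -> float:
    try:
        c = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular marginal covariance in model evidence") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    quad = float(y @ cho_solve(c, y))
    return -0.5 * (y.size * np.log(2 * np.pi) + logdet + quad)


def model_evidence(red: PCReduction, subset: tuple[int, ...], sigma_prior: float = 0.5) -> float:
    """Log marginal likelihood of the sub-model restricted to ``subset``."""
    if len(subset) == 0:
        return _gaussian_loglik(red.beta_y_pc, red.omega_yy)
    if red.p <= len(subset):
        raise ValidationError("sub-model has more risk factors than principal components")
    b = red.beta_x_pc[:, list(subset)]
    cov = sigma_prior**2 * (b @ b.T) + red.omega_yy
    return _gaussian_loglik(red.beta_y_pc, cov)


def enumerate_bma(
    red: PCReduction,
    prior_p: float = 0.1,
    sigma_prior: float = 0.5,
    max_size: int | None = None,
) -> BMAResult:
    """Exhaustive Bayesian model averaging over non-empty risk-factor subsets."""
    k = red.n_traits
    if k > _MAX_K:
        raise ValidationError(f"K = {k} risk factors: cap subset enumeration via max_size <= {_MAX_K}")
    if not 0 < prior_p < 1:
        raise ValidationError("prior_p must lie in (0, 1)")
    max_size = k if max_size is None else min(max_size, k)
    if max_size < 1:
        raise ValidationError("max_size must be at least 1")

    subsets: list[tuple[int, ...]] = []
    log_weights: list[float] = []
    for size in range(1, max_size + 1):
        log_prior = size * np.log(prior_p) + (k - size) * np.log1p(-prior_p)
        for subset in combinations(range(k), size):
            subsets.append(subset)
            log_weights.append(log_prior + model_evidence(red, subset, sigma_prior))

    log_w = np.asarray(log_weights)
    post = np.exp(log_w - logsumexp(log_w))
    post = post / post.sum()

    inclusion = np.zeros(k)
    for subset, pr in zip(subsets, post):
        for idx in subset:
            inclusion[idx] += pr
    order = np.argsort(-post)
    models = [(subsets[i], float(post[i])) for i in order]
    return BMAResult(models=models, inclusion=inclusion, prior_p=prior_p,
                     trait_names=list(red.trait_names))
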