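"""Approximate-Bayes-factor colocalization for two traits in one region.

Assumes at most one causal variant per trait.  Per-variant evidence uses
the Wakefield approximate Bayes factor from the marginal beta and standard
error; hypothesis posteriors come from enumerating the single-causal-variant
configurations:

    H0  neither trait has a causal variant in the region
    H1  trait 1 only            (J configurations)
    H2  trait 2 only            (J configurations)
    H3  both, distinct variants (J * (J - 1) configurations)
    H4  both, the same variant  (J configurations)

with per-configuration priors p1, p2, p1 * p2 and p12 respectively.
Sensitivity of the shared-variant posterior to p12 — the prior probability
that a variant is causal for both traits — is exposed as a grid scan.
"""
from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .datatypes import ColocResult, ValidationError

__all__ = ["approximate_bayes_factors", "colocalize", "p12_sensitivity"]

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2


def approximate_bayes_factors(beta: np.ndarray, se: np.ndarray,
                              prior_sd: float = PRIOR_SD_QUANTITATIVE) -> np.ndarray:
    """Per-variant Wakefield log approximate Bayes factors.

    With shrinkage ratio r = prior_sd^2 / (prior_sd^2 + se^2) and Wald ratio
    z = beta / se, logABF = 0.5 * (log(1 - r) + r * z^2): the log ratio of
    the marginal likelihood under a N(0, prior_sd^2) effect prior to that
    under the point-null.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValidationError("non-finite beta or se")
    if np.any(se <= 0):
        raise ValidationError("standard errors must be strictly positive")
    if prior_sd < 0:
        raise ValidationError("prior_sd must be non-negative")
    r = prior_sd**2 / (prior_sd**2 + se**2)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def colocalize(
    data1: tuple[np.ndarray, np.ndarray],
    data2: tuple[np.ndarray, np.ndarray],
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd1: float = PRIOR_SD_QUANTITATIVE,
    prior_sd2: float = PRIOR_SD_QUANTITATIVE,
) -> ColocResult:
    """Posterior probabilities of hypotheses H0-H4 for two aligned traits."""
    p1, p2, p12 = priors
    if min(p1, p2, p12) <= 0 or p1 + p2 + p12 >= 1:
        raise ValidationError("priors must be positive with p1 + p2 + p12 < 1")
    l1 = approximate_bayes_factors(*data1, prior_sd=prior_sd1)
    l2 = approximate_bayes_factors(*data2, prior_sd=prior_sd2)
    if l1.shape != l2.shape:
        raise ValidationError("trait 1 and trait 2 must cover the same variants in order")
    j = l1.size

    s1 = logsumexp(l1)                 # log sum_j ABF1_j
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)           # log sum_j ABF1_j ABF2_j
    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(p1) + s1
    log_h[2] = np.log(p2) + s2
    # sum_{j != k} ABF1_j ABF2_k = (sum ABF1)(sum ABF2) - sum ABF1 ABF2
    both = logsumexp([s1 + s2, s12], b=[1.0, -1.0])
    if j < 2 or not np.isfinite(both):
        log_h[3] = -np.inf
    else:
        log_h[3] = np.log(p1) + np.log(p2) + both
    log_h[4] = np.log(p12) + s12

    post = np.exp(log_h - logsumexp(log_h))
    post = post / post.sum()
    h3, h4 = post[3], post[4]
    cond_h3 = float(h3 / (h3 + h4)) if h3 + h4 > 0 else float("nan")
    return ColocResult(posteriors=post, priors=(p1, p2, p12), conditional_h3=cond_h3)


def p12_sensitivity(
    data1: tuple[np.ndarray, np.ndarray],
    data2: tuple[np.ndarray, np.ndarray],
    p12_grid: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    prior_sd1: float = PRIOR_SD_QUANTITATIVE,
    prior_sd2: float = PRIOR_SD_QUANTITATIVE,
) -> list[tuple[float, ColocResult]]:
    """Colocalization across a grid of shared-causal-variant priors p12."""
    results = []
    for p12 in np.asarray(p12_grid, dtype=float):
        res = colocalize(data1, data2, priors=(p1, p2, float(p12)),
                         prior_sd1=prior_sd1, prior_sd2=prior_sd2)
        results.append((float(p12), res))
    return results
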