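"""Conditional F-statistics for dimension-reduced genetic associations.

Phenotypic heterogeneity — distinct variants in the region associating with
different patterns of risk factors — is what identifies multivariable
causal effects from a single gene.  Its absence is a rank reduction: the
PC-scale associations of one risk factor are a linear combination of the
others'.  For risk factor k we fit the best such combination delta by
minimizing the continuously-weighted quadratic form

    q(delta) = h(delta)' V(delta)^-1 h(delta),
    h(delta) = beta_x_pc[:, k] - beta_x_pc[:, -k] @ delta,

where V(delta) is the exact covariance of h implied by the omega_xx blocks.
The weighting is updated continuously by iterating the GLS estimating
equation delta <- argmin_d h(d)' V(delta)^-1 h(d) to a fixed point.  (Joint
minimization of the quadratic form over delta is deliberately avoided: the
jointly-minimized criterion is invariant to rescaling the combination
vector, so its infimum detects a rank deficiency anywhere in the
coefficient matrix and is identical for every risk factor; the fixed-point
form keeps the statistic specific to risk factor k.)  Under the null of no
phenotypic heterogeneity the quadratic form at the fixed point is
asymptotically chi-squared with p - K + 1 degrees of freedom; the
conditional F-statistic is the quadratic form divided by those degrees of
freedom.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .datatypes import ConditionalFResult, PCReduction, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["conditional_f", "all_conditional_f"]

WEAK_F_THRESHOLD = 10.0
VERY_WEAK_F_THRESHOLD = 1.0


def _residual_covariance(red: PCReduction, k: int, others: np.ndarray,
                         delta: np.ndarray) -> np.ndarray:
    """Covariance of beta_x_pc[:, k] - sum_l delta_l beta_x_pc[:, l]."""
    v = red.omega_xx[k, k].copy()
    for i, l in enumerate(others):
        v -= delta[i] * (red.omega_xx[k, l] + red.omega_xx[l, k])
        for j, m in enumerate(others):
            v += delta[i] * delta[j] * red.omega_xx[l, m]
    return 0.5 * (v + v.T)


def _q_delta(red: PCReduction, k: int, others: np.ndarray, delta: np.ndarray) -> float:
    h = red.beta_x_pc[:, k] - red.beta_x_pc[:, others] @ delta
    v = _residual_covariance(red, k, others, delta)
    try:
        c = cho_factor(v, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("residual covariance not positive definite") from exc
    return float(h @ cho_solve(c, h))


def _gls_step(red: PCReduction, k: int, others: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """One GLS update of delta with the weighting held at the current delta."""
    v = _residual_covariance(red, k, others, delta)
    try:
        c = cho_factor(v, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("residual covariance not positive definite") from exc
    b = red.beta_x_pc[:, others]
    wb = cho_solve(c, b)
    return np.linalg.solve(b.T @ wb, wb.T @ red.beta_x_pc[:, k])


def conditional_f(red: PCReduction, k: int) -> tuple[float, int, float]:
    """Conditional F-statistic for risk factor ``k`` given the others.

    Returns (statistic, df, pvalue); the p-value refers the minimized
    quadratic form (statistic * df) to its limiting chi-squared null.  With
    a single risk factor the statistic falls back to the unconditional
    mean chi-squared of its PC-scale associations.
    """
    p, n_traits = red.p, red.n_traits
    if p <= n_traits:
        raise ValidationError("need more principal components than risk factors")
    if not 0 <= k < n_traits:
        raise ValidationError(f"risk-factor index {k} out of range")

    if n_traits == 1:
        b = red.beta_x_pc[:, 0]
        c = cho_factor(red.omega_xx[0, 0], lower=True)
        q = float(b @ cho_solve(c, b))
        df = p
        return q / df, df, float(stats.chi2.sf(q, df))

    others = np.array([l for l in range(n_traits) if l != k])
    delta = np.zeros(others.size)
    q_prev = np.inf
    for _ in range(200):
        delta_new = _gls_step(red, k, others, delta)
        q_new = _q_delta(red, k, others, delta_new)
        step = np.max(np.abs(delta_new - delta)) / (1.0 + np.max(np.abs(delta_new)))
        delta = delta_new
        if step < 1e-10 or abs(q_new - q_prev) < 1e-12 * (1.0 + q_new):
            q_prev = q_new
            break
        q_prev = q_new
    else:
        logger.warning("conditional F weighting iteration did not fully converge for k=%d", k)
    q_fix = float(q_prev)
    df = p - n_traits + 1
    return q_fix / df, df, float(stats.chi2.sf(q_fix, df))


def all_conditional_f(red: PCReduction) -> ConditionalFResult:
    """Conditional F-statistics for every risk factor, with weak-instrument warnings."""
    n_traits = red.n_traits
    f_stats = np.empty(n_traits)
    pvalues = np.empty(n_traits)
    df = red.p - n_traits + 1 if n_traits > 1 else red.p
    names = red.trait_names or [f"trait{k + 1}" for k in range(n_traits)]
    for k in range(n_traits):
        f_stats[k], _, pvalues[k] = conditional_f(red, k)
        if f_stats[k] < VERY_WEAK_F_THRESHOLD:
            logger.warning("conditional F for %s is %.3f (< 1): instruments are very weak",
                           names[k], f_stats[k])
        elif f_stats[k] < WEAK_F_THRESHOLD:
            logger.info("conditional F for %s is %.3f (< 10): weak-instrument bias possible",
                        names[k], f_stats[k])
    return ConditionalFResult(f_stats=f_stats, df=df, pvalues=pvalues,
                              n_pcs=red.p, trait_names=names)
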