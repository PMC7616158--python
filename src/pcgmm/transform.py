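"""Principal-component dimension reduction of correlated variant associations.

Marginal per-variant regression coefficients in a gene region are highly
collinear because of linkage disequilibrium.  This module builds a weighted
genetic correlation matrix, retains the leading eigenvectors explaining a
target fraction of its variance, and re-expresses the marginal associations
as multivariable regression coefficients on the principal-component scale,
together with their full variance structure.

With loadings L (J x p), LD matrix rho and Gram matrix S = L' rho L:

    beta_y_pc        = S^-1 L' beta_y
    omega_yy         = S^-1 L' D_y rho D_y L S^-1,      D_y = diag(se_y)
    omega_xx[k, l]   = c_kl S^-1 L' D_xk rho D_xl L S^-1

where c_kl is the phenotypic correlation between risk factors k and l.  The
same sandwich applied to an isotropic variant-scale direct-effect covariance
gives the overdispersion basis S^-1 L' rho^2 L S^-1 used by the robust
estimator.
"""
from __future__ import annotations

import numpy as np

from .datatypes import (
    LDMatrix,
    PCReduction,
    RegionalSummaryData,
    TraitCorrelation,
    ValidationError,
)

__all__ = [
    "weighted_correlation_matrix",
    "select_components",
    "transform_associations",
    "pc_reduce",
]

# components with eigenvalues at numerical-noise level are never retained
_RELATIVE_EIG_FLOOR = 1e-12
_MAX_CONDITION = 1e12


def weighted_correlation_matrix(data: RegionalSummaryData, ld: LDMatrix,
                                weight_mode: str = "exposure") -> np.ndarray:
    """Weighted genetic correlation matrix Psi with Psi_ij = rho_ij w_i w_j.

    The default weight aggregates association strength across risk factors
    against outcome precision, w_j = sum_k |beta_x[j, k]| / se_y[j]; the
    ``outcome`` mode uses |beta_y[j]| / se_y[j] instead.
    """
    if ld.variant_ids != data.variant_ids:
        raise ValidationError("data and LD matrix are not aligned")
    if np.any(data.se_y <= 0):
        raise ValidationError("outcome standard errors must be strictly positive")
    if weight_mode == "exposure":
        w = np.abs(data.beta_x).sum(axis=1) / data.se_y
    elif weight_mode == "outcome":
        w = np.abs(data.beta_y) / data.se_y
    else:
        raise ValidationError(f"unknown weight_mode {weight_mode!r}")
    return ld.rho * np.outer(w, w)


def select_components(psi: np.ndarray, variance_threshold: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Retain the leading eigenvectors of Psi explaining the target variance.

    Returns (loadings, eigenvalues, p) with eigenvalues in descending order;
    p is the smallest integer whose cumulative eigenvalue share (relative to
    the sum of non-negative eigenvalues) reaches the threshold.  Columns are
    sign-fixed so their largest-magnitude entry is positive.
    """
    if not 0 < variance_threshold <= 1:
        raise ValidationError("variance_threshold must lie in (0, 1]")
    psi = np.asarray(psi, dtype=float)
    if not np.all(np.isfinite(psi)):
        raise ValidationError("non-finite entries in the weighted correlation matrix")
    eigval, eigvec = np.linalg.eigh(psi)
    eigval, eigvec = eigval[::-1], eigvec[:, ::-1]

    total = np.clip(eigval, 0.0, None).sum()
    if total <= 0:
        raise ValidationError("weighted correlation matrix has no positive eigenvalues")
    frac = np.cumsum(np.clip(eigval, 0.0, None)) / total
    p = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    # never keep numerically null directions
    floor = _RELATIVE_EIG_FLOOR * eigval[0]
    p = min(p, int(np.sum(eigval > floor)))
    p = max(p, 1)

    loadings = eigvec[:, :p].copy()
    for c in range(p):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
    return loadings, eigval, p


def transform_associations(
    data: RegionalSummaryData,
    ld: LDMatrix,
    loadings: np.ndarray,
    trait_cor: TraitCorrelation | None = None,
    eigenvalues: np.ndarray | None = None,
    variance_threshold: float = float("nan"),
) -> PCReduction:
    """Transform marginal associations into PC-scale multivariable coefficients."""
    j, p = loadings.shape
    k = data.n_traits
    if j != data.n_variants:
        raise ValidationError("loadings row count does not match number of variants")
    if trait_cor is None:
        trait_cor = TraitCorrelation.identity(k)
    if trait_cor.matrix.shape[0] != k:
        raise ValidationError("trait correlation dimension does not match risk factors")

    m = loadings.T @ ld.rho           # p x J
    s = m @ loadings                  # Gram matrix S = L' rho L
    if np.linalg.cond(s) > _MAX_CONDITION:
        raise ValidationError(
            "PC-scale Gram matrix is numerically singular; lower the variance threshold"
        )
    s_inv_lt = np.linalg.solve(s, loadings.T)       # S^-1 L'
    s_inv_m = np.linalg.solve(s, m)                 # S^-1 L' rho

    beta_y_pc = s_inv_lt @ data.beta_y
    beta_x_pc = s_inv_lt @ data.beta_x

    # cov(beta_y) = D_y rho D_y; omega_yy = (S^-1 L') D_y rho D_y (L S^-1)
    b_y = s_inv_lt * data.se_y[None, :]             # S^-1 L' D_y
    omega_yy = b_y @ ld.rho @ b_y.T
    omega_yy = 0.5 * (omega_yy + omega_yy.T)

    b_x = [s_inv_lt * data.se_x[:, kk][None, :] for kk in range(k)]   # S^-1 L' D_xk
    omega_xx = np.empty((k, k, p, p))
    for a in range(k):
        rho_bxa = ld.rho @ b_x[a].T
        for b in range(a, k):
            block = trait_cor.matrix[a, b] * (b_x[b] @ rho_bxa)
            omega_xx[b, a] = block
            omega_xx[a, b] = block.T
    # enforce exact symmetry of the diagonal blocks
    for a in range(k):
        omega_xx[a, a] = 0.5 * (omega_xx[a, a] + omega_xx[a, a].T)

    od_basis = s_inv_m @ s_inv_m.T                  # S^-1 L' rho^2 L S^-1
    od_basis = 0.5 * (od_basis + od_basis.T)

    if eigenvalues is None:
        eigenvalues = np.full(j, np.nan)
    return PCReduction(
        loadings=loadings,
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        p=p,
        variance_threshold=variance_threshold,
        beta_x_pc=beta_x_pc,
        beta_y_pc=beta_y_pc,
        omega_xx=omega_xx,
        omega_yy=omega_yy,
        s_matrix=s,
        overdispersion_basis=od_basis,
        trait_names=list(data.trait_names),
        n_y=float(data.n_y),
    )


def pc_reduce(
    data: RegionalSummaryData,
    ld: LDMatrix,
    variance_threshold: float = 0.99,
    trait_cor: TraitCorrelation | None = None,
    weight_mode: str = "exposure",
) -> PCReduction:
    """Full reduction: weighted matrix -> component selection -> transform."""
    psi = weighted_correlation_matrix(data, ld, weight_mode=weight_mode)
    loadings, eigval, _p = select_components(psi, variance_threshold)
    return transform_associations(
        data, ld, loadings,
        trait_cor=trait_cor,
        eigenvalues=eigval,
        variance_threshold=variance_threshold,
    )
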