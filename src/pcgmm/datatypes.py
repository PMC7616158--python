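"""Core containers shared across the package.

All containers are thin dataclasses around numpy arrays.  Validation happens
at construction time via ``__post_init__`` so that downstream numerical code
can assume clean inputs (aligned row order, strictly positive standard
errors, symmetric correlation matrices).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Variant",
    "RegionalSummaryData",
    "LDMatrix",
    "TraitCorrelation",
    "PCReduction",
    "PCGMMFit",
    "ConditionalFResult",
    "ColocResult",
    "BMAResult",
    "SimulationSpec",
]

_VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


class ConfigurationError(ValueError):
    """Raised when user-supplied configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class Variant:
    """A genetic variant with 1-based GRCh-style coordinates."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValidationError(f"variant {self.id}: pos must be positive, got {self.pos}")
        ea, oa = self.effect_allele.upper(), self.other_allele.upper()
        if ea == oa:
            raise ValidationError(f"variant {self.id}: effect and other allele are identical ({ea})")
        for allele in (ea, oa):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValidationError(f"variant {self.id}: invalid allele string {allele!r}")
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)

    @property
    def is_palindromic(self) -> bool:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if len(self.effect_allele) != 1 or len(self.other_allele) != 1:
            return False
        return comp[self.effect_allele] == self.other_allele


@dataclass
class RegionalSummaryData:
    """Marginal GWAS associations for J variants with K risk factors and one outcome.

    ``beta_x``/``se_x`` are (J, K); ``beta_y``/``se_y`` are length J.  Row
    order is shared with ``variants``.
    """

    variants: list[Variant]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    n_x: np.ndarray
    n_y: float
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        self.beta_y = np.asarray(self.beta_y, dtype=float).ravel()
        self.se_y = np.asarray(self.se_y, dtype=float).ravel()
        self.n_x = np.asarray(self.n_x, dtype=float).ravel()
        j, k = self.beta_x.shape
        if len(self.variants) != j:
            raise ValidationError(f"{len(self.variants)} variants but beta_x has {j} rows")
        if self.se_x.shape != (j, k) or self.beta_y.shape != (j,) or self.se_y.shape != (j,):
            raise ValidationError("summary-statistic array shapes are inconsistent")
        if len(self.trait_names) != k:
            raise ValidationError(f"{len(self.trait_names)} trait names for K={k} risk factors")
        if self.n_x.shape != (k,):
            raise ValidationError("n_x must give one sample size per risk factor")
        for arr, name in ((self.beta_x, "beta_x"), (self.se_x, "se_x"),
                          (self.beta_y, "beta_y"), (self.se_y, "se_y")):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in {name}")
        bad = np.where(~(self.se_x > 0).all(axis=1) | ~(self.se_y > 0))[0]
        if bad.size:
            ids = ", ".join(self.variants[i].id for i in bad[:5])
            raise ValidationError(f"non-positive standard error for variant(s): {ids}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_traits(self) -> int:
        return self.beta_x.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset(self, index: Sequence[int]) -> "RegionalSummaryData":
        idx = np.asarray(index, dtype=int)
        return RegionalSummaryData(
            variants=[self.variants[i] for i in idx],
            beta_x=self.beta_x[idx],
            se_x=self.se_x[idx],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            n_x=self.n_x.copy(),
            n_y=self.n_y,
            trait_names=list(self.trait_names),
        )


@dataclass
class LDMatrix:
    """Signed variant correlation matrix aligned to a variant-id list."""

    variant_ids: list[str]
    rho: np.ndarray
    psd_repaired: bool = False
    min_eigenvalue_before: float = float("nan")

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        j = len(self.variant_ids)
        if self.rho.shape != (j, j):
            raise ValidationError(f"LD matrix shape {self.rho.shape} does not match {j} variant ids")
        if not np.allclose(self.rho, self.rho.T, atol=1e-8):
            raise ValidationError("LD matrix is asymmetric beyond 1e-8")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-6):
            raise ValidationError("LD matrix diagonal must be 1")
        # slight overshoot beyond |r| = 1 (float noise, shrinkage-free panel
        # estimates) is tolerated here and resolved by repair_psd
        if np.max(np.abs(self.rho)) > 1 + 5e-3:
            raise ValidationError("LD entries must lie in [-1, 1]")
        # exact unit diagonal and symmetry after the tolerance check
        self.rho = 0.5 * (self.rho + self.rho.T)
        np.fill_diagonal(self.rho, 1.0)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset(self, index: Sequence[int]) -> "LDMatrix":
        idx = np.asarray(index, dtype=int)
        return LDMatrix(
            variant_ids=[self.variant_ids[i] for i in idx],
            rho=self.rho[np.ix_(idx, idx)],
            psd_repaired=self.psd_repaired,
            min_eigenvalue_before=self.min_eigenvalue_before,
        )


@dataclass
class TraitCorrelation:
    """K x K phenotypic correlation matrix of the risk factors."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        k = self.matrix.shape[0]
        if self.matrix.shape != (k, k):
            raise ValidationError("trait correlation matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValidationError("trait correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-8):
            raise ValidationError("trait correlation matrix must have unit diagonal")
        if np.max(np.abs(self.matrix)) > 1 + 1e-8:
            raise ValidationError("trait correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(self.matrix).min() < -1e-8:
            raise ValidationError("trait correlation matrix must be positive semi-definite")

    @classmethod
    def identity(cls, k: int) -> "TraitCorrelation":
        return cls(np.eye(k))


@dataclass
class PCReduction:
    """PC-scale multivariable coefficients and their variance structure.

    ``omega_xx`` is a (K, K) block array of (p, p) matrices: block (k, l)
    is the covariance between the PC-scale coefficients of risk factors k
    and l.  ``s_matrix`` is the PC-scale Gram matrix S = L' rho L and
    ``overdispersion_basis`` is S^-1 L' rho^2 L S^-1, the PC-scale image of
    an isotropic variant-scale direct-effect covariance.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    p: int
    variance_threshold: float
    beta_x_pc: np.ndarray
    beta_y_pc: np.ndarray
    omega_xx: np.ndarray
    omega_yy: np.ndarray
    s_matrix: np.ndarray
    overdispersion_basis: np.ndarray
    trait_names: list[str] = field(default_factory=list)
    n_y: float = float("nan")

    @property
    def n_traits(self) -> int:
        return self.beta_x_pc.shape[1]


@dataclass
class PCGMMFit:
    """Result of a (robust or unrobust) PC-GMM fit."""

    theta: np.ndarray
    se_theta: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    kappa2: float
    robust: bool
    q_stat: float
    q_df: int
    q_pvalue: float | None
    n_pcs: int
    converged: bool
    pvalues: np.ndarray | None = None
    trait_names: list[str] = field(default_factory=list)


@dataclass
class ConditionalFResult:
    """Per-risk-factor conditional F-statistics with chi-squared p-values."""

    f_stats: np.ndarray
    df: int
    pvalues: np.ndarray
    n_pcs: int
    trait_names: list[str] = field(default_factory=list)


@dataclass
class ColocResult:
    """Posterior probabilities over the five colocalization hypotheses."""

    posteriors: np.ndarray  # (H0, H1, H2, H3, H4)
    priors: tuple[float, float, float]
    conditional_h3: float

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.posteriors.shape != (5,):
            raise ValidationError("posteriors must contain exactly the five hypotheses H0..H4")
        if abs(self.posteriors.sum() - 1.0) > 1e-10:
            raise ValidationError("posteriors must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {f"H{i}": float(p) for i, p in enumerate(self.posteriors)}


@dataclass
class BMAResult:
    """Bayesian model averaging over risk-factor subsets."""

    models: list[tuple[tuple[int, ...], float]]  # sorted by posterior, descending
    inclusion: np.ndarray
    prior_p: float
    trait_names: list[str] = field(default_factory=list)


@dataclass
class SimulationSpec:
    """Parameters of the two-sample linear IV data-generating process.

    ``xi`` controls phenotypic heterogeneity: at 0, risk factors 2 and 3
    share the same causal instruments (a rank reduction); at 1 each risk
    factor has its own instruments.  ``kappa2`` scales the variance of
    per-variant direct effects on the outcome (overdispersion).
    """

    xi: float = 1.0
    kappa2: float = 0.0
    n_x: int = 20_000
    n_y: int = 20_000
    theta: tuple[float, float, float] = (-1 / 3, 0.0, 1 / 3)
    n_instruments: int = 200
    n_causal: int = 15
    beta_scale: float = 0.2
    err_cor: float = 0.3
    conf_cor: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi <= 1.0:
            raise ValidationError(f"xi must lie in [0, 1], got {self.xi}")
        if self.kappa2 < 0:
            raise ValidationError("kappa2 must be non-negative")
        if self.n_x < 100 or self.n_y < 100:
            raise ValidationError("sample sizes below 100 are not supported")
        if self.n_causal > self.n_instruments:
            raise ValidationError("more causal instruments than instruments")
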