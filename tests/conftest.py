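import logging

import numpy as np
import pytest

from pcgmm.datatypes import (
    LDMatrix,
    PCReduction,
    RegionalSummaryData,
    TraitCorrelation,
    Variant,
)

logging.getLogger("pcgmm").setLevel(logging.ERROR)


def make_variants(n, chrom="6", start=39_000_000, step=500, ea="A", oa="G"):
    return [
        Variant(id=f"rs{i + 1}", chrom=chrom, pos=start + step * i,
                effect_allele=ea, other_allele=oa)
        for i in range(n)
    ]


def make_summary(beta_x, se_x, beta_y, se_y, n_x=10_000.0, n_y=10_000.0, variants=None):
    beta_x = np.atleast_2d(np.asarray(beta_x, float))
    k = beta_x.shape[1]
    j = beta_x.shape[0]
    return RegionalSummaryData(
        variants=variants or make_variants(j),
        beta_x=beta_x,
        se_x=np.atleast_2d(np.asarray(se_x, float)),
        beta_y=beta_y,
        se_y=se_y,
        n_x=np.repeat(float(n_x), k),
        n_y=float(n_y),
        trait_names=[f"X{i + 1}" for i in range(k)],
    )


def ar1_ld(j, rho, ids=None):
    r = rho ** np.abs(np.subtract.outer(np.arange(j), np.arange(j)))
    return LDMatrix(variant_ids=ids or [f"rs{i + 1}" for i in range(j)], rho=r)


def make_reduction(beta_x_pc, beta_y_pc, omega_yy=None, omega_xx=None,
                   s_matrix=None, od_basis=None, n_y=float("nan")):
    """Assemble a PCReduction directly from PC-scale pieces (unit defaults)."""
    beta_x_pc = np.atleast_2d(np.asarray(beta_x_pc, float))
    p, k = beta_x_pc.shape
    if omega_yy is None:
        omega_yy = np.eye(p)
    if omega_xx is None:
        omega_xx = np.zeros((k, k, p, p))
        for a in range(k):
            omega_xx[a, a] = np.eye(p)
    if s_matrix is None:
        s_matrix = np.eye(p)
    if od_basis is None:
        od_basis = np.eye(p)
    return PCReduction(
        loadings=np.eye(p),
        eigenvalues=np.ones(p),
        p=p,
        variance_threshold=1.0,
        beta_x_pc=beta_x_pc,
        beta_y_pc=np.asarray(beta_y_pc, float),
        omega_xx=np.asarray(omega_xx, float),
        omega_yy=np.asarray(omega_yy, float),
        s_matrix=np.asarray(s_matrix, float),
        overdispersion_basis=np.asarray(od_basis, float),
        trait_names=[f"X{i + 1}" for i in range(k)],
        n_y=n_y,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim_ld():
    """A 60-variant near-singular LD matrix usable for fast simulation tests."""
    from pcgmm.simulate import synthetic_ld

    return synthetic_ld(j=60, n_blocks=6, within_block_rho=0.6, rank=20,
                        tail_share=1e-6, seed=3)


@pytest.fixture(scope="session")
def identity_trait_cor():
    return TraitCorrelation.identity(3)
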