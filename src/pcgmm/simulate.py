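"""Two-sample summary-data simulator for the linear IV model with 3 risk factors.

The data-generating process: J = 200 correlated instruments Z (multivariate
normal, correlation from a block-structured synthetic LD matrix), of which
15 mutually weakly correlated (R^2 <= 0.2) instruments carry fixed effects
of size 0.2 on at least one risk factor:

    X1 = 0.2 * sum(Z_1..5)                                    + V1
    X2 = 0.2 * xi * sum(Z_6..10) + 0.2 * (1 - xi) * sum(Z_11..15) + V2
    X3 = 0.2 * sum(Z_11..15)                                  + V3

with unit-variance errors V correlated at 0.3 pairwise.  The outcome is

    Y = theta1 X1 + theta2 X2 + theta3 X3 + Z' alpha + U

with var(U) = 1, cor(V_k, U) = 0.2, and per-variant direct (pleiotropic)
effects alpha ~ N(0, kappa2 / n_Y) drawn once per replicate.  xi in [0, 1]
indexes phenotypic heterogeneity (xi = 0 makes risk factors 2 and 3 share
the same causal instruments, a rank reduction) and kappa2 >= 0 indexes
overdispersion heterogeneity.  True effects default to (-1/3, 0, 1/3).

Summary statistics are computed by actual per-variant univariable
regressions: exposures in sample 1 (size n_x), outcome in an independent
sample 2 (size n_y).  The empirical exposure correlation from sample 1 is
returned as the trait-correlation input to the PC transform.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    LDMatrix,
    RegionalSummaryData,
    SimulationSpec,
    TraitCorrelation,
    ValidationError,
    Variant,
)
from .estimation import fit_robust, fit_unrobust
from .strength import all_conditional_f
from .transform import pc_reduce

__all__ = [
    "synthetic_ld",
    "causal_indices",
    "generate_two_sample",
    "TwoSampleResult",
    "run_cell",
    "run_grid",
    "GridResult",
]

CAUSAL_R2_MAX = 0.2
SIM_VARIANCE_THRESHOLD = 0.9999


def causal_indices(n_instruments: int = 200, n_blocks: int = 10, n_causal: int = 15) -> np.ndarray:
    """Deterministic placement of causal instruments, spread across LD blocks.

    Blocks receive causal variants round-robin; when a block holds more
    than one, within-block offsets are spaced half a block apart so the
    AR(1) decay keeps the causal set mutually weakly correlated.
    """
    block = n_instruments // n_blocks
    layers = -(-n_causal // n_blocks)  # ceil
    spacing = block // layers
    if spacing == 0:
        raise ValidationError("cannot place distinct causal instruments; use more blocks")
    idx: list[int] = []
    for i in range(n_causal):
        b = i % n_blocks
        layer = i // n_blocks
        offset = (2 + layer * spacing) % block
        idx.append(b * block + offset)
    if len(set(idx)) != n_causal:
        raise ValidationError("cannot place distinct causal instruments; use more blocks")
    return np.array(sorted(idx))


def synthetic_ld(
    j: int = 200,
    n_blocks: int = 10,
    within_block_rho: float = 0.9,
    seed: int = 0,
    between_block_rho: float | None = None,
    jitter: float = 0.05,
    n_causal: int = 15,
    rank: int | None = 30,
    tail_share: float = 2e-5,
) -> LDMatrix:
    """Block-structured stand-in for a measured gene-region LD matrix.

    Within-block correlations decay as AR(1) in position distance; a uniform
    between-block component and a seeded low-rank perturbation add the mild
    long-range structure seen in real regions.  Both extras scale with
    ``within_block_rho`` so a zero within-block correlation yields exactly
    the identity.

    Measured regional LD is ill-conditioned: a few dozen haplotype
    dimensions carry essentially all the variance.  To emulate that, the
    spectrum is truncated to an effective ``rank`` with the remaining
    eigenvalues rescaled to carry only ``tail_share`` of the total variance
    (skipped when ``within_block_rho`` is 0 or ``rank`` is None).  The
    designated causal instruments are verified to be mutually weakly
    correlated (R^2 <= 0.2).
    """
    if not 1 <= n_blocks <= j:
        raise ValidationError("need 1 <= n_blocks <= J")
    if not 0 <= within_block_rho < 1:
        raise ValidationError("within_block_rho must lie in [0, 1)")
    if between_block_rho is None:
        between_block_rho = 0.12 * within_block_rho
    b = float(between_block_rho)
    c = float(jitter) * within_block_rho
    if not 0 <= b + c < 1:
        raise ValidationError("between-block correlation plus jitter must lie in [0, 1)")

    block = j // n_blocks
    pos = np.arange(j)
    block_id = np.minimum(pos // block, n_blocks - 1)
    dist = np.abs(pos[:, None] - pos[None, :])
    same = block_id[:, None] == block_id[None, :]
    structural = np.where(same, within_block_rho**dist, 0.0)

    if n_causal:
        # cap the jitter weight so the causal set stays weakly correlated
        # (R^2 <= 0.2) for every jitter seed; jitter entries are bounded by c
        idx0 = causal_indices(j, n_blocks, n_causal)
        struct0 = (1.0 - b) * structural + b
        off0 = struct0[np.ix_(idx0, idx0)].copy()
        np.fill_diagonal(off0, 0.0)
        headroom = np.sqrt(CAUSAL_R2_MAX) - float(np.max(np.abs(off0))) - 0.01
        c = float(np.clip(min(c, headroom), 0.0, None))

    rho = (1.0 - b - c) * structural + b
    if c > 0:
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(j, max(j // 4, 2)))
        w = a @ a.T
        d = np.sqrt(np.diag(w))
        rho = rho + c * (w / np.outer(d, d))
    np.fill_diagonal(rho, 1.0)

    if rank is not None and 0 < rank < j and within_block_rho > 0:
        if not 0 < tail_share < 1:
            raise ValidationError("tail_share must lie in (0, 1)")
        eigval, eigvec = np.linalg.eigh(rho)
        eigval, eigvec = np.clip(eigval[::-1], 1e-12, None), eigvec[:, ::-1]
        tail = eigval[rank:]
        eigval[rank:] = tail * (tail_share * eigval.sum() / tail.sum())
        rho = (eigvec * eigval) @ eigvec.T
        d = np.sqrt(np.diag(rho))
        rho = rho / np.outer(d, d)
        rho = 0.5 * (rho + rho.T)
        np.fill_diagonal(rho, 1.0)

    ld = LDMatrix(variant_ids=[f"v{i + 1:04d}" for i in range(j)], rho=rho)
    if n_causal:
        idx = causal_indices(j, n_blocks, n_causal)
        off = ld.rho[np.ix_(idx, idx)].copy()
        np.fill_diagonal(off, 0.0)
        worst = float(np.max(off**2))
        if worst > CAUSAL_R2_MAX:
            raise ValidationError(
                f"causal instruments too correlated (max R^2 = {worst:.3f} > {CAUSAL_R2_MAX}); "
                "lower within_block_rho or use more blocks"
            )
    return ld


def _variants_for(ld: LDMatrix) -> list[Variant]:
    return [
        Variant(id=vid, chrom="6", pos=39_000_000 + 500 * i,
                effect_allele="A", other_allele="G")
        for i, vid in enumerate(ld.variant_ids)
    ]


def _marginal_regressions(z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant univariable OLS (with intercept) of each trait on each variant.

    ``y`` may be (n,) or (n, T); returns betas and SEs of shape (J,) or (J, T).
    The centered genotype cross-products are shared across traits.
    """
    n = z.shape[0]
    zc = z - z.mean(axis=0)
    y2 = np.atleast_2d(y.T).T  # (n, T)
    yc = y2 - y2.mean(axis=0)
    szz = np.einsum("ij,ij->j", zc, zc)
    szy = zc.T @ yc                                # (J, T)
    beta = szy / szz[:, None]
    syy = np.einsum("it,it->t", yc, yc)
    ss_res = syy[None, :] - beta * szy
    se = np.sqrt(np.clip(ss_res, 0.0, None) / ((n - 2) * szz[:, None]))
    if y.ndim == 1:
        return beta[:, 0], se[:, 0]
    return beta, se


@dataclass
class TwoSampleResult:
    """Simulated summary data plus the sample trait correlation and causal set."""

    data: RegionalSummaryData
    trait_cor: TraitCorrelation
    causal_idx: np.ndarray
    sample_ld: LDMatrix | None = None


def generate_two_sample(
    spec: SimulationSpec,
    ld: LDMatrix,
    rng: np.random.Generator | None = None,
    chol: np.ndarray | None = None,
    causal_idx: np.ndarray | None = None,
    estimate_sample_ld: bool = False,
) -> TwoSampleResult:
    """Draw one replicate of two-sample summary statistics under the DGP."""
    j = spec.n_instruments
    if ld.n_variants != j:
        raise ValidationError(f"LD matrix has {ld.n_variants} variants, spec expects {j}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if chol is None:
        chol = np.linalg.cholesky(ld.rho + 1e-10 * np.eye(j))
    if causal_idx is None:
        causal_idx = causal_indices(j, n_causal=spec.n_causal)
    third = spec.n_causal // 3
    g1, g2, g3 = causal_idx[:third], causal_idx[third:2 * third], causal_idx[2 * third:]

    theta = np.asarray(spec.theta, dtype=float)
    b, xi = spec.beta_scale, spec.xi

    def exposures(z: np.ndarray, v: np.ndarray) -> np.ndarray:
        x1 = b * z[:, g1].sum(axis=1) + v[:, 0]
        x2 = b * xi * z[:, g2].sum(axis=1) + b * (1 - xi) * z[:, g3].sum(axis=1) + v[:, 1]
        x3 = b * z[:, g3].sum(axis=1) + v[:, 2]
        return np.column_stack([x1, x2, x3])

    # sample 1: exposures
    z1 = rng.standard_normal((spec.n_x, j)) @ chol.T
    cov_v = np.full((3, 3), spec.err_cor)
    np.fill_diagonal(cov_v, 1.0)
    v1 = rng.multivariate_normal(np.zeros(3), cov_v, size=spec.n_x,
                                 method="cholesky")
    x1 = exposures(z1, v1)

    # sample 2: outcome; (V1..V3, U) jointly normal with cor(V_k, U) = conf_cor
    z2 = rng.standard_normal((spec.n_y, j)) @ chol.T
    cov_vu = np.full((4, 4), spec.err_cor)
    cov_vu[:3, 3] = cov_vu[3, :3] = spec.conf_cor
    np.fill_diagonal(cov_vu, 1.0)
    vu = rng.multivariate_normal(np.zeros(4), cov_vu, size=spec.n_y,
                                 method="cholesky")
    x2 = exposures(z2, vu[:, :3])
    alpha = rng.normal(0.0, np.sqrt(spec.kappa2 / spec.n_y), size=j)
    y = x2 @ theta + z2 @ alpha + vu[:, 3]

    beta_x, se_x = _marginal_regressions(z1, x1)
    beta_y, se_y = _marginal_regressions(z2, y)

    data = RegionalSummaryData(
        variants=_variants_for(ld),
        beta_x=beta_x,
        se_x=se_x,
        beta_y=beta_y,
        se_y=se_y,
        n_x=np.repeat(float(spec.n_x), 3),
        n_y=float(spec.n_y),
        trait_names=["X1", "X2", "X3"],
    )
    trait_cor = TraitCorrelation(np.corrcoef(x1, rowvar=False))
    sample_ld = None
    if estimate_sample_ld:
        sample_ld = LDMatrix(variant_ids=list(ld.variant_ids),
                             rho=np.corrcoef(z1, rowvar=False))
    return TwoSampleResult(data=data, trait_cor=trait_cor,
                           causal_idx=np.asarray(causal_idx), sample_ld=sample_ld)


def run_cell(
    xi: float,
    kappa2: float,
    n: int,
    reps: int,
    seed: int,
    ld: LDMatrix | None = None,
    variance_threshold: float = SIM_VARIANCE_THRESHOLD,
    do_robust: bool = True,
    do_unrobust: bool = True,
    do_condf: bool = True,
    alpha_level: float = 0.05,
    use_sample_ld: bool = False,
    n_blocks: int = 10,
    n_causal: int = 15,
) -> dict:
    """Run one (xi, kappa2, n) simulation cell and aggregate replicate results.

    Tests of theta are two-sided Wald at the nominal ``alpha_level`` against
    the true null/non-null values; conditional F-tests compare the minimized
    quadratic form with the 0.95 chi-squared quantile of its null.
    """
    if ld is None:
        ld = synthetic_ld()
    chol = np.linalg.cholesky(ld.rho + 1e-10 * np.eye(ld.n_variants))
    causal = causal_indices(ld.n_variants, n_blocks, n_causal)
    theta_true = np.array([-1 / 3, 0.0, 1 / 3])
    z_crit = stats.norm.ppf(1 - alpha_level / 2)

    thetas_r, thetas_u = [], []
    rej_r = np.zeros(3)
    rej_u = np.zeros(3)
    rej_f = np.zeros(3)
    f_sum = np.zeros(3)
    kappa2_sum = 0.0
    q_sum = 0.0
    n_pcs_sum = 0
    fails = 0
    n_r = n_u = n_f = 0

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(child_seeds[r])
        spec = SimulationSpec(xi=xi, kappa2=kappa2, n_x=n, n_y=n, seed=0,
                              n_instruments=ld.n_variants, n_causal=n_causal)
        sim = generate_two_sample(spec, ld, rng=rng, chol=chol, causal_idx=causal,
                                  estimate_sample_ld=use_sample_ld)
        use_ld = sim.sample_ld if use_sample_ld else ld
        try:
            red = pc_reduce(sim.data, use_ld, variance_threshold=variance_threshold,
                            trait_cor=sim.trait_cor)
            n_pcs_sum += red.p
            if do_condf:
                cf = all_conditional_f(red)
                q_crit = stats.chi2.ppf(0.95, cf.df)
                rej_f += (cf.f_stats * cf.df) > q_crit
                f_sum += cf.f_stats
                n_f += 1
            if do_unrobust:
                fit_u = fit_unrobust(red, seed=1)
                thetas_u.append(fit_u.theta)
                rej_u += np.abs(fit_u.theta - np.array([0.0, 0.0, 0.0])) / fit_u.se_theta > z_crit
                q_sum += fit_u.q_stat
                n_u += 1
            if do_robust:
                fit_r = fit_robust(red, seed=1)
                thetas_r.append(fit_r.theta)
                rej_r += np.abs(fit_r.theta) / fit_r.se_theta > z_crit
                kappa2_sum += fit_r.kappa2
                n_r += 1
        except (ValidationError, np.linalg.LinAlgError):
            fails += 1
            continue

    out: dict = {
        "xi": xi, "kappa2": kappa2, "n": n, "reps": reps,
        "n_failed": fails,
        "mean_n_pcs": n_pcs_sum / max(reps - fails, 1),
        "theta_true_1": theta_true[0], "theta_true_2": theta_true[1],
        "theta_true_3": theta_true[2],
    }
    if do_condf and n_f:
        for k in range(3):
            out[f"condf_reject_{k + 1}"] = rej_f[k] / n_f
            out[f"condf_mean_{k + 1}"] = f_sum[k] / n_f
    if do_unrobust and n_u:
        arr = np.asarray(thetas_u)
        for k in range(3):
            out[f"unrobust_bias_{k + 1}"] = float(arr[:, k].mean() - theta_true[k])
            out[f"unrobust_rmse_{k + 1}"] = float(np.sqrt(((arr[:, k] - theta_true[k]) ** 2).mean()))
            out[f"unrobust_reject_{k + 1}"] = rej_u[k] / n_u
        out["unrobust_mean_q"] = q_sum / n_u
    if do_robust and n_r:
        arr = np.asarray(thetas_r)
        for k in range(3):
            out[f"robust_mean_{k + 1}"] = float(arr[:, k].mean())
            out[f"robust_mc_se_{k + 1}"] = float(arr[:, k].std(ddof=1) / np.sqrt(len(arr)))
            out[f"robust_bias_{k + 1}"] = float(arr[:, k].mean() - theta_true[k])
            out[f"robust_rmse_{k + 1}"] = float(np.sqrt(((arr[:, k] - theta_true[k]) ** 2).mean()))
            out[f"robust_reject_{k + 1}"] = rej_r[k] / n_r
        out["mean_kappa2_hat"] = kappa2_sum / n_r
    return out


@dataclass
class GridResult:
    """Aggregated simulation results, one row per (xi, kappa2, n) cell."""

    table: pd.DataFrame
    seed: int
    variance_threshold: float = SIM_VARIANCE_THRESHOLD
    notes: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_grid(
    xi_grid,
    kappa2_grid,
    n_grid,
    reps: int = 200,
    variance_threshold: float = SIM_VARIANCE_THRESHOLD,
    seed: int = 0,
    ld: LDMatrix | None = None,
    **cell_kwargs,
) -> GridResult:
    """Sweep the simulation over a (xi, kappa2, n) grid.

    Per-cell seeds are derived from the master seed and the cell index so
    results are reproducible and cells are independent.
    """
    if reps < 50:
        raise ValidationError("use at least 50 replicates per cell")
    if ld is None:
        ld = synthetic_ld()
    rows = []
    notes = []
    cell = 0
    for xi in np.atleast_1d(xi_grid):
        for kappa2 in np.atleast_1d(kappa2_grid):
            for n in np.atleast_1d(n_grid):
                cell_seed = int(np.random.SeedSequence([seed, cell]).generate_state(1)[0] % (2**31))
                row = run_cell(float(xi), float(kappa2), int(n), reps, cell_seed,
                               ld=ld, variance_threshold=variance_threshold, **cell_kwargs)
                if row["n_failed"] > 0.1 * reps:
                    notes.append(
                        f"cell xi={xi} kappa2={kappa2} n={n}: "
                        f"{row['n_failed']}/{reps} replicates failed"
                    )
                rows.append(row)
                cell += 1
    return GridResult(table=pd.DataFrame(rows), seed=seed,
                      variance_threshold=variance_threshold, notes=notes)
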