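"""Reading, validation, harmonization and region filtering of GWAS summary data.

Summary statistics arrive as tab- or comma-delimited text with one row per
variant; LD matrices arrive either as a square whitespace-delimited matrix
with a header row of variant ids, or as long-format (id1, id2, r) triplets
of signed correlations.  Rows with missing effect sizes are dropped (never
imputed) and the drop count is logged.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ConfigurationError,
    LDMatrix,
    RegionalSummaryData,
    ValidationError,
    Variant,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "harmonize",
    "filter_region",
    "prune_and_screen",
    "repair_psd",
    "min_risk_factor_pvalues",
    "write_manifest",
]

_META_COLUMNS = ("variant", "chrom", "pos", "effect_allele", "other_allele")


def _default_column_map(columns: Sequence[str]) -> dict:
    """Infer the column map from conventional column names.

    Risk-factor traits are discovered from paired ``beta_<name>``/``se_<name>``
    columns; the outcome uses ``beta_out``/``se_out``.
    """
    traits = []
    for col in columns:
        if col.startswith("beta_") and col != "beta_out":
            name = col[len("beta_"):]
            if f"se_{name}" in columns:
                traits.append(name)
    return {
        "variant": "variant",
        "chrom": "chrom",
        "pos": "pos",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "traits": {t: {"beta": f"beta_{t}", "se": f"se_{t}"} for t in traits},
        "outcome": {"beta": "beta_out", "se": "se_out"},
    }


def read_summary_stats(
    path: str | Path,
    column_map: Mapping | None = None,
    n_x: Sequence[float] | None = None,
    n_y: float = float("nan"),
) -> RegionalSummaryData:
    """Read and validate per-variant summary associations.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    column_map
        Mapping naming the metadata columns and, under ``traits`` and
        ``outcome``, the beta/se column for each trait.  When omitted the
        conventional ``beta_<name>``/``se_<name>``/``beta_out``/``se_out``
        names are assumed.
    n_x, n_y
        Per-risk-factor and outcome sample sizes (optional; may also be
        carried in ``n_<name>`` / ``n_out`` columns, in which case the
        median across variants is used).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cmap = dict(column_map) if column_map is not None else _default_column_map(df.columns)

    for key in _META_COLUMNS:
        col = cmap.get(key, key)
        if col not in df.columns:
            raise ConfigurationError(f"mandatory column {col!r} (for {key}) missing from {path.name}")

    traits: Mapping[str, Mapping[str, str]] = cmap.get("traits", {})
    if not traits:
        raise ConfigurationError("column_map defines no risk-factor trait columns")
    outcome = cmap.get("outcome", {"beta": "beta_out", "se": "se_out"})
    value_cols: list[str] = []
    for tname, tcols in traits.items():
        for role in ("beta", "se"):
            col = tcols[role]
            if col not in df.columns:
                raise ConfigurationError(f"mandatory column {col!r} (trait {tname}) missing")
            value_cols.append(col)
    for role in ("beta", "se"):
        col = outcome[role]
        if col not in df.columns:
            raise ConfigurationError(f"mandatory column {col!r} (outcome) missing")
        value_cols.append(col)

    n_before = len(df)
    df = df.dropna(subset=value_cols)
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d/%d rows with missing beta/se values", dropped, n_before)

    se_cols = [traits[t]["se"] for t in traits] + [outcome["se"]]
    bad = df[(df[se_cols] <= 0).any(axis=1)]
    if len(bad):
        vid = str(bad.iloc[0][cmap.get("variant", "variant")])
        raise ValidationError(f"non-positive standard error for variant {vid}")

    variants = [
        Variant(
            id=str(r[cmap.get("variant", "variant")]),
            chrom=str(r[cmap.get("chrom", "chrom")]),
            pos=int(r[cmap.get("pos", "pos")]),
            effect_allele=str(r[cmap.get("effect_allele", "effect_allele")]),
            other_allele=str(r[cmap.get("other_allele", "other_allele")]),
        )
        for r in df.to_dict("records")
    ]
    trait_names = list(traits)
    beta_x = np.column_stack([df[traits[t]["beta"]].to_numpy(float) for t in trait_names])
    se_x = np.column_stack([df[traits[t]["se"]].to_numpy(float) for t in trait_names])

    if n_x is None:
        n_x_arr = np.array(
            [df[f"n_{t}"].median() if f"n_{t}" in df.columns else np.nan for t in trait_names]
        )
    else:
        n_x_arr = np.asarray(n_x, dtype=float)
    if np.isnan(n_y) and "n_out" in df.columns:
        n_y = float(df["n_out"].median())

    return RegionalSummaryData(
        variants=variants,
        beta_x=beta_x,
        se_x=se_x,
        beta_y=df[outcome["beta"]].to_numpy(float),
        se_y=df[outcome["se"]].to_numpy(float),
        n_x=n_x_arr,
        n_y=n_y,
        trait_names=trait_names,
    )


def write_summary_stats(data: RegionalSummaryData, path: str | Path) -> None:
    """Write a RegionalSummaryData back to the conventional TSV layout."""
    cols: dict[str, object] = {
        "variant": data.variant_ids,
        "chrom": [v.chrom for v in data.variants],
        "pos": [v.pos for v in data.variants],
        "effect_allele": [v.effect_allele for v in data.variants],
        "other_allele": [v.other_allele for v in data.variants],
    }
    for k, name in enumerate(data.trait_names):
        cols[f"beta_{name}"] = data.beta_x[:, k]
        cols[f"se_{name}"] = data.se_x[:, k]
        cols[f"n_{name}"] = np.repeat(data.n_x[k], data.n_variants)
    cols["beta_out"] = data.beta_y
    cols["se_out"] = data.se_y
    cols["n_out"] = np.repeat(data.n_y, data.n_variants)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read an LD matrix from square-with-header or long triplet format.

    Triplet files need exactly three columns (id1, id2, signed r); missing
    off-diagonal pairs default to 0 and the diagonal to 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] == 3 and not _looks_square(df):
        ids = list(dict.fromkeys(df.iloc[:, 0].astype(str)) | dict.fromkeys(df.iloc[:, 1].astype(str)))
        index = {v: i for i, v in enumerate(ids)}
        rho = np.eye(len(ids))
        for a, b, r in df.itertuples(index=False):
            i, j = index[str(a)], index[str(b)]
            rho[i, j] = rho[j, i] = float(r)
        np.fill_diagonal(rho, 1.0)
        return LDMatrix(variant_ids=ids, rho=rho)
    ids = [str(c) for c in df.columns]
    rho = df.to_numpy(dtype=float)
    if rho.shape[0] != rho.shape[1]:
        raise ValidationError(f"LD matrix in {path.name} is not square: {rho.shape}")
    return LDMatrix(variant_ids=ids, rho=rho)


def _looks_square(df: pd.DataFrame) -> bool:
    return df.shape[0] == df.shape[1] and all(
        pd.api.types.is_numeric_dtype(df[c]) for c in df.columns
    )


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.rho, columns=ld.variant_ids).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def harmonize(data: RegionalSummaryData, reference: Sequence[Variant]) -> RegionalSummaryData:
    """Reorder rows to a reference variant list, sign-flipping swapped alleles.

    A row whose effect/other alleles are swapped relative to the reference
    has every beta (all risk factors and the outcome) negated.  Palindromic
    variants (A/T or C/G) cannot be strand-checked from alleles alone; they
    are retained with a warning.
    """
    by_id = {v.id: i for i, v in enumerate(data.variants)}
    missing = [ref.id for ref in reference if ref.id not in by_id]
    if missing:
        raise ValidationError(f"variants missing from data: {', '.join(missing[:10])}")

    order: list[int] = []
    flip = np.ones(len(reference))
    new_variants: list[Variant] = []
    for out_row, ref in enumerate(reference):
        i = by_id[ref.id]
        v = data.variants[i]
        order.append(i)
        if (v.effect_allele, v.other_allele) == (ref.effect_allele, ref.other_allele):
            pass
        elif (v.effect_allele, v.other_allele) == (ref.other_allele, ref.effect_allele):
            flip[out_row] = -1.0
        else:
            raise ValidationError(
                f"variant {v.id}: alleles {v.effect_allele}/{v.other_allele} incompatible "
                f"with reference {ref.effect_allele}/{ref.other_allele}"
            )
        if ref.is_palindromic:
            logger.warning("palindromic variant %s retained; strand cannot be verified", ref.id)
        new_variants.append(ref)

    idx = np.asarray(order)
    return RegionalSummaryData(
        variants=new_variants,
        beta_x=data.beta_x[idx] * flip[:, None],
        se_x=data.se_x[idx],
        beta_y=data.beta_y[idx] * flip,
        se_y=data.se_y[idx],
        n_x=data.n_x.copy(),
        n_y=data.n_y,
        trait_names=list(data.trait_names),
    )


def filter_region(
    data: RegionalSummaryData, chrom: str, start: int, end: int, flank: int = 0
) -> RegionalSummaryData:
    """Keep variants on ``chrom`` with start-flank <= pos <= end+flank (1-based, inclusive)."""
    if start > end:
        raise ValidationError(f"region start {start} exceeds end {end}")
    if flank < 0:
        raise ValidationError("flank must be non-negative")
    lo, hi = start - flank, end + flank
    keep = [
        i for i, v in enumerate(data.variants)
        if v.chrom == str(chrom) and lo <= v.pos <= hi
    ]
    if not keep:
        raise ValidationError(
            f"no variants in {chrom}:{lo}-{hi}; widen the region or flank"
        )
    return data.subset(keep)


def min_risk_factor_pvalues(data: RegionalSummaryData) -> np.ndarray:
    """Per-variant minimum two-sided Wald p-value across the risk factors."""
    z = data.beta_x / data.se_x
    p = 2.0 * stats.norm.sf(np.abs(z))
    return p.min(axis=1)


def prune_and_screen(
    data: RegionalSummaryData,
    ld: LDMatrix,
    r2_max: float = 0.95,
    p_screen: float = 0.05,
) -> tuple[RegionalSummaryData, LDMatrix]:
    """Greedy LD pruning followed by a marginal-significance screen.

    Variants are ranked by their minimum risk-factor p-value (ties broken by
    position, then id).  Walking down that ranking, a variant is kept only
    if its squared correlation with every already-kept variant is <= r2_max.
    Kept variants whose minimum p-value is >= p_screen are then removed.
    """
    if not 0 < r2_max <= 1 or not 0 < p_screen <= 1:
        raise ValidationError("r2_max and p_screen must lie in (0, 1]")
    if ld.variant_ids != data.variant_ids:
        raise ValidationError("data and LD matrix are not aligned")

    pmin = min_risk_factor_pvalues(data)
    ranking = sorted(
        range(data.n_variants),
        key=lambda i: (pmin[i], data.variants[i].pos, data.variants[i].id),
    )
    rho2 = ld.rho**2
    kept: list[int] = []
    for i in ranking:
        if all(rho2[i, j] <= r2_max for j in kept):
            kept.append(i)
    # screen: strict inequality p < p_screen retains the variant
    survivors = sorted(i for i in kept if pmin[i] < p_screen)

    k = data.n_traits
    if len(survivors) < k + 1:
        raise ValidationError(
            f"only {len(survivors)} variants survive pruning/screening; "
            f"at least {k + 1} needed to identify {k} risk-factor effects"
        )
    logger.info(
        "pruning kept %d/%d variants; significance screen kept %d",
        len(kept), data.n_variants, len(survivors),
    )
    return data.subset(survivors), ld.subset(survivors)


def repair_psd(ld: LDMatrix) -> LDMatrix:
    """Project an indefinite correlation matrix to the PSD cone.

    Negative eigenvalues are clipped at zero and the matrix rescaled back to
    unit diagonal.  PSD inputs (smallest eigenvalue >= -1e-10) pass through
    untouched.
    """
    if not np.allclose(ld.rho, ld.rho.T, atol=1e-8):
        raise ValidationError("LD matrix asymmetric beyond 1e-8; cannot repair")
    eigval, eigvec = np.linalg.eigh(ld.rho)
    min_eig = float(eigval[0])
    if min_eig >= -1e-10:
        return LDMatrix(
            variant_ids=list(ld.variant_ids),
            rho=ld.rho,
            psd_repaired=False,
            min_eigenvalue_before=min_eig,
        )
    clipped = np.clip(eigval, 0.0, None)
    repaired = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    d[d == 0] = 1.0
    repaired = repaired / np.outer(d, d)
    repaired = 0.5 * (repaired + repaired.T)
    np.fill_diagonal(repaired, 1.0)
    return LDMatrix(
        variant_ids=list(ld.variant_ids),
        rho=repaired,
        psd_repaired=True,
        min_eigenvalue_before=min_eig,
    )


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest recording inputs, thresholds and versions."""
    import pcgmm

    manifest = {"pcgmm_version": pcgmm.__version__, "numpy_version": np.__version__}
    manifest.update(entries)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
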