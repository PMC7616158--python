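"""Run configuration and the end-to-end analysis pipeline.

A YAML config names the input files and thresholds; ``run_pipeline``
executes read -> harmonize -> region filter -> prune/screen -> PSD repair
-> PC transform -> conditional F -> (robust) PC-GMM fit, with optional
colocalization and model averaging, writing TSV results and a JSON run
manifest.  Identical config + inputs + seed give byte-identical outputs
(numbers are printed at 6 significant digits).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .bma import enumerate_bma
from .coloc import colocalize
from .datatypes import ConfigurationError, TraitCorrelation
from .estimation import fit_robust, fit_unrobust, heterogeneity_test
from .strength import all_conditional_f
from .transform import pc_reduce

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    summary_path: str = ""
    ld_path: str = ""
    out_dir: str = "pcgmm_results"
    column_map: dict | None = None
    trait_cor_path: str | None = None
    region: dict | None = None          # {chrom, start, end, flank}
    variance_threshold: float = 0.99
    r2_max: float = 0.95
    p_screen: float = 0.05
    robust: bool = True
    ci_level: float = 0.95
    seed: int = 0
    run_coloc: bool = False
    coloc_traits: tuple[int, int] = (0, 1)
    run_bma: bool = False
    bma_prior_p: float = 0.1
    bma_sigma_prior: float = 0.5
    n_x: list[float] | None = None
    n_y: float = float("nan")

    def validate(self) -> None:
        if not self.summary_path or not self.ld_path:
            raise ConfigurationError("summary_path and ld_path are required")
        if not 0 < self.variance_threshold <= 1:
            raise ConfigurationError(f"variance_threshold {self.variance_threshold} outside (0, 1]")
        if not 0 < self.r2_max <= 1:
            raise ConfigurationError(f"r2_max {self.r2_max} outside (0, 1]")
        if not 0 < self.p_screen <= 1:
            raise ConfigurationError(f"p_screen {self.p_screen} outside (0, 1]")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError(f"ci_level {self.ci_level} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _fit_table(fit, trait_names: list[str], n_variants: int) -> pd.DataFrame:
    return pd.DataFrame({
        "risk_factor": trait_names,
        "estimate": fit.theta,
        "se": fit.se_theta,
        "ci_lower": fit.ci_lower,
        "ci_upper": fit.ci_upper,
        "p_value": fit.pvalues,
        "n_pcs": fit.n_pcs,
        "n_variants": n_variants,
        "kappa2": fit.kappa2,
        "robust": fit.robust,
    })


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        data = sio.read_summary_stats(config.summary_path, config.column_map,
                                      n_x=config.n_x, n_y=config.n_y)
    except Exception as exc:
        raise ConfigurationError(f"[summary_io] reading {config.summary_path}: {exc}") from exc
    ld = sio.read_ld_matrix(config.ld_path)

    ref_order = {vid: i for i, vid in enumerate(ld.variant_ids)}
    have = [v for v in data.variants if v.id in ref_order]
    have.sort(key=lambda v: ref_order[v.id])
    data = sio.harmonize(data, have)
    ld = ld.subset([ref_order[v.id] for v in have])

    if config.region:
        r = config.region
        data_f = sio.filter_region(data, str(r["chrom"]), int(r["start"]), int(r["end"]),
                                   int(r.get("flank", 0)))
        keep = {v.id for v in data_f.variants}
        ld = ld.subset([i for i, vid in enumerate(ld.variant_ids) if vid in keep])
        data = data_f

    data, ld = sio.prune_and_screen(data, ld, config.r2_max, config.p_screen)
    ld = sio.repair_psd(ld)

    trait_cor = None
    if config.trait_cor_path:
        tc = pd.read_csv(config.trait_cor_path, sep=None, engine="python", header=None)
        trait_cor = TraitCorrelation(tc.to_numpy(float))

    red = pc_reduce(data, ld, variance_threshold=config.variance_threshold,
                    trait_cor=trait_cor)
    condf = all_conditional_f(red)
    pd.DataFrame({
        "risk_factor": condf.trait_names,
        "conditional_F": condf.f_stats,
        "df": condf.df,
        "p_value": condf.pvalues,
        "n_pcs": condf.n_pcs,
    }).to_csv(out / "conditional_f.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    fit_u = fit_unrobust(red, level=config.ci_level, seed=config.seed)
    fit = fit_robust(red, level=config.ci_level, seed=config.seed) if config.robust else fit_u
    _fit_table(fit, red.trait_names, data.n_variants).to_csv(
        out / "estimates.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    q, df, pv = heterogeneity_test(fit_u)
    pd.DataFrame([{"q_stat": q, "df": df, "p_value": pv}]).to_csv(
        out / "heterogeneity.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    if config.run_coloc:
        i1, i2 = config.coloc_traits
        res = colocalize((data.beta_x[:, i1], data.se_x[:, i1]),
                         (data.beta_x[:, i2], data.se_x[:, i2]))
        row = res.as_dict() | {"conditional_h3": res.conditional_h3}
        pd.DataFrame([row]).to_csv(out / "coloc.tsv", sep="\t", index=False,
                                   float_format=FLOAT_FMT)
    if config.run_bma:
        bma = enumerate_bma(red, prior_p=config.bma_prior_p,
                            sigma_prior=config.bma_sigma_prior)
        pd.DataFrame({
            "model": ["+".join(bma.trait_names[i] for i in subset) for subset, _ in bma.models],
            "posterior": [p for _, p in bma.models],
        }).to_csv(out / "bma_models.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        pd.DataFrame({
            "risk_factor": bma.trait_names,
            "inclusion_probability": bma.inclusion,
        }).to_csv(out / "bma_inclusion.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    sio.write_manifest(
        out / "manifest.json",
        summary_path=str(config.summary_path),
        ld_path=str(config.ld_path),
        n_variants=data.n_variants,
        n_pcs=red.p,
        variance_threshold=config.variance_threshold,
        r2_max=config.r2_max,
        p_screen=config.p_screen,
        robust=config.robust,
        ci_level=config.ci_level,
        seed=config.seed,
        psd_repaired=ld.psd_repaired,
    )
    return out
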