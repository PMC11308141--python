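"""Orchestrate the multi-taxon MR screen and multiple-testing control.

One run screens many exposures (microbial taxa) against a single outcome
cohort: per taxon, select instruments, harmonize against the outcome,
estimate with every applicable method, run the sensitivity battery
(re-estimating on the MR-PRESSO-corrected set when outliers are flagged),
then adjust the primary (IVW) p-values across all attempted taxa with the
Benjamini–Hochberg step-up procedure. A two-cohort design (e.g. European
and East Asian outcome GWAS against the same exposures) is two runs.

The FDR family is every taxon attempted within the run — including taxa
whose IVW was null — recorded in the run metadata so the family behind
each q-value is always explicit. Taxa that fail a stage (no instruments,
nothing harmonizable, degenerate estimators) yield structured skip
records, never silent omission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from micromr import gwas_io
from micromr.estimators import EstimatorConfig, MREstimate, estimate_all
from micromr.gwas_io import SummaryDataset, read_summary_stats, write_results_table
from micromr.harmonization import HarmonizedSet, harmonize
from micromr.instrument_selection import (
    InstrumentSet,
    LDMatrixProvider,
    SelectionConfig,
    select_instruments,
)
from micromr.sensitivity import SensitivityReport, sensitivity_report

logger = logging.getLogger(__name__)

SKIP_REASONS = ("no_instruments", "nothing_to_harmonize", "estimator_failure")

FDR_ALPHA = 0.05
LOW_IV_K = 3


@dataclass
class TaxonResult:
    """Everything the screen produced for one taxon against one outcome."""

    taxon_id: str
    population: str
    instruments: InstrumentSet
    harmonized: HarmonizedSet
    estimates: list[MREstimate]
    sensitivity: SensitivityReport
    ivw_pval: float
    fdr: float = float("nan")
    significant: bool = False
    low_iv_flag: bool = False
    #: estimates recomputed after MR-PRESSO outlier removal (None when no
    #: outlier was flagged)
    estimates_corrected: list[MREstimate] | None = None

    @property
    def k(self) -> int:
        return len(self.harmonized)

    def primary_estimate(self) -> MREstimate:
        for est in self.estimates:
            if est.method in ("ivw", "wald_ratio"):
                return est
        raise ValueError(f"no primary estimate for {self.taxon_id}")


@dataclass
class SkipRecord:
    taxon_id: str
    reason: str
    detail: str = ""


@dataclass
class RunConfig:
    """File-driven configuration for one pipeline invocation."""

    exposures: list[tuple[str, str]]  # (taxon_id, path)
    outcome_path: str
    outcome_id: str = "outcome"
    population: str = ""
    exposure_columns: str | dict = "standard"
    outcome_columns: str | dict = "standard"
    ld_path: str | None = None
    default_n_exposure: int = 0
    default_n_outcome: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sel = SelectionConfig(**raw.pop("selection", {}))
        est = EstimatorConfig(**raw.pop("estimator", {}))
        exposures = [tuple(e) for e in raw.pop("exposures")]
        seed = int(raw.pop("seed", 0))
        est.seed = seed
        return cls(exposures=exposures, selection=sel, estimator=est, seed=seed, **raw)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def analyze_taxa(
    exposures: list[SummaryDataset],
    outcome: SummaryDataset,
    ld: LDMatrixProvider,
    selection: SelectionConfig | None = None,
    estimator: EstimatorConfig | None = None,
    presso_n_sim: int = 1000,
    presso_outlier_alpha: float = 0.05,
    seed: int = 0,
    population: str = "",
) -> tuple[list[TaxonResult], list[SkipRecord]]:
    """Run the full per-taxon cascade, then BH-adjust across attempted taxa.

    Deterministic given inputs and ``seed``: every per-taxon bootstrap and
    MR-PRESSO simulation is seeded from ``seed`` plus a fixed per-taxon
    stride. The FDR input is each taxon's primary p-value (IVW, or the
    Wald ratio when only one instrument survives).
    """
    selection = selection or SelectionConfig()
    estimator = estimator or EstimatorConfig()
    results: list[TaxonResult] = []
    skips: list[SkipRecord] = []

    for i, exposure in enumerate(exposures):
        taxon_seed = seed + 1009 * i  # fixed stride keeps per-taxon streams disjoint
        inst = select_instruments(exposure, ld, selection)
        if inst is None:
            skips.append(SkipRecord(exposure.trait_id, "no_instruments"))
            continue
        hs = harmonize(inst, outcome)
        if len(hs) == 0:
            skips.append(SkipRecord(exposure.trait_id, "nothing_to_harmonize", str(hs.dropped)))
            continue
        est_cfg = EstimatorConfig(
            ivw_model=estimator.ivw_model,
            n_boot=estimator.n_boot,
            seed=taxon_seed,
            mode_bandwidth_factor=estimator.mode_bandwidth_factor,
        )
        try:
            estimates = estimate_all(hs, est_cfg)
            sens, corrected_hs = sensitivity_report(
                hs,
                est_cfg,
                presso_n_sim=presso_n_sim,
                presso_outlier_alpha=presso_outlier_alpha,
                seed=taxon_seed + 7,
            )
            estimates_corrected = (
                estimate_all(corrected_hs, est_cfg) if corrected_hs is not None else None
            )
        except ValueError as exc:
            skips.append(SkipRecord(exposure.trait_id, "estimator_failure", str(exc)))
            continue
        res = TaxonResult(
            taxon_id=exposure.trait_id,
            population=population,
            instruments=inst,
            harmonized=hs,
            estimates=estimates,
            sensitivity=sens,
            ivw_pval=float("nan"),
            estimates_corrected=estimates_corrected,
            low_iv_flag=len(hs) < LOW_IV_K,
        )
        res.ivw_pval = res.primary_estimate().pval
        results.append(res)

    if results:
        q = bh_fdr([r.ivw_pval for r in results])
        for r, qv in zip(results, q):
            r.fdr = float(qv)
            r.significant = bool(qv < FDR_ALPHA)
    return results, skips


def run_analysis(config: RunConfig) -> tuple[list[TaxonResult], list[SkipRecord]]:
    """File-driven entry point: load inputs, analyze, optionally write the
    report bundle to ``config.out_dir``."""
    exposures = [
        read_summary_stats(
            path,
            config.exposure_columns,
            trait_id=taxon_id,
            trait_role="exposure",
            default_n=config.default_n_exposure,
        )
        for taxon_id, path in config.exposures
    ]
    outcome = read_summary_stats(
        config.outcome_path,
        config.outcome_columns,
        trait_id=config.outcome_id,
        trait_role="outcome",
        default_n=config.default_n_outcome,
        population=config.population,
    )
    ld = (
        LDMatrixProvider.from_triplets(config.ld_path, config.selection.clump_window_bp)
        if config.ld_path
        else LDMatrixProvider(window_bp=config.selection.clump_window_bp)
    )
    results, skips = analyze_taxa(
        exposures,
        outcome,
        ld,
        selection=config.selection,
        estimator=config.estimator,
        presso_n_sim=config.presso_n_sim,
        presso_outlier_alpha=config.presso_outlier_alpha,
        seed=config.seed,
        population=config.population,
    )
    if config.out_dir is not None:
        build_report(results, config.out_dir, skips=skips, config=config)
    return results, skips


def _forest_frame(results: list[TaxonResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for corrected, ests in ((False, res.estimates), (True, res.estimates_corrected or [])):
            for e in ests:
                rows.append(
                    {
                        "population": res.population,
                        "taxon": res.taxon_id,
                        "method": e.method,
                        "outliers_removed": corrected,
                        "n_snp": e.n_snp,
                        "b": e.b,
                        "se": e.se,
                        "or": e.odds_ratio,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                        "pval": e.pval,
                        "low_iv_flag": res.low_iv_flag,
                        "significant": res.significant,
                    }
                )
    return pd.DataFrame(rows)


def _per_snp_frame(results: list[TaxonResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        retained = {i.rsid: i for i in res.harmonized.instruments}
        exposure_by = {v.rsid: v for v in res.instruments.snps}
        for rsid, action in res.harmonized.actions:
            inst = retained.get(rsid)
            exp = exposure_by[rsid]
            rows.append(
                {
                    "population": res.population,
                    "taxon": res.taxon_id,
                    "rsid": rsid,
                    "effect_allele": exp.effect_allele,
                    "other_allele": exp.other_allele,
                    "gamma": exp.beta,
                    "se_gamma": exp.se,
                    "Gamma": np.nan if inst is None else inst.Gamma,
                    "se_Gamma": np.nan if inst is None else inst.se_Gamma,
                    "action": action,
                }
            )
    return pd.DataFrame(rows)


def build_report(
    results: list[TaxonResult],
    output_dir: str | Path,
    skips: list[SkipRecord] | None = None,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write the report bundle: statistics table, per-SNP table, tidy
    per-method (forest) table, scatter data, and run-metadata JSON."""
    if not results:
        raise ValueError("no results to report")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "statistics": out / "statistics.tsv",
        "per_snp": out / "per_snp.tsv",
        "forest": out / "estimates_forest.tsv",
        "scatter": out / "scatter.tsv",
        "metadata": out / "run_metadata.json",
    }
    write_results_table(results, paths["statistics"])
    _per_snp_frame(results).to_csv(paths["per_snp"], sep="\t", index=False, float_format="%.12g")
    _forest_frame(results).to_csv(paths["forest"], sep="\t", index=False, float_format="%.12g")

    scatter_rows = [
        {
            "population": r.population,
            "taxon": r.taxon_id,
            "rsid": i.rsid,
            "gamma": i.gamma,
            "se_gamma": i.se_gamma,
            "Gamma": i.Gamma,
            "se_Gamma": i.se_Gamma,
        }
        for r in results
        for i in r.harmonized.instruments
    ]
    pd.DataFrame(scatter_rows).to_csv(paths["scatter"], sep="\t", index=False, float_format="%.12g")

    meta = {
        "seed": None if config is None else config.seed,
        "population": results[0].population,
        "fdr_family_size": len(results),
        "fdr_alpha": FDR_ALPHA,
        "selection": None if config is None else asdict(config.selection),
        "estimator": None if config is None else asdict(config.estimator),
        "taxa": {
            r.taxon_id: {
                "k": r.k,
                "attrition": r.instruments.attrition,
                "harmonization_dropped": r.harmonized.dropped,
                "ivw_pval": r.ivw_pval,
                "fdr": r.fdr,
                "significant": r.significant,
                "low_iv_flag": r.low_iv_flag,
                "presso_outliers": r.sensitivity.presso_outliers,
            }
            for r in results
        },
        "skipped": [asdict(s) for s in (skips or [])],
    }
    gwas_io.write_run_metadata(meta, paths["metadata"])
    return paths
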