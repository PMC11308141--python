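"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

For one harmonized exposure–outcome pair this module provides:

* Cochran's Q across the per-instrument Wald ratios (fixed-effect IVW
  center), testing whether instruments estimate a common effect;
* the MR-Egger intercept test for directional pleiotropy;
* leave-one-out IVW re-estimation, exposing single-variant influence;
* MR-PRESSO: a simulation-based residual-sum-of-squares test that detects
  globally inflated heterogeneity, flags individual pleiotropic outlier
  instruments (Bonferroni-adjusted empirical p per SNP), and tests whether
  removing them distorts the causal estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from micromr.estimators import (
    EstimatorConfig,
    MREstimate,
    cochran_q_fixed,
    egger,
    ivw,
    _arrays,
)
from micromr.harmonization import HarmonizedSet

logger = logging.getLogger(__name__)

PRESSO_MIN_INSTRUMENTS = 4


@dataclass
class PressoResult:
    global_pval: float
    outliers: list[str]
    distortion_pval: float | None
    corrected_hs: HarmonizedSet | None


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure–outcome pair; fields are ``None``
    when the instrument count makes a diagnostic inapplicable."""

    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_pval: float | None = None
    loo: dict[str, MREstimate] = field(default_factory=dict)


def cochran_q(hs: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q = Σ w_j (r_j − b_fixed)², p from χ² with J−1 df."""
    j = len(hs)
    if j < 2:
        raise ValueError(f"Cochran's Q needs ≥ 2 instruments, got {j}")
    q, _ = cochran_q_fixed(hs)
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(hs: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, SE, p) from the MR-Egger fit; p tests H₀: intercept = 0."""
    est = egger(hs)
    assert est.intercept is not None
    return est.intercept, est.intercept_se, est.intercept_pval


def leave_one_out(hs: HarmonizedSet, ivw_model: str = "random") -> dict[str, MREstimate]:
    """IVW estimate with each instrument excluded in turn, keyed by the
    excluded rsid. With two instruments each entry degenerates to the
    remaining instrument's Wald ratio."""
    if len(hs) < 2:
        raise ValueError(f"leave-one-out needs ≥ 2 instruments, got {len(hs)}")
    out: dict[str, MREstimate] = {}
    for inst in hs.instruments:
        out[inst.rsid] = ivw(hs.without([inst.rsid]), model=ivw_model)
    return out


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out zero-intercept WLS slopes of Γ on γ, vectorized.

    Works on 1-D arrays or on (n_sim, J) matrices (row-wise)."""
    s1 = np.sum(w * g * G, axis=-1, keepdims=True)
    s2 = np.sum(w * g * g, axis=-1, keepdims=True)
    return (s1 - w * g * G) / (s2 - w * g * g)


def presso(
    hs: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    sig_outlier: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    The observed global statistic is Σ_j w_j (Γ_j − θ̂₍₋ⱼ₎ γ_j)² with
    w_j = 1/σ_Γj² and θ̂₍₋ⱼ₎ the IVW slope excluding instrument j. Its null
    distribution is built by parametric simulation: Γ*_j ~ N(θ̂₍₋ⱼ₎ γ_j,
    σ_Γj), γ*_j ~ N(γ_j, σ_γj), with the statistic recomputed (including
    the leave-one-out slopes) on each simulated dataset. Empirical tail
    p-values use the +1 continuity correction, so the smallest attainable
    p is 1/(n_sim+1). Per-instrument outlier p-values are
    Bonferroni-adjusted across J; instruments below ``sig_outlier`` are
    flagged and the distortion test compares the full-set IVW slope to the
    outlier-removed slope against a resampling null.

    Requires ≥ 4 instruments (leave-one-out slopes on 3 are too unstable
    to calibrate).
    """
    j = len(hs)
    if j < PRESSO_MIN_INSTRUMENTS:
        raise ValueError(f"MR-PRESSO needs ≥ {PRESSO_MIN_INSTRUMENTS} instruments, got {j}")
    if n_sim < 1:
        raise ValueError("n_sim must be ≥ 1")
    rng = np.random.default_rng(seed)

    g, sg, G, sG = _arrays(hs)
    w = 1.0 / sG**2
    theta_loo = _loo_slopes(g, G, w)
    rss_obs = w * (G - theta_loo * g) ** 2
    global_obs = float(np.sum(rss_obs))

    g_star = rng.normal(g, sg, size=(n_sim, j))
    G_star = rng.normal(theta_loo * g, sG, size=(n_sim, j))
    theta_star = _loo_slopes(g_star, G_star, w)
    rss_star = w * (G_star - theta_star * g_star) ** 2
    global_star = np.sum(rss_star, axis=1)

    global_pval = float((1 + np.sum(global_star >= global_obs)) / (n_sim + 1))

    p_snp = (1 + np.sum(rss_star >= rss_obs[None, :], axis=0)) / (n_sim + 1)
    p_snp_adj = np.minimum(1.0, p_snp * j)
    outlier_mask = p_snp_adj < sig_outlier
    outliers = [hs.instruments[i].rsid for i in np.flatnonzero(outlier_mask)]

    if len(outliers) == j:
        raise ValueError("MR-PRESSO flagged every instrument; no estimate possible")

    distortion_pval = None
    corrected = None
    if outliers:
        corrected = hs.without(outliers)
        keep = ~outlier_mask

        def slope(mask: np.ndarray) -> float:
            return float(np.sum(w[mask] * g[mask] * G[mask]) / np.sum(w[mask] * g[mask] ** 2))

        b_all = slope(np.ones(j, dtype=bool))
        b_kept = slope(keep)
        if b_kept == 0:
            distortion_pval = 1.0
        else:
            d_obs = 100.0 * (b_all - b_kept) / abs(b_kept)
            kept_idx = np.flatnonzero(keep)
            n_out = int(outlier_mask.sum())
            d_null = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(kept_idx, size=min(n_out, kept_idx.size - 1), replace=False)
                mask = keep.copy()
                mask[drop] = False
                b_s = slope(mask)
                d_null[s] = 100.0 * (b_all - b_s) / abs(b_s) if b_s != 0 else np.inf
            distortion_pval = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))

    return PressoResult(
        global_pval=global_pval,
        outliers=outliers,
        distortion_pval=distortion_pval,
        corrected_hs=corrected,
    )


def sensitivity_report(
    hs: HarmonizedSet,
    config: EstimatorConfig | None = None,
    presso_n_sim: int = 1000,
    presso_outlier_alpha: float = 0.05,
    seed: int = 0,
) -> tuple[SensitivityReport, HarmonizedSet | None]:
    """Run every diagnostic whose instrument-count precondition is met.

    Returns the report and, when MR-PRESSO flags outliers, the corrected
    (outlier-removed) harmonized set, else ``None``. Diagnostics that are
    inapplicable at this instrument count stay ``None`` and are rendered
    downstream as the ``"-"`` sentinel.
    """
    cfg = config or EstimatorConfig()
    rep = SensitivityReport()
    k = len(hs)
    if k >= 2:
        rep.q, rep.q_df, rep.q_pval = cochran_q(hs)
        rep.loo = leave_one_out(hs, ivw_model=cfg.ivw_model)
    if k >= 3:
        rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_pval = (
            egger_intercept_test(hs)
        )
    corrected = None
    if k >= PRESSO_MIN_INSTRUMENTS:
        pres = presso(hs, n_sim=presso_n_sim, seed=seed, sig_outlier=presso_outlier_alpha)
        rep.presso_global_pval = pres.global_pval
        rep.presso_outliers = pres.outliers
        rep.presso_distortion_pval = pres.distortion_pval
        corrected = pres.corrected_hs
    return rep, corrected
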