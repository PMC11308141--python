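"""Causal-effect estimators for two-sample summary-data MR.

Given J harmonized instruments with exposure effects γ_j (SE σ_γj) and
outcome effects Γ_j (SE σ_Γj), each method combines the per-instrument Wald
ratios r_j = Γ_j/γ_j, with first-order standard error σ_Γj/|γ_j|, into one
causal estimate on the log-odds scale:

* ``ivw`` — inverse-variance-weighted mean of the ratios (equivalently a
  zero-intercept weighted regression of Γ on γ). Fixed-effect SE, or the
  multiplicative random-effects SE inflated by √(Q/(J−1)) when the
  heterogeneity statistic Q exceeds its degrees of freedom (default).
* ``egger`` — weighted regression of Γ on γ with a free intercept; the
  intercept estimates average directional pleiotropy and the slope is a
  pleiotropy-adjusted causal effect. Consistent under the InSIDE
  assumption (pleiotropy independent of instrument strength).
* ``weighted_median`` / ``simple_median`` — the 50% weighted quantile of
  the ratios; consistent when instruments carrying at least half the
  weight are valid. SE by parametric bootstrap.
* ``weighted_mode`` / ``simple_mode`` — the maximizer of a Gaussian-kernel
  density over the ratios (modified Silverman bandwidth); consistent when
  the largest group of instruments sharing one ratio is valid.
* ``wald_ratio`` — the single-instrument degenerate case.

Estimates are reported as log-OR with SE, two-sided p, and the OR with
Wald 95% CI exp(b ± 1.96·SE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from micromr.harmonization import HarmonizedSet, HarmonizedInstrument

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Deterministic per-method seed offsets, so one run-level seed drives every
#: bootstrap reproducibly.
SEED_OFFSETS = {
    "weighted_median": 11,
    "simple_median": 12,
    "weighted_mode": 13,
    "simple_mode": 14,
}

MODE_GRID_POINTS = 512


@dataclass
class EstimatorConfig:
    ivw_model: str = "random"  # "random" (multiplicative) or "fixed"
    n_boot: int = 1000
    seed: int = 0
    mode_bandwidth_factor: float = 1.0


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str
    b: float
    se: float
    pval: float
    n_snp: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None


@dataclass(frozen=True)
class RatioTerm:
    """Per-instrument Wald ratio with first-order SE and IVW weight."""

    rsid: str
    ratio: float
    se_ratio: float
    weight: float


def _arrays(hs: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = np.array([i.gamma for i in hs.instruments], dtype=float)
    sg = np.array([i.se_gamma for i in hs.instruments], dtype=float)
    G = np.array([i.Gamma for i in hs.instruments], dtype=float)
    sG = np.array([i.se_Gamma for i in hs.instruments], dtype=float)
    return g, sg, G, sG


def ratio_terms(hs: HarmonizedSet) -> list[RatioTerm]:
    terms = []
    for i in hs.instruments:
        if i.gamma == 0:
            raise ValueError(f"degenerate instrument {i.rsid}: exposure effect is zero")
        se_ratio = i.se_Gamma / abs(i.gamma)
        terms.append(
            RatioTerm(rsid=i.rsid, ratio=i.Gamma / i.gamma, se_ratio=se_ratio,
                      weight=1.0 / se_ratio**2)
        )
    return terms


def _normal_p(b: float, se: float) -> float:
    if se == 0:
        return 1.0 if b == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(b) / se))


def _t_p(b: float, se: float, df: int) -> float:
    if se == 0:
        return 1.0 if b == 0 else 0.0
    return float(2.0 * stats.t.sf(abs(b) / se, df))


def _make(method: str, b: float, se: float, pval: float, n_snp: int, **egger_fields) -> MREstimate:
    return MREstimate(
        method=method,
        b=float(b),
        se=float(se),
        pval=float(pval),
        n_snp=int(n_snp),
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - Z_95 * se)),
        ci_high=float(np.exp(b + Z_95 * se)),
        **egger_fields,
    )


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-instrument causal estimate Γ/γ with first-order SE σ_Γ/|γ|."""
    if inst.gamma == 0:
        raise ValueError(f"degenerate instrument {inst.rsid}: exposure effect is zero")
    b = inst.Gamma / inst.gamma
    se = inst.se_Gamma / abs(inst.gamma)
    return _make("wald_ratio", b, se, _normal_p(b, se), 1)


def cochran_q_fixed(hs: HarmonizedSet) -> tuple[float, float]:
    """(Q, fixed-effect IVW b) over the ratio terms."""
    terms = ratio_terms(hs)
    r = np.array([t.ratio for t in terms])
    w = np.array([t.weight for t in terms])
    b = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - b) ** 2))
    return q, b


def ivw(hs: HarmonizedSet, model: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate b = Σ w_j r_j / Σ w_j.

    ``model="fixed"``: SE = (Σ w_j)^{-1/2}. ``model="random"``
    (multiplicative random effects, the default): the fixed SE scaled by
    max(1, √(Q/(J−1))), conservative under between-instrument
    heterogeneity. Delegates to :func:`wald_ratio` for a single instrument.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = len(hs)
    if j < 1:
        raise ValueError("IVW needs at least one instrument")
    if j == 1:
        # degenerate case: the IVW of one ratio IS the Wald ratio; keep the
        # truthful method label
        return wald_ratio(hs.instruments[0])
    terms = ratio_terms(hs)
    w = np.array([t.weight for t in terms])
    q, b = cochran_q_fixed(hs)
    se = float(1.0 / np.sqrt(np.sum(w)))
    if model == "random":
        se *= max(1.0, float(np.sqrt(q / (j - 1))))
    return _make("ivw", b, se, _normal_p(b, se), j)


def egger(hs: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of Γ on γ with a free intercept.

    Instruments are oriented so γ_j ≥ 0 (both effects sign-flipped where
    needed); weights are 1/σ_Γj². SEs use the multiplicative
    random-effects convention max(1, residual SE); p-values are Student t
    with J − 2 df. Requires ≥ 3 instruments.
    """
    j = len(hs)
    if j < 3:
        raise ValueError(f"MR-Egger needs ≥ 3 instruments, got {j}")
    g, _, G, sG = _arrays(hs)
    sign = np.where(g < 0, -1.0, 1.0)
    x, y, w = g * sign, G * sign, 1.0 / sG**2
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    scale = float(res.scale)  # residual variance estimate (rse²)
    if scale > 0:
        # statsmodels bse includes ×rse; enforce the max(1, rse) floor
        adj = max(1.0, np.sqrt(scale)) / np.sqrt(scale)
        bse = res.bse * adj
    else:
        bse = np.zeros(2)
    intercept, slope = float(res.params[0]), float(res.params[1])
    se_i, se_b = float(bse[0]), float(bse[1])
    return _make(
        "egger",
        slope,
        se_b,
        _t_p(slope, se_b, j - 2),
        j,
        intercept=intercept,
        intercept_se=se_i,
        intercept_pval=_t_p(intercept, se_i, j - 2),
    )


def _weighted_median_rows(ratio_rows: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with linear interpolation at the 0.5
    crossing of the half-step normalized cumulative weight."""
    m, j = ratio_rows.shape
    order = np.argsort(ratio_rows, axis=1)
    rs = np.take_along_axis(ratio_rows, order, axis=1)
    ws = weights[order]
    total = weights.sum()
    cw = (np.cumsum(ws, axis=1) - 0.5 * ws) / total
    below = np.sum(cw < 0.5, axis=1) - 1
    out = np.empty(m)
    first = below < 0
    out[first] = rs[first, 0]
    idx = np.where(~first)[0]
    i = below[idx]
    last = i >= j - 1
    if np.any(last):  # cumulative weight never reaches 0.5 only at j=1
        out[idx[last]] = rs[idx[last], j - 1]
        idx, i = idx[~last], i[~last]
    r0 = rs[idx, i]
    r1 = rs[idx, i + 1]
    c0 = cw[idx, i]
    c1 = cw[idx, i + 1]
    out[idx] = r0 + (r1 - r0) * (0.5 - c0) / (c1 - c0)
    return out


def _bootstrap_ratios(hs: HarmonizedSet, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Parametric resamples of the per-instrument ratios, shape (n_boot, J)."""
    g, sg, G, sG = _arrays(hs)
    g_star = rng.normal(g, sg, size=(n_boot, g.size))
    G_star = rng.normal(G, sG, size=(n_boot, g.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        return G_star / g_star


def _median_estimate(hs: HarmonizedSet, weights: np.ndarray, method: str,
                     n_boot: int, seed: int) -> MREstimate:
    terms = ratio_terms(hs)
    r = np.array([t.ratio for t in terms])
    b = float(_weighted_median_rows(r[None, :], weights)[0])
    rng = np.random.default_rng(seed)
    boots = _weighted_median_rows(_bootstrap_ratios(hs, n_boot, rng), weights)
    se = float(np.std(boots[np.isfinite(boots)], ddof=1))
    return _make(method, b, se, _normal_p(b, se), len(hs))


def weighted_median(hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate; consistent when valid instruments carry
    > 50% of the inverse-variance weight. SE by parametric bootstrap."""
    if len(hs) < 3:
        raise ValueError(f"weighted median needs ≥ 3 instruments, got {len(hs)}")
    w = np.array([t.weight for t in ratio_terms(hs)])
    return _median_estimate(hs, w, "weighted_median", n_boot, seed)


def simple_median(hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Equal-weight median of the per-instrument ratios."""
    if len(hs) < 3:
        raise ValueError(f"simple median needs ≥ 3 instruments, got {len(hs)}")
    w = np.ones(len(hs))
    return _median_estimate(hs, w, "simple_median", n_boot, seed)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    r = np.asarray(ratios, dtype=float)
    j = r.size
    sd = float(np.std(r, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    s = 0.9 * min(sd, mad if mad > 0 else sd) / j ** 0.2
    if s <= 0:
        return float(r[0])  # all ratios identical
    h = bandwidth_factor * s
    lo, hi = float(r.min()), float(r.max())
    if hi - lo > 100 * h:
        # a stray extreme ratio (near-zero denominator in a bootstrap draw)
        # would make the fixed grid too coarse to resolve the mode; confine
        # it to a wide window around the central mass, where any multi-point
        # density maximum must lie
        center = float(np.median(r))
        lo, hi = max(lo, center - 50 * h), min(hi, center + 50 * h)
    grid = np.linspace(lo - 3 * h, hi + 3 * h, MODE_GRID_POINTS)
    dens = np.sum(weights[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2), axis=1)
    return float(grid[np.argmax(dens)])  # argmax → first max → smallest grid value


def mode_based(hs: HarmonizedSet, weighted: bool = True, bandwidth_factor: float = 1.0,
               n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode-based estimate: maximizer of a Gaussian-kernel-smoothed density
    of the ratios over a fixed 512-point grid.

    Bandwidth is ``bandwidth_factor`` × the modified Silverman rule
    0.9·min(SD, 1.4826·MAD)·J^{−1/5} on the ratios; inverse-variance
    weights when ``weighted``. SE by parametric bootstrap (bandwidth
    recomputed per draw).
    """
    if len(hs) < 3:
        raise ValueError(f"mode-based estimate needs ≥ 3 instruments, got {len(hs)}")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    terms = ratio_terms(hs)
    r = np.array([t.ratio for t in terms])
    w = np.array([t.weight for t in terms]) if weighted else np.ones(len(hs))
    w = w / w.sum()
    b = _mode_point(r, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    boot_r = _bootstrap_ratios(hs, n_boot, rng)
    boots = np.array([
        _mode_point(row, w, bandwidth_factor) for row in boot_r if np.all(np.isfinite(row))
    ])
    se = float(np.std(boots, ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return _make(method, b, se, _normal_p(b, se), len(hs))


def estimate_all(hs: HarmonizedSet, config: EstimatorConfig | None = None) -> list[MREstimate]:
    """Every estimator applicable at this instrument count.

    One instrument → Wald ratio only; two → IVW only (median/mode/Egger
    need ≥ 3); three or more → IVW, MR-Egger, weighted/simple median,
    weighted/simple mode. All bootstraps are seeded from ``config.seed``
    via fixed per-method offsets, so results are reproducible and
    order-invariant.
    """
    cfg = config or EstimatorConfig()
    k = len(hs)
    if k < 1:
        raise ValueError("no instruments to estimate from")
    if k == 1:
        return [wald_ratio(hs.instruments[0])]
    if k == 2:
        return [ivw(hs, model=cfg.ivw_model)]
    return [
        ivw(hs, model=cfg.ivw_model),
        egger(hs),
        weighted_median(hs, cfg.n_boot, cfg.seed + SEED_OFFSETS["weighted_median"]),
        simple_median(hs, cfg.n_boot, cfg.seed + SEED_OFFSETS["simple_median"]),
        mode_based(hs, True, cfg.mode_bandwidth_factor, cfg.n_boot,
                   cfg.seed + SEED_OFFSETS["weighted_mode"]),
        mode_based(hs, False, cfg.mode_bandwidth_factor, cfg.n_boot,
                   cfg.seed + SEED_OFFSETS["simple_mode"]),
    ]
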