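"""Monte-Carlo calibration studies of the MR estimators.

Each function runs replicated simulations under a named generator scenario
and summarises one operating characteristic: bias and confidence-interval
coverage under a true effect, type-I error under the null, the weighted
median's breakdown behaviour as the invalid-weight fraction crosses 50%,
MR-PRESSO outlier detection power and global-test calibration, and the
end-to-end false-discovery rate of the multi-taxon screen.

Estimator benchmarks evaluate methods on the generator's designed
instruments (via :func:`micromr.synthetic_data.harmonized_from_truth`),
isolating estimator behaviour from selection effects; the screen
benchmarks run the full pipeline including selection, clumping and
harmonization.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from micromr.estimators import ivw, weighted_median
from micromr.pipeline import analyze_taxa
from micromr.sensitivity import egger_intercept_test, presso
from micromr.synthetic_data import (
    SimulationConfig,
    harmonized_from_truth,
    scenario,
    simulate_pair,
    simulate_screen,
)


def _derive(seed: int, index: int) -> int:
    """Decorrelated 31-bit child seed for replicate ``index``."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


def _replicate_sets(name: str, n_reps: int, seed: int, **overrides):
    base = replace(scenario(name), **overrides)
    for r in range(n_reps):
        cfg = replace(base, seed=_derive(seed, r))
        exposure, outcome, truth = simulate_pair(cfg)
        yield harmonized_from_truth(exposure, outcome, truth), truth


def ivw_recovery(n_reps: int = 1000, seed: int = 0, theta: float = 0.3) -> dict:
    """Bias and 95% CI coverage of random-effects IVW under clean_causal."""
    b = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    for i, (hs, truth) in enumerate(_replicate_sets("clean_causal", n_reps, seed, theta=theta)):
        est = ivw(hs)
        b[i] = est.b
        covered[i] = est.b - 1.96 * est.se <= theta <= est.b + 1.96 * est.se
    return {
        "theta": theta,
        "mean_bias": float(np.mean(b) - theta),
        "sd": float(np.std(b, ddof=1)),
        "coverage": float(np.mean(covered)),
        "n_reps": n_reps,
    }


def ivw_type1(n_reps: int = 1000, seed: int = 0, alpha: float = 0.05) -> dict:
    """IVW rejection rate when the true causal effect is zero."""
    rej = 0
    for hs, _ in _replicate_sets("clean_null", n_reps, seed):
        rej += ivw(hs).pval < alpha
    return {"rejection_rate": rej / n_reps, "alpha": alpha, "n_reps": n_reps}


def egger_intercept_type1(n_reps: int = 1000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Egger-intercept rejection rate under balanced (mean-zero) pleiotropy."""
    rej = 0
    for hs, _ in _replicate_sets("balanced_pleiotropy", n_reps, seed):
        rej += egger_intercept_test(hs)[2] < alpha
    return {"rejection_rate": rej / n_reps, "alpha": alpha, "n_reps": n_reps}


def egger_pleiotropy_recovery(n_reps: int = 500, seed: int = 0) -> dict:
    """Egger-intercept estimate of the mean directional pleiotropy (InSIDE
    holding)."""
    intercepts = np.array([
        egger_intercept_test(hs)[0]
        for hs, _ in _replicate_sets("directional_pleiotropy", n_reps, seed)
    ])
    true_mean = scenario("directional_pleiotropy").pleiotropy_mean
    return {
        "true_mean": true_mean,
        "mean_intercept": float(intercepts.mean()),
        "sd": float(intercepts.std(ddof=1)),
        "bias_in_sds": float(abs(intercepts.mean() - true_mean) / intercepts.std(ddof=1)),
        "n_reps": n_reps,
    }


def weighted_median_breakdown(
    invalid_frac: float,
    n_reps: int = 500,
    seed: int = 0,
    n_instruments: int = 10,
    ratio_offset: float = 1.0,
    n_boot: int = 200,
    theta: float = 0.3,
) -> dict:
    """Weighted-median bias, in Monte-Carlo SDs, at a given invalid-weight
    fraction.

    Instruments have equal strength so the flagged fraction of instruments
    is the flagged fraction of weight; invalid instruments share a
    directional ratio offset (correlated pleiotropy). Below the 50%
    breakdown point the bias stays within the estimator's own Monte-Carlo
    spread; above it the estimator tracks the invalid cluster.
    """
    n_invalid = int(round(invalid_frac * n_instruments))
    b = np.empty(n_reps)
    gen = _replicate_sets(
        "clean_causal", n_reps, seed,
        theta=theta, n_variants=n_instruments, n_causal=n_instruments,
        equal_strength=True, n_invalid=n_invalid, invalid_ratio_offset=ratio_offset,
    )
    for i, (hs, _) in enumerate(gen):
        b[i] = weighted_median(hs, n_boot=n_boot, seed=seed + i).b
    sd = float(np.std(b, ddof=1))
    return {
        "invalid_frac": invalid_frac,
        "theta": theta,
        "mean_b": float(b.mean()),
        "sd": sd,
        "bias_in_sds": float(abs(b.mean() - theta) / sd),
        "n_reps": n_reps,
    }


def presso_outlier_power(n_reps: int = 200, seed: int = 0, n_sim: int = 1000) -> dict:
    """Fraction of replicates in which the injected gross outlier (pleiotropy
    10× its outcome SE, among 15 instruments) is flagged."""
    hits = 0
    for i, (hs, truth) in enumerate(_replicate_sets("outlier_contaminated", n_reps, seed)):
        res = presso(hs, n_sim=n_sim, seed=seed + i)
        hits += set(truth.outlier_rsids) <= set(res.outliers)
    return {"detection_rate": hits / n_reps, "n_reps": n_reps, "n_sim": n_sim}


def presso_clean_calibration(n_reps: int = 200, seed: int = 0, n_sim: int = 1000) -> dict:
    """Fraction of clean-data replicates with MR-PRESSO global p > 0.05."""
    ok = 0
    any_outlier = 0
    for i, (hs, _) in enumerate(_replicate_sets("clean_causal", n_reps, seed)):
        res = presso(hs, n_sim=n_sim, seed=seed + i)
        ok += res.global_pval > 0.05
        any_outlier += bool(res.outliers)
    return {
        "frac_global_p_above_05": ok / n_reps,
        "frac_with_outliers": any_outlier / n_reps,
        "n_reps": n_reps,
        "n_sim": n_sim,
    }


def null_screen_fdr(
    n_taxa: int = 50,
    n_runs: int = 3,
    seed: int = 0,
    n_variants: int = 30,
    n_causal: int = 10,
    n_boot: int = 100,
    presso_n_sim: int = 300,
) -> dict:
    """End-to-end discovery fraction of the full screen when every taxon is
    null (θ = 0 throughout): instruments exist but none affect the outcome."""
    from micromr.estimators import EstimatorConfig

    base = replace(scenario("clean_null"), n_variants=n_variants, n_causal=n_causal)
    fracs = []
    for run in range(n_runs):
        run_seed = _derive(seed, run)
        exposures, outcome, ld, _ = simulate_screen(n_taxa, 0.0, base, seed=run_seed)
        results, _ = analyze_taxa(
            exposures, outcome, ld,
            estimator=EstimatorConfig(n_boot=n_boot),
            presso_n_sim=presso_n_sim, seed=run_seed,
        )
        fracs.append(sum(r.significant for r in results) / max(1, len(results)))
    return {
        "mean_discovery_fraction": float(np.mean(fracs)),
        "per_run": [float(f) for f in fracs],
        "n_taxa": n_taxa,
        "n_runs": n_runs,
    }


def causal_screen_recovery(
    n_taxa: int = 20,
    n_causal_taxa: int = 4,
    theta: float = 0.35,
    seed: int = 0,
    n_variants: int = 30,
    n_causal: int = 10,
    n_boot: int = 100,
    presso_n_sim: int = 300,
) -> dict:
    """Sensitivity/specificity of the screen with a few truly causal taxa."""
    from micromr.estimators import EstimatorConfig

    base = replace(scenario("clean_causal"), n_variants=n_variants, n_causal=n_causal)
    thetas = [theta] * n_causal_taxa + [0.0] * (n_taxa - n_causal_taxa)
    exposures, outcome, ld, truths = simulate_screen(n_taxa, thetas, base, seed=seed)
    results, _ = analyze_taxa(
        exposures, outcome, ld,
        estimator=EstimatorConfig(n_boot=n_boot),
        presso_n_sim=presso_n_sim, seed=seed,
    )
    causal_ids = {t for t, tr in truths.items() if tr.theta != 0}
    hits = {r.taxon_id for r in results if r.significant}
    return {
        "true_positives": len(hits & causal_ids),
        "false_positives": len(hits - causal_ids),
        "n_causal_taxa": n_causal_taxa,
        "n_taxa": n_taxa,
        "theta": theta,
    }
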