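"""Synthetic paired GWAS summary statistics with known ground truth.

The generator emulates the statistical structure a two-sample MR pipeline
must cope with, at the summary level (no individual genotypes):

* a pool of variants, a subset truly associated with the exposure
  (instrument candidates) with effects drawn so the median per-variant F
  statistic at the exposure sample size is configurable;
* per-variant direct (pleiotropic) effects on the outcome, optionally
  correlated with instrument strength (an InSIDE violation), plus optional
  gross outlier instruments whose pleiotropy is a fixed multiple of their
  outcome SE;
* heteroscedastic standard errors SE = 1/√(2p(1−p)N) from allele
  frequency and sample size, the standardized-trait approximation;
* block LD: variants in a block share an index signal and correlated
  noise with pairwise r² equal to ``ld_within_r2``, and the pairwise r²
  values are exposed for clumping;
* file-dialect hazards: palindromic (A/T, C/G) allele pairs, and outcome
  rows stored on the swapped allele orientation with negated betas.

The true causal effect θ is interpreted as log-odds of outcome per SD of
exposure, matching the pipeline's odds-ratio reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import stats

from micromr.gwas_io import SummaryDataset, VariantAssociation
from micromr.harmonization import HarmonizedInstrument, HarmonizedSet
from micromr.instrument_selection import LDMatrixProvider

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ≈ 0.4549

_NONPALINDROMIC_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                         ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated exposure/outcome pair.

    ``target_median_f`` sets the scale of the causal exposure effects so
    that the median per-variant F statistic (≈ z², for large N) at
    ``n_exp`` is approximately that value; ``n_outliers`` causal variants
    receive an additional directional pleiotropic effect of
    ``outlier_scale`` × their outcome SE.

    For a case-control outcome, ``n_out`` is the *effective* sample size
    4/(1/n_cases + 1/n_controls), the N under which 1/√(2p(1−p)N) matches
    the SE of a logistic GWAS; the default corresponds to a cohort of
    ≈ 5.5k cases / 90k controls. ``n_exp`` defaults to the sample size of
    the largest published gut-microbiome GWAS meta-analysis.
    """

    n_variants: int = 200
    n_causal: int = 20
    theta: float = 0.0
    n_exp: int = 18_340
    n_out: int = 20_914
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False
    ld_block_size: int = 1
    ld_within_r2: float = 0.8
    frac_palindromic: float = 0.0
    frac_flipped: float = 0.0
    target_median_f: float = 30.0
    n_outliers: int = 0
    outlier_scale: float = 10.0
    n_invalid: int = 0
    invalid_ratio_offset: float = 0.0
    #: give every causal variant the same F (γ_j = √F·SE_γj) instead of
    #: drawing effect sizes; pins each instrument's share of the
    #: inverse-variance weight, which breakdown-fraction studies need
    equal_strength: bool = False
    #: shift of the rsid namespace, so several simulated exposures can share
    #: one outcome dataset without variant collisions
    rsid_offset: int = 0
    seed: int = 0
    taxon_id: str = "taxon"
    outcome_id: str = "outcome"

    def validate(self) -> None:
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if self.n_outliers > self.n_causal:
            raise ValueError("n_outliers cannot exceed n_causal")
        if self.n_invalid > self.n_causal:
            raise ValueError("n_invalid cannot exceed n_causal")
        for name in ("frac_palindromic", "frac_flipped"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (0.0 <= self.ld_within_r2 < 1.0):
            raise ValueError("ld_within_r2 must be in [0,1)")
        if self.ld_block_size < 1 or self.n_variants < 1:
            raise ValueError("n_variants and ld_block_size must be ≥ 1")
        if self.pleiotropy_sd < 0 or self.target_median_f <= 0:
            raise ValueError("pleiotropy_sd must be ≥ 0 and target_median_f > 0")
        if min(self.n_exp, self.n_out) < 10:
            raise ValueError("sample sizes must be realistic (≥ 10)")


@dataclass
class GroundTruth:
    """Per-variant truth paired with one simulated dataset."""

    rsids: list[str]
    true_gamma: np.ndarray
    alpha: np.ndarray
    causal: np.ndarray
    block: np.ndarray
    palindromic: np.ndarray
    flipped_in_outcome: np.ndarray
    theta: float
    outlier_rsids: list[str]
    invalid_rsids: list[str]
    ld_pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def causal_rsids(self) -> list[str]:
        return [r for r, c in zip(self.rsids, self.causal) if c]

    def ld_provider(self, window_bp: int = 1_000_000) -> LDMatrixProvider:
        return LDMatrixProvider(dict(self.ld_pairs), window_bp=window_bp)


def _se_from_freq(freq: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * n)


def simulate_pair(config: SimulationConfig) -> tuple[SummaryDataset, SummaryDataset, GroundTruth]:
    """Draw one exposure/outcome summary-statistic pair plus its truth.

    Deterministic given ``config`` (all randomness flows from
    ``config.seed``). The causal variants are the index (first) variants
    of the first ``n_causal`` LD blocks; remaining members of a causal
    block carry the attenuated tag signal √r²·γ_index and their summary
    noise is correlated with the index at r = √r², so pairwise summary r²
    within a block is ≈ ``ld_within_r2``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    rsids = [f"rs{100000 + config.rsid_offset + i}" for i in range(m)]

    block = np.arange(m) // config.ld_block_size
    n_blocks = int(block.max()) + 1
    chrom = np.array([str(b % 22 + 1) for b in range(n_blocks)])[block]
    # blocks on the same chromosome are ≥ 5 Mb apart; members 20 kb apart
    pos = np.array(
        [10_000_000 + (b // 22) * 5_000_000 + (i % config.ld_block_size) * 20_000
         for i, b in enumerate(block)]
    )

    freq = rng.uniform(0.05, 0.5, size=m)
    se_exp = _se_from_freq(freq, config.n_exp)
    se_out = _se_from_freq(freq, config.n_out)

    # causal index variants: first variant of each of the first n_causal blocks
    is_index = np.arange(m) % config.ld_block_size == 0
    causal = np.zeros(m, dtype=bool)
    causal[is_index & (block < config.n_causal)] = True

    true_gamma = np.zeros(m)
    if config.n_causal:
        sigma_gamma = np.sqrt(
            config.target_median_f * float(np.median(se_exp[causal] ** 2)) / _CHI2_1_MEDIAN
        )
        # effect alleles are coded exposure-increasing (the labeling is
        # arbitrary, and this makes "directional" pleiotropy well defined
        # relative to the instruments' orientation)
        if config.equal_strength:
            true_gamma[causal] = np.sqrt(config.target_median_f) * se_exp[causal]
        else:
            true_gamma[causal] = np.abs(rng.normal(0.0, sigma_gamma, size=int(causal.sum())))
        # tag variants inside causal blocks carry the attenuated index signal
        tag = (block < config.n_causal) & ~causal
        if tag.any():
            idx_gamma = {b: true_gamma[(block == b) & causal][0] for b in range(config.n_causal)}
            true_gamma[tag] = np.sqrt(config.ld_within_r2) * np.array(
                [idx_gamma[b] for b in block[tag]]
            )
    else:
        sigma_gamma = 1.0

    alpha = np.zeros(m)
    if config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0:
        noise = rng.normal(0.0, 1.0, size=m)
        if config.inside_violation and config.pleiotropy_sd > 0:
            rho = 0.6
            alpha = (
                config.pleiotropy_mean
                + rho * config.pleiotropy_sd * true_gamma / sigma_gamma
                + np.sqrt(1 - rho**2) * config.pleiotropy_sd * noise
            )
        else:
            alpha = config.pleiotropy_mean + config.pleiotropy_sd * noise

    # gross outliers: directional pleiotropy, a fixed multiple of the outcome SE
    outlier_rsids: list[str] = []
    if config.n_outliers:
        causal_idx = np.flatnonzero(causal)
        out_idx = causal_idx[-config.n_outliers:]
        alpha[out_idx] += config.outlier_scale * se_out[out_idx]
        outlier_rsids = [rsids[i] for i in out_idx]

    # invalid instruments: correlated (directional) pleiotropy acting through
    # a shared pathway, shifting each flagged instrument's Wald ratio by a
    # common offset — the invalidity model used for robust-estimator
    # breakdown studies
    invalid_rsids: list[str] = []
    if config.n_invalid:
        inv_idx = np.flatnonzero(causal)[: config.n_invalid]
        alpha[inv_idx] += config.invalid_ratio_offset * true_gamma[inv_idx]
        invalid_rsids = [rsids[i] for i in inv_idx]

    true_Gamma = config.theta * true_gamma + alpha

    def _block_noise() -> np.ndarray:
        z = rng.normal(size=m)
        if config.ld_block_size == 1 or config.ld_within_r2 == 0:
            return z
        r = np.sqrt(config.ld_within_r2)
        shared = rng.normal(size=n_blocks)[block]
        return r * shared + np.sqrt(1 - r**2) * z

    beta_exp = true_gamma + _block_noise() * se_exp
    beta_out = true_Gamma + _block_noise() * se_out

    def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
        return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), 1e-300, 1.0)

    p_exp = _pvals(beta_exp, se_exp)
    p_out = _pvals(beta_out, se_out)

    n_pal = int(round(config.frac_palindromic * m))
    palindromic = np.zeros(m, dtype=bool)
    palindromic[rng.choice(m, size=n_pal, replace=False)] = True
    pairs = np.empty((m, 2), dtype="<U1")
    pal_pick = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    non_pick = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    for i in range(m):
        pairs[i] = _PALINDROMIC_PAIRS[pal_pick[i]] if palindromic[i] else _NONPALINDROMIC_PAIRS[non_pick[i]]

    n_flip = int(round(config.frac_flipped * m))
    flipped = np.zeros(m, dtype=bool)
    flipped[rng.choice(m, size=n_flip, replace=False)] = True

    exp_variants = [
        VariantAssociation(
            rsid=rsids[i], chrom=chrom[i], pos=int(pos[i]),
            effect_allele=pairs[i, 0], other_allele=pairs[i, 1],
            eaf=float(freq[i]), beta=float(beta_exp[i]), se=float(se_exp[i]),
            pval=float(p_exp[i]), n=config.n_exp,
        )
        for i in range(m)
    ]
    out_variants = []
    for i in range(m):
        if flipped[i]:
            ea, oa = pairs[i, 1], pairs[i, 0]
            b, f = -beta_out[i], 1.0 - freq[i]
        else:
            ea, oa = pairs[i, 0], pairs[i, 1]
            b, f = beta_out[i], freq[i]
        out_variants.append(
            VariantAssociation(
                rsid=rsids[i], chrom=chrom[i], pos=int(pos[i]),
                effect_allele=ea, other_allele=oa, eaf=float(f),
                beta=float(b), se=float(se_out[i]), pval=float(p_out[i]), n=config.n_out,
            )
        )

    ld_pairs: dict[tuple[str, str], float] = {}
    if config.ld_block_size > 1:
        for b in range(n_blocks):
            members = np.flatnonzero(block == b)
            for ii in range(len(members)):
                for jj in range(ii + 1, len(members)):
                    ld_pairs[(rsids[members[ii]], rsids[members[jj]])] = config.ld_within_r2

    exposure = SummaryDataset(
        trait_id=config.taxon_id, trait_role="exposure", variants=exp_variants,
        default_n=config.n_exp,
    )
    outcome = SummaryDataset(
        trait_id=config.outcome_id, trait_role="outcome", variants=out_variants,
        default_n=config.n_out,
    )
    truth = GroundTruth(
        rsids=rsids,
        true_gamma=true_gamma,
        alpha=alpha,
        causal=causal,
        block=block,
        palindromic=palindromic,
        flipped_in_outcome=flipped,
        theta=config.theta,
        outlier_rsids=outlier_rsids,
        invalid_rsids=invalid_rsids,
        ld_pairs=ld_pairs,
    )
    return exposure, outcome, truth


def harmonized_from_truth(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    truth: GroundTruth,
    rsids: Iterable[str] | None = None,
) -> HarmonizedSet:
    """Build a harmonized set directly from the designed instruments.

    Pairs the observed exposure and outcome effects of the causal index
    variants (or an explicit ``rsids`` subset), resolving allele
    orientation from the ground truth. Used by estimator benchmarks that
    evaluate a method on a known instrument set, bypassing selection (and
    therefore free of winner's-curse conditioning).
    """
    wanted = list(rsids) if rsids is not None else truth.causal_rsids
    exp_by = exposure.by_rsid()
    out_by = outcome.by_rsid()
    flipped = dict(zip(truth.rsids, truth.flipped_in_outcome))
    instruments = []
    for rsid in wanted:
        e, o = exp_by[rsid], out_by[rsid]
        Gamma = -o.beta if flipped[rsid] else o.beta
        instruments.append(
            HarmonizedInstrument(
                rsid=rsid, effect_allele=e.effect_allele, other_allele=e.other_allele,
                gamma=e.beta, se_gamma=e.se, Gamma=Gamma, se_Gamma=o.se,
                action="flipped" if flipped[rsid] else "unchanged",
            )
        )
    return HarmonizedSet(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
        instruments=instruments, dropped={},
    )


def simulate_screen(
    n_taxa: int,
    thetas: float | list[float],
    base: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[list[SummaryDataset], SummaryDataset, LDMatrixProvider, dict[str, GroundTruth]]:
    """Simulate a multi-taxon screen against one outcome cohort.

    Each taxon gets its own disjoint variant pool (so instruments are not
    shared across exposures) with causal effect ``thetas[i]``; the outcome
    dataset is the union of every taxon's outcome rows, and the LD provider
    covers all blocks. Returns (exposures, outcome, ld, truths-by-taxon).
    """
    base = base or SimulationConfig()
    if isinstance(thetas, (int, float)):
        thetas = [float(thetas)] * n_taxa
    if len(thetas) != n_taxa:
        raise ValueError("need one theta per taxon")
    exposures: list[SummaryDataset] = []
    out_variants = []
    ld_pairs: dict[tuple[str, str], float] = {}
    truths: dict[str, GroundTruth] = {}
    for i in range(n_taxa):
        cfg = replace(
            base,
            theta=thetas[i],
            taxon_id=f"taxon_{i:03d}",
            rsid_offset=i * base.n_variants,
            seed=seed + i,
        )
        exp, out, truth = simulate_pair(cfg)
        exposures.append(exp)
        out_variants.extend(out.variants)
        ld_pairs.update(truth.ld_pairs)
        truths[cfg.taxon_id] = truth
    outcome = SummaryDataset(
        trait_id=base.outcome_id, trait_role="outcome", variants=out_variants,
        default_n=base.n_out,
    )
    return exposures, outcome, LDMatrixProvider(ld_pairs), truths


SCENARIOS: dict[str, SimulationConfig] = {
    # estimator benchmarks run on the designed instruments, so these four
    # make every variant a (strong) instrument candidate
    "clean_null": SimulationConfig(n_variants=20, n_causal=20, theta=0.0),
    "clean_causal": SimulationConfig(n_variants=20, n_causal=20, theta=0.3),
    "directional_pleiotropy": SimulationConfig(
        n_variants=20, n_causal=20, theta=0.3, pleiotropy_mean=0.01, pleiotropy_sd=0.005
    ),
    "balanced_pleiotropy": SimulationConfig(
        n_variants=20, n_causal=20, theta=0.3, pleiotropy_mean=0.0, pleiotropy_sd=0.01
    ),
    "outlier_contaminated": SimulationConfig(
        n_variants=15, n_causal=15, theta=0.3, n_outliers=1, outlier_scale=10.0
    ),
    # two very strong instruments among nulls: exercises the k=2 IVW-only path
    "low_iv": SimulationConfig(n_variants=40, n_causal=2, theta=0.3,
                               target_median_f=200.0, equal_strength=True),
}


def scenario(name: str) -> SimulationConfig:
    """A documented preset configuration (copy; override with
    ``dataclasses.replace``)."""
    try:
        return replace(SCENARIOS[name])
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; valid: {sorted(SCENARIOS)}") from None
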