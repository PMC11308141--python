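"""Select independent, strongly associated instruments from an exposure GWAS.

The selection cascade mirrors standard two-sample MR practice for
microbiome exposures: keep variants with association p below a relaxed
genome-wide threshold (default 5e-6, strict inequality), prune linkage
disequilibrium by greedy clumping (default r² < 0.001 within 1 Mb), drop
rare variants (minor allele frequency ≤ 0.01), then screen instrument
strength with the per-variant F statistic (keep F > 10).

Variance explained by a single variant is approximated from its summary
statistics as R² = β² / (β² + SE²) (see :func:`snp_r2`); the F statistic
for K instruments explaining R² of an exposure measured in N samples is
F = R²(N − 1 − K) / ((1 − R²)K).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from micromr.gwas_io import SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Thresholds for the instrument-selection cascade."""

    p_threshold: float = 5e-6
    clump_r2: float = 0.001
    clump_window_bp: int = 1_000_000
    maf_min: float = 0.01
    f_min: float = 10.0


class LDMatrixProvider:
    """Pairwise squared-correlation lookup for clumping.

    Stores r² for known pairs; r²(a, a) = 1 by contract, unknown pairs are
    treated as independent (r² = 0) with a warning, since summary-level
    pipelines rarely have LD for every variant pair. Pairs farther apart
    than ``window_bp`` are 0 by contract (the provider itself is
    position-agnostic; the window is enforced by the clumping routine).
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None,
                 window_bp: int = 1_000_000):
        self.window_bp = int(window_bp)
        self._r2: dict[frozenset, float] = {}
        self._known: set[str] = set()
        self._warned: set[str] = set()
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    def add(self, rsid_a: str, rsid_b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r² must be in [0,1], got {r2} for ({rsid_a},{rsid_b})")
        self._r2[frozenset((rsid_a, rsid_b))] = float(r2)
        self._known.update((rsid_a, rsid_b))

    def r2(self, rsid_a: str, rsid_b: str) -> float:
        if rsid_a == rsid_b:
            return 1.0
        for rsid in (rsid_a, rsid_b):
            if rsid not in self._known and rsid not in self._warned:
                logger.warning("rsid %s absent from LD provider; assuming r²=0", rsid)
                self._warned.add(rsid)
        return self._r2.get(frozenset((rsid_a, rsid_b)), 0.0)

    @classmethod
    def from_triplets(cls, path: str | Path, window_bp: int = 1_000_000) -> "LDMatrixProvider":
        """Read 3-column tab-delimited (rsid_a, rsid_b, r²) triplets."""
        df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "r2"], comment="#")
        prov = cls(window_bp=window_bp)
        for a, b, r2 in df.itertuples(index=False):
            prov.add(str(a), str(b), float(r2))
        return prov

    @classmethod
    def from_matrix(cls, path: str | Path, window_bp: int = 1_000_000) -> "LDMatrixProvider":
        """Read a square r² matrix with an rsid header row and index column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        prov = cls(window_bp=window_bp)
        for a in df.index:
            for b in df.columns:
                if str(a) != str(b):
                    prov.add(str(a), str(b), float(df.loc[a, b]))
        return prov

    def write_triplets(self, path: str | Path) -> None:
        rows = sorted((tuple(sorted(k)), v) for k, v in self._r2.items())
        with open(path, "w") as fh:
            for (a, b), r2 in rows:
                fh.write(f"{a}\t{b}\t{r2:.6g}\n")


@dataclass
class InstrumentSet:
    """Instruments selected for one exposure, with per-SNP strength."""

    exposure_id: str
    snps: list[VariantAssociation]
    per_snp_r2: np.ndarray
    per_snp_f: np.ndarray
    n_exposure: int
    attrition: dict[str, int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.snps)

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.per_snp_f)) if self.k else float("nan")

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.snps]


def _replace_variants(dataset: SummaryDataset, variants: list[VariantAssociation]) -> SummaryDataset:
    return SummaryDataset(
        trait_id=dataset.trait_id,
        trait_role=dataset.trait_role,
        variants=variants,
        population=dataset.population,
        default_n=dataset.default_n,
    )


def filter_by_pvalue(dataset: SummaryDataset, threshold: float = 5e-6) -> SummaryDataset:
    """Retain variants with p strictly below ``threshold``, order preserved."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    kept = [v for v in dataset.variants if v.pval < threshold]
    return _replace_variants(dataset, kept)


def filter_by_maf(dataset: SummaryDataset, maf_min: float = 0.01) -> SummaryDataset:
    """Remove variants whose minor-allele frequency is ≤ ``maf_min``.

    Variants with no reported frequency pass with a warning (frequency-free
    sources cannot be screened on MAF).
    """
    kept = []
    n_missing = 0
    for v in dataset.variants:
        maf = v.minor_allele_frequency()
        if maf is None:
            n_missing += 1
            kept.append(v)
        elif maf > maf_min:
            kept.append(v)
    if n_missing:
        logger.warning(
            "%s: %d variants lack eaf; MAF filter not applied to them", dataset.trait_id, n_missing
        )
    return _replace_variants(dataset, kept)


def ld_clump(
    dataset: SummaryDataset,
    ld: LDMatrixProvider,
    r2_max: float = 0.001,
    window_bp: int = 1_000_000,
) -> SummaryDataset:
    """Greedy index-variant clumping.

    Sort by ascending p (ties broken by (chrom, pos, rsid) so the result is
    invariant to input row order); repeatedly keep the best remaining
    variant and discard every unkept variant on the same chromosome within
    ``window_bp`` (closed interval on |Δpos|) whose r² with it is ≥
    ``r2_max``. Returns survivors in ascending-p order.
    """
    if not (0.0 < r2_max < 1.0):
        raise ValueError(f"r2_max must be in (0,1), got {r2_max}")
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    pool = sorted(dataset.variants, key=lambda v: (v.pval, v.chrom, v.pos, v.rsid))
    kept: list[VariantAssociation] = []
    removed: set[str] = set()
    for v in pool:
        if v.rsid in removed:
            continue
        kept.append(v)
        for u in pool:
            if u.rsid in removed or u.rsid == v.rsid:
                continue
            if u.chrom == v.chrom and abs(u.pos - v.pos) <= window_bp:
                if ld.r2(v.rsid, u.rsid) >= r2_max:
                    removed.add(u.rsid)
    return _replace_variants(dataset, kept)


def snp_r2(beta: float, se: float) -> float:
    """Per-variant variance explained, R² = β² / (β² + SE²)."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    b2 = float(beta) ** 2
    return b2 / (b2 + float(se) ** 2)


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument-strength F = R²(N − 1 − K) / ((1 − R²)K).

    ``n`` is the exposure sample size and ``k`` the number of instruments
    jointly explaining ``r2`` of the exposure variance. For a single
    variant, pass k = 1.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must be in [0,1), got {r2}")
    if k < 1:
        raise ValueError(f"k must be ≥ 1, got {k}")
    if n <= k + 1:
        raise ValueError(f"n must exceed k+1, got n={n}, k={k}")
    return r2 * (n - 1 - k) / ((1.0 - r2) * k)


def filter_by_f(instruments: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Remove instruments with per-SNP F ≤ ``f_min``; mean F recomputed."""
    keep = instruments.per_snp_f > f_min
    return InstrumentSet(
        exposure_id=instruments.exposure_id,
        snps=[v for v, k in zip(instruments.snps, keep) if k],
        per_snp_r2=instruments.per_snp_r2[keep],
        per_snp_f=instruments.per_snp_f[keep],
        n_exposure=instruments.n_exposure,
        attrition=dict(instruments.attrition),
    )


def select_instruments(
    dataset: SummaryDataset,
    ld: LDMatrixProvider,
    config: SelectionConfig | None = None,
) -> InstrumentSet | None:
    """Run the full selection cascade on an exposure dataset.

    Order: p-value screen → LD clump → MAF filter → per-SNP R²/F → F screen.
    Stage-by-stage attrition counts are recorded on the returned
    :class:`InstrumentSet`. Returns ``None`` when no instrument survives
    (the caller decides whether that skips the exposure or is an error).
    """
    if dataset.trait_role != "exposure":
        raise ValueError(f"instrument selection needs an exposure dataset, got {dataset.trait_role}")
    cfg = config or SelectionConfig()
    attrition = {"input": len(dataset)}

    stage = filter_by_pvalue(dataset, cfg.p_threshold)
    attrition["after_pvalue"] = len(stage)
    stage = ld_clump(stage, ld, cfg.clump_r2, cfg.clump_window_bp)
    attrition["after_clump"] = len(stage)
    stage = filter_by_maf(stage, cfg.maf_min)
    attrition["after_maf"] = len(stage)

    if len(stage) == 0:
        logger.info("%s: no instruments after filtering", dataset.trait_id)
        return None

    n_exp = max(v.n for v in stage.variants)
    r2 = np.array([snp_r2(v.beta, v.se) for v in stage.variants])
    f = np.array([f_statistic(x, n_exp, 1) for x in r2])
    inst = InstrumentSet(
        exposure_id=dataset.trait_id,
        snps=list(stage.variants),
        per_snp_r2=r2,
        per_snp_f=f,
        n_exposure=n_exp,
        attrition=attrition,
    )
    inst = filter_by_f(inst, cfg.f_min)
    inst.attrition["after_f"] = inst.k
    if inst.k == 0:
        logger.info("%s: no instruments with F > %g", dataset.trait_id, cfg.f_min)
        return None
    return inst
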