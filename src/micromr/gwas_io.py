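"""Read, validate, and write GWAS summary statistics and MR result tables.

Summary-statistic files are tab- (or whitespace-) delimited text with a
header row, optionally gzip-compressed, one row per variant. Column naming
differs between consortia, so reading is driven by an explicit column map;
presets are shipped for the MiBioGen, FinnGen R10 and IEU OpenGWAS export
dialects. There is deliberately no auto-detection: a silent misread of the
effect-allele column flips every downstream causal estimate.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: Sentinel written for statistics that are inapplicable for a row
#: (e.g. Egger columns for a two-instrument exposure).
NA_SENTINEL = "-"

#: Significant digits used when writing numeric table cells. Chosen so that
#: a write→read round trip preserves values to at least 10 significant digits.
_FLOAT_FMT = "%.12g"

STANDARD_FIELDS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: Column-map presets for common summary-statistic dialects. ``eaf`` and ``n``
#: may be mapped to None when the dialect does not provide them.
COLUMN_PRESETS: dict[str, dict[str, str | None]] = {
    # identity mapping: files written by micromr itself
    "standard": {f: f for f in (
        "rsid", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pval", "n",
    )},
    "mibiogen": {
        "rsid": "rsID",
        "chrom": "chr",
        "pos": "bp",
        "effect_allele": "eff.allele",
        "other_allele": "ref.allele",
        "eaf": None,
        "beta": "beta",
        "se": "SE",
        "pval": "P.weightedSumZ",
        "n": "N",
    },
    "finngen_r10": {
        "rsid": "rsids",
        "chrom": "#chrom",
        "pos": "pos",
        "effect_allele": "alt",
        "other_allele": "ref",
        "eaf": "af_alt",
        "beta": "beta",
        "se": "sebeta",
        "pval": "pval",
        "n": None,
    },
    "ieu": {
        "rsid": "SNP",
        "chrom": "chr",
        "pos": "position",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "eaf",
        "beta": "beta",
        "se": "se",
        "pval": "pval",
        "n": "samplesize",
    },
}


class MissingColumnError(KeyError):
    """A mapped column is absent from the input file."""


class EmptyDatasetError(ValueError):
    """No valid variant rows survived parsing."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the signed effect per copy of ``effect_allele`` (log-odds for
    binary traits, SD units for normalised quantitative traits); ``eaf`` is
    the effect-allele frequency and may be ``None`` when the source file does
    not report frequencies (MiBioGen-style files).
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def is_valid(self) -> bool:
        return (
            self.effect_allele in VALID_ALLELES
            and self.other_allele in VALID_ALLELES
            and self.effect_allele != self.other_allele
            and self.pos >= 1
            and math.isfinite(self.beta)
            and self.se > 0
            and math.isfinite(self.se)
            and 0.0 < self.pval <= 1.0
            and self.n >= 1
            and (self.eaf is None or 0.0 <= self.eaf <= 1.0)
        )

    def minor_allele_frequency(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SummaryDataset:
    """An ordered set of variant associations for one trait.

    ``trait_role`` is ``"exposure"`` or ``"outcome"``; ``n_dropped`` counts
    input rows discarded during parsing for violating variant invariants.
    """

    trait_id: str
    trait_role: str
    variants: list[VariantAssociation]
    population: str = ""
    default_n: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_role not in ("exposure", "outcome"):
            raise ValueError(f"trait_role must be exposure|outcome, got {self.trait_role!r}")
        rsids = [v.rsid for v in self.variants]
        if len(rsids) != len(set(rsids)):
            seen: set[str] = set()
            dupes = {r for r in rsids if r in seen or seen.add(r)}  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate rsids in dataset {self.trait_id!r}: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.variants)

    def by_rsid(self) -> dict[str, VariantAssociation]:
        return {v.rsid: v for v in self.variants}

    def subset(self, rsids: Iterable[str]) -> "SummaryDataset":
        """Order-preserving restriction to ``rsids`` (drop tally not carried)."""
        keep = set(rsids)
        return SummaryDataset(
            trait_id=self.trait_id,
            trait_role=self.trait_role,
            variants=[v for v in self.variants if v.rsid in keep],
            population=self.population,
            default_n=self.default_n,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": v.rsid,
                "chrom": v.chrom,
                "pos": v.pos,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
                "eaf": np.nan if v.eaf is None else v.eaf,
                "beta": v.beta,
                "se": v.se,
                "pval": v.pval,
                "n": v.n,
            }
            for v in self.variants
        ]
        return pd.DataFrame(rows, columns=list(STANDARD_FIELDS))


def _coerce_float(value) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str | None] | str,
    trait_id: str,
    trait_role: str,
    default_n: int = 0,
    population: str = "",
) -> SummaryDataset:
    """Parse a summary-statistic file into a validated :class:`SummaryDataset`.

    Parameters
    ----------
    column_map
        Mapping from standard field names (:data:`STANDARD_FIELDS`) to column
        names in the file, or the name of a preset in :data:`COLUMN_PRESETS`.
        ``eaf`` and ``n`` may map to ``None`` (missing frequency / constant
        sample size ``default_n``).
    default_n
        Sample size applied when the file carries no per-variant N.

    Rows violating variant invariants (non-ACGT or identical alleles, se ≤ 0,
    p outside (0, 1], non-finite beta) are dropped and tallied in
    ``SummaryDataset.n_dropped``. Raises :class:`MissingColumnError` if a
    mapped column is absent and :class:`EmptyDatasetError` if no row survives.
    """
    if isinstance(column_map, str):
        try:
            column_map = COLUMN_PRESETS[column_map]
        except KeyError:
            raise KeyError(
                f"unknown column preset {column_map!r}; available: {sorted(COLUMN_PRESETS)}"
            ) from None

    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment=None)
    for std, col in column_map.items():
        if std not in STANDARD_FIELDS:
            raise MissingColumnError(f"unknown standard field {std!r}")
        if col is not None and col not in df.columns:
            raise MissingColumnError(f"mapped column {col!r} (for {std!r}) not in {list(df.columns)}")

    variants: list[VariantAssociation] = []
    n_dropped = 0
    seen_rsids: set[str] = set()
    for _, row in df.iterrows():
        def get(field_name: str):
            col = column_map.get(field_name)
            return None if col is None else row[col]

        rsid = get("rsid")
        if rsid is None or pd.isna(rsid):
            n_dropped += 1
            continue
        rsid = str(rsid)
        if rsid in seen_rsids:
            n_dropped += 1
            logger.warning("duplicate rsid %s in %s: keeping first occurrence", rsid, path)
            continue
        eaf_raw = get("eaf")
        eaf = None
        if eaf_raw is not None and not pd.isna(eaf_raw):
            eaf = _coerce_float(eaf_raw)
        n_raw = get("n")
        n = default_n if n_raw is None or pd.isna(n_raw) else int(float(n_raw))
        pos_raw = get("pos")
        try:
            # position 1 stands in for "unknown" (files with no position
            # column are never clumped, which is the only position use)
            pos = int(float(pos_raw)) if pos_raw is not None and not pd.isna(pos_raw) else 1
        except (TypeError, ValueError):
            pos = 0
        variant = VariantAssociation(
            rsid=rsid,
            chrom="" if get("chrom") is None or pd.isna(get("chrom")) else str(get("chrom")),
            pos=pos,
            effect_allele=str(get("effect_allele") or "").upper(),
            other_allele=str(get("other_allele") or "").upper(),
            eaf=eaf,
            beta=_coerce_float(get("beta")),
            se=_coerce_float(get("se")),
            pval=_coerce_float(get("pval")),
            n=n,
        )
        if variant.is_valid():
            variants.append(variant)
            seen_rsids.add(rsid)
        else:
            n_dropped += 1

    if n_dropped:
        logger.info("%s: dropped %d invalid rows of %d", path, n_dropped, len(df))
    if not variants:
        raise EmptyDatasetError(
            f"no valid variant rows in {path} ({n_dropped} dropped of {len(df)})"
        )
    return SummaryDataset(
        trait_id=trait_id,
        trait_role=trait_role,
        variants=variants,
        population=population,
        default_n=default_n,
        n_dropped=n_dropped,
    )


def write_summary_stats(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset in the package's standard tab-delimited dialect
    (readable back with ``column_map="standard"``)."""
    df = dataset.to_frame()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = [_fmt(v) if not (isinstance(v, float) and math.isnan(v)) else "NA" for v in df[col]]
    df.to_csv(path, sep="\t", index=False)


RESULT_COLUMNS = [
    "population",
    "taxon",
    "method",
    "n_snp",
    "mean_f",
    "b",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "pval",
    "fdr",
    "q",
    "q_pval",
    "egger_intercept",
    "egger_intercept_pval",
    "presso_global_pval",
]

_NUMERIC_RESULT_COLUMNS = RESULT_COLUMNS[3:]


def _fmt(value) -> str:
    if value is None:
        return NA_SENTINEL
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, float) and math.isnan(value):
        return NA_SENTINEL
    return _FLOAT_FMT % value


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """Flatten :class:`~micromr.pipeline.TaxonResult` objects to one row per
    (taxon, method)."""
    rows = []
    for res in results:
        sens = res.sensitivity
        for est in res.estimates:
            rows.append(
                {
                    "population": res.population,
                    "taxon": res.taxon_id,
                    "method": est.method,
                    "n_snp": est.n_snp,
                    "mean_f": res.instruments.mean_f if res.instruments is not None else None,
                    "b": est.b,
                    "se": est.se,
                    "or": est.odds_ratio,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pval": est.pval,
                    "fdr": res.fdr if est.method in ("ivw", "wald_ratio") else None,
                    "q": None if sens is None else sens.q,
                    "q_pval": None if sens is None else sens.q_pval,
                    "egger_intercept": None if sens is None else sens.egger_intercept,
                    "egger_intercept_pval": None if sens is None else sens.egger_intercept_pval,
                    "presso_global_pval": None if sens is None else sens.presso_global_pval,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_table(results: Sequence, path: str | Path) -> None:
    """Write the per-(taxon, method) statistics table, tab-delimited.

    Inapplicable cells (e.g. Egger intercept when fewer than three
    instruments were available) are written as ``"-"``. Raises ``ValueError``
    on an empty result collection.
    """
    if len(results) == 0:
        raise ValueError("refusing to write an empty results table")
    df = results_to_frame(results)
    out = df.copy()
    for col in _NUMERIC_RESULT_COLUMNS:
        out[col] = [_fmt(v) for v in df[col]]
    out.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_results_table`; ``"-"`` → NaN."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_SENTINEL], keep_default_na=False)
    for col in _NUMERIC_RESULT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_run_metadata(metadata: Mapping, path: str | Path) -> None:
    """Serialise run metadata (thresholds, seed, per-stage counts) as JSON."""
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
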