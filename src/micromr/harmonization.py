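"""Align exposure and outcome effects onto a common effect allele.

Two-sample MR pairs each instrument's exposure effect γ with the outcome
effect Γ measured in a different cohort, so the two files may report the
same variant on opposite allele orientations. Harmonization resolves this:
same alleles → keep as is; swapped alleles → negate the outcome beta;
anything else → drop. Palindromic variants (A/T or C/G) are dropped
unconditionally, because their strand is ambiguous between cohorts and the
exposure source may lack the allele frequencies needed to resolve it.
No strand-flip rescue is attempted: complementary-allele matches are
treated as mismatches, the safer choice absent strand metadata.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from micromr.gwas_io import SummaryDataset, VALID_ALLELES
from micromr.instrument_selection import InstrumentSet

logger = logging.getLogger(__name__)

RETAINED_ACTIONS = ("unchanged", "flipped")
DROP_ACTIONS = ("dropped_palindromic", "dropped_mismatch", "dropped_missing")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One instrument with exposure (γ) and outcome (Γ) effects on a common
    effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    action: str


@dataclass
class HarmonizedSet:
    """Retained instruments plus a tally of drops by reason."""

    exposure_id: str
    outcome_id: str
    instruments: list[HarmonizedInstrument]
    dropped: dict[str, int] = field(default_factory=dict)
    #: (rsid, action) for every input instrument, in input order — keeps the
    #: fate of dropped variants reportable per SNP
    actions: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def rsids(self) -> list[str]:
        return [i.rsid for i in self.instruments]

    def without(self, rsids) -> "HarmonizedSet":
        """Copy of this set with ``rsids`` removed (drop tally not altered)."""
        excl = set(rsids)
        return HarmonizedSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            instruments=[i for i in self.instruments if i.rsid not in excl],
            dropped=dict(self.dropped),
        )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    for a in (effect_allele, other_allele):
        if a not in VALID_ALLELES:
            raise ValueError(f"invalid allele {a!r}")
    pair = frozenset((effect_allele, other_allele))
    return pair == frozenset("AT") or pair == frozenset("CG")


def harmonize(instruments: InstrumentSet, outcome: SummaryDataset) -> HarmonizedSet:
    """Pair each instrument with its outcome association.

    Per instrument: absent from the outcome → ``dropped_missing``;
    palindromic allele pair → ``dropped_palindromic`` (unconditional);
    outcome alleles identical → retained ``unchanged``; outcome alleles
    swapped → outcome beta negated, retained ``flipped``; any other
    combination (including an outcome rsid appearing more than once) →
    ``dropped_mismatch``.
    """
    if instruments.k == 0:
        raise ValueError("cannot harmonize an empty instrument set")

    rsid_counts = Counter(v.rsid for v in outcome.variants)
    outcome_by_rsid = {v.rsid: v for v in outcome.variants}

    retained: list[HarmonizedInstrument] = []
    dropped = Counter({a: 0 for a in DROP_ACTIONS})
    actions: list[tuple[str, str]] = []

    def drop(rsid: str, reason: str) -> None:
        dropped[reason] += 1
        actions.append((rsid, reason))

    for exp in instruments.snps:
        if exp.rsid not in outcome_by_rsid:
            drop(exp.rsid, "dropped_missing")
            continue
        if is_palindromic(exp.effect_allele, exp.other_allele):
            drop(exp.rsid, "dropped_palindromic")
            continue
        if rsid_counts[exp.rsid] > 1:
            logger.warning("rsid %s has multiple outcome records; dropping as ambiguous", exp.rsid)
            drop(exp.rsid, "dropped_mismatch")
            continue
        out = outcome_by_rsid[exp.rsid]
        if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
            action, Gamma = "unchanged", out.beta
        elif (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele):
            action, Gamma = "flipped", -out.beta
        else:
            drop(exp.rsid, "dropped_mismatch")
            continue
        actions.append((exp.rsid, action))
        retained.append(
            HarmonizedInstrument(
                rsid=exp.rsid,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                gamma=exp.beta,
                se_gamma=exp.se,
                Gamma=Gamma,
                se_Gamma=out.se,
                action=action,
            )
        )

    hs = HarmonizedSet(
        exposure_id=instruments.exposure_id,
        outcome_id=outcome.trait_id,
        instruments=retained,
        dropped=dict(dropped),
        actions=actions,
    )
    if not retained:
        logger.info(
            "%s vs %s: nothing to harmonize (%s)", instruments.exposure_id, outcome.trait_id, dict(dropped)
        )
    return hs
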