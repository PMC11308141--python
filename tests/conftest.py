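import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from micromr.gwas_io import SummaryDataset, VariantAssociation
from micromr.harmonization import HarmonizedInstrument, HarmonizedSet


def make_hs(gamma, se_gamma, Gamma, se_Gamma, exposure_id="exp", outcome_id="out"):
    """Harmonized set from plain effect arrays (rs0, rs1, ... labels)."""
    instruments = [
        HarmonizedInstrument(
            rsid=f"rs{i}", effect_allele="A", other_allele="G",
            gamma=float(g), se_gamma=float(sg), Gamma=float(G), se_Gamma=float(sG),
            action="unchanged",
        )
        for i, (g, sg, G, sG) in enumerate(zip(gamma, se_gamma, Gamma, se_Gamma))
    ]
    return HarmonizedSet(exposure_id=exposure_id, outcome_id=outcome_id,
                         instruments=instruments, dropped={})


def make_variant(rsid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                 beta=0.1, se=0.02, pval=1e-8, n=10000):
    return VariantAssociation(rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea,
                              other_allele=oa, eaf=eaf, beta=beta, se=se,
                              pval=pval, n=n)


def make_dataset(variants, trait_id="exp", trait_role="exposure", default_n=10000):
    return SummaryDataset(trait_id=trait_id, trait_role=trait_role,
                          variants=list(variants), default_n=default_n)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noisy_hs(rng):
    """20 instruments around a true ratio of 0.3 with realistic noise."""
    j = 20
    gamma = rng.uniform(0.04, 0.12, j) * rng.choice([-1, 1], j)
    se_gamma = np.full(j, 0.01)
    se_Gamma = np.full(j, 0.01)
    Gamma = 0.3 * gamma + rng.normal(0, 0.01, j)
    return make_hs(gamma, se_gamma, Gamma, se_Gamma)
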