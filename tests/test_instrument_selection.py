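import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micromr.instrument_selection import (
    InstrumentSet,
    LDMatrixProvider,
    SelectionConfig,
    f_statistic,
    filter_by_f,
    filter_by_maf,
    filter_by_pvalue,
    ld_clump,
    select_instruments,
    snp_r2,
)

from conftest import make_dataset, make_variant


class TestFilterByPvalue:
    def test_strict_inequality_at_threshold(self):
        ds = make_dataset([
            make_variant(rsid=f"rs{i}", pval=p)
            for i, p in enumerate([1e-7, 4.9e-6, 5e-6, 0.01])
        ])
        kept = filter_by_pvalue(ds, 5e-6)
        assert [v.rsid for v in kept.variants] == ["rs0", "rs1"]

    def test_threshold_one_keeps_everything_below_one(self):
        ds = make_dataset([make_variant(rsid=f"rs{i}", pval=p)
                           for i, p in enumerate([0.1, 0.5, 0.999])])
        assert len(filter_by_pvalue(ds, 1.0)) == 3

    def test_retained_count_matches_brute_force(self, rng):
        pvals = rng.uniform(0, 1, 1000).clip(1e-12, 1.0)
        ds = make_dataset([make_variant(rsid=f"rs{i}", pval=p) for i, p in enumerate(pvals)])
        thr = 0.3
        assert len(filter_by_pvalue(ds, thr)) == int(np.sum(pvals < thr))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_by_pvalue(make_dataset([make_variant()]), 0.0)


class TestFilterByMaf:
    @pytest.mark.parametrize("eaf,kept", [(0.01, False), (0.5, True), (0.995, False),
                                          (0.02, True), (0.992, False)])
    def test_boundary_and_symmetry(self, eaf, kept):
        ds = make_dataset([make_variant(eaf=eaf)])
        assert (len(filter_by_maf(ds, 0.01)) == 1) is kept

    def test_missing_eaf_passes(self):
        ds = make_dataset([make_variant(eaf=None)])
        assert len(filter_by_maf(ds)) == 1


class TestSnpR2AndF:
    def test_zero_beta(self):
        assert snp_r2(0.0, 0.01) == 0.0

    def test_beta_equals_se(self):
        assert snp_r2(0.012, 0.012) == pytest.approx(0.5, abs=1e-15)

    def test_direct_arithmetic(self):
        beta, se = -0.031, 0.012
        assert snp_r2(beta, se) == pytest.approx(beta**2 / (beta**2 + se**2), rel=1e-12)

    def test_se_must_be_positive(self):
        with pytest.raises(ValueError):
            snp_r2(0.1, 0.0)

    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0), st.floats(1.001, 2.0))
    def test_monotone_in_abs_beta_and_se(self, beta, se, factor):
        assert snp_r2(beta * factor, se) > snp_r2(beta, se)
        assert snp_r2(beta, se * factor) < snp_r2(beta, se)

    def test_f_zero_r2(self):
        assert f_statistic(0.0, 1000, 5) == 0.0

    @pytest.mark.parametrize("k", [1, 3, 10])
    def test_f_forced_value(self, k):
        # r2 = 0.5 and n = k + 2 collapse the formula to 1/k
        assert f_statistic(0.5, k + 2, k) == pytest.approx(1.0 / k, rel=1e-12)

    def test_f_direct_arithmetic(self):
        r2, n, k = 0.01, 18340, 5
        assert f_statistic(r2, n, k) == pytest.approx(
            r2 * (n - 1 - k) / ((1 - r2) * k), rel=1e-12)

    def test_f_monotone_in_r2(self):
        fs = [f_statistic(r2, 18340, 1) for r2 in np.linspace(0, 0.99, 50)]
        assert np.all(np.diff(fs) > 0)

    def test_f_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100, 1)
        with pytest.raises(ValueError):
            f_statistic(0.5, 2, 1)


def _brute_force_clump(variants, ld, r2_max, window):
    """Independent greedy reference: explicit pairwise scan."""
    pool = sorted(variants, key=lambda v: (v.pval, v.chrom, v.pos, v.rsid))
    kept, removed = [], set()
    for v in pool:
        if v.rsid in removed:
            continue
        kept.append(v)
        for u in pool:
            if u.rsid in removed or u.rsid == v.rsid:
                continue
            same_window = u.chrom == v.chrom and abs(u.pos - v.pos) <= window
            if same_window and ld.r2(v.rsid, u.rsid) >= r2_max:
                removed.add(u.rsid)
    return [v.rsid for v in kept]


class TestLdClump:
    def test_correlated_pair_keeps_best_p(self):
        a = make_variant(rsid="rsA", pos=1_000_000, pval=1e-8)
        b = make_variant(rsid="rsB", pos=1_500_000, pval=1e-7)
        ld = LDMatrixProvider({("rsA", "rsB"): 0.5})
        kept = ld_clump(make_dataset([a, b]), ld)
        assert [v.rsid for v in kept.variants] == ["rsA"]

    def test_out_of_window_pair_both_kept(self):
        a = make_variant(rsid="rsA", pos=1_000_000, pval=1e-8)
        b = make_variant(rsid="rsB", pos=3_000_000, pval=1e-7)
        ld = LDMatrixProvider({("rsA", "rsB"): 0.9})
        kept = ld_clump(make_dataset([a, b]), ld, window_bp=1_000_000)
        assert len(kept) == 2

    def test_blocks_match_brute_force(self, rng):
        # 50 SNPs in 5 LD blocks of 10; within-block r² = 0.9
        variants, pairs = [], {}
        for b in range(5):
            ids = [f"rs{b}_{i}" for i in range(10)]
            for i, rid in enumerate(ids):
                variants.append(make_variant(
                    rsid=rid, chrom=str(b + 1), pos=1_000_000 + i * 10_000,
                    pval=float(rng.uniform(1e-10, 1e-4))))
                for j in range(i):
                    pairs[(ids[j], rid)] = 0.9
        ld = LDMatrixProvider(pairs)
        kept = ld_clump(make_dataset(variants), ld, 0.001, 1_000_000)
        assert [v.rsid for v in kept.variants] == _brute_force_clump(
            variants, ld, 0.001, 1_000_000)
        assert len(kept) == 5  # one index SNP per block

    def test_invariant_to_input_order(self, rng):
        variants, pairs = [], {}
        for i in range(20):
            variants.append(make_variant(rsid=f"rs{i}", pos=1_000_000 + i * 50_000,
                                         pval=float(rng.uniform(1e-9, 1e-5))))
        for i in range(20):
            for j in range(i):
                if rng.uniform() < 0.3:
                    pairs[(f"rs{j}", f"rs{i}")] = float(rng.uniform(0.002, 1.0))
        ld = LDMatrixProvider(pairs)
        base = [v.rsid for v in ld_clump(make_dataset(variants), ld).variants]
        shuffled = list(variants)
        rng.shuffle(shuffled)
        assert [v.rsid for v in ld_clump(make_dataset(shuffled), ld).variants] == base

    def test_unknown_rsid_treated_independent(self):
        a = make_variant(rsid="rsA", pos=1_000_000, pval=1e-8)
        b = make_variant(rsid="rsUnknown", pos=1_100_000, pval=1e-7)
        kept = ld_clump(make_dataset([a, b]), LDMatrixProvider({}))
        assert len(kept) == 2


class TestFilterByF:
    def test_all_strong_unchanged(self):
        inst = InstrumentSet("x", [make_variant(rsid="rs1"), make_variant(rsid="rs2")],
                             np.array([0.01, 0.01]), np.array([25.0, 25.0]), 10000)
        assert filter_by_f(inst).k == 2

    def test_weak_removed_mean_recomputed(self):
        inst = InstrumentSet("x", [make_variant(rsid="rs1"), make_variant(rsid="rs2")],
                             np.array([0.001, 0.01]), np.array([5.0, 15.0]), 10000)
        out = filter_by_f(inst, 10.0)
        assert out.k == 1 and out.mean_f == 15.0


class TestSelectInstruments:
    def _strong_exposure(self, n_strong=8, n_null=20):
        variants = []
        for i in range(n_strong):
            variants.append(make_variant(
                rsid=f"sig{i}", chrom=str(i + 1), pos=10_000_000,
                beta=0.08, se=0.012, pval=1e-8, eaf=0.3))
        for i in range(n_null):
            variants.append(make_variant(
                rsid=f"null{i}", chrom=str(i % 22 + 1), pos=90_000_000,
                beta=0.001, se=0.012, pval=0.5, eaf=0.3))
        return make_dataset(variants)

    def test_independent_strong_snps_all_selected(self):
        inst = select_instruments(self._strong_exposure(), LDMatrixProvider({}))
        assert inst.k == 8
        assert inst.attrition["input"] == 28
        assert inst.attrition["after_pvalue"] == 8

    def test_no_snp_below_threshold_gives_none(self):
        ds = make_dataset([make_variant(pval=0.5)])
        assert select_instruments(ds, LDMatrixProvider({})) is None

    def test_requires_exposure_role(self):
        ds = make_dataset([make_variant()], trait_role="outcome")
        with pytest.raises(ValueError):
            select_instruments(ds, LDMatrixProvider({}))

    def test_every_stage_contracts(self):
        inst = select_instruments(self._strong_exposure(), LDMatrixProvider({}))
        counts = [inst.attrition[s] for s in
                  ("input", "after_pvalue", "after_clump", "after_maf", "after_f")]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert inst.mean_f == pytest.approx(float(np.mean(inst.per_snp_f)))
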