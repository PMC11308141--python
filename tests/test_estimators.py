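import dataclasses
import math

import numpy as np
import pytest

import micromr as m
from micromr.estimators import (
    EstimatorConfig,
    egger,
    estimate_all,
    ivw,
    mode_based,
    ratio_terms,
    simple_median,
    wald_ratio,
    weighted_median,
)

from conftest import make_hs


def hs_from_ratios(ratios, se_Gamma=0.01, gamma=0.1):
    """Noise-free set in which instrument j has Wald ratio ratios[j]."""
    j = len(ratios)
    g = np.full(j, gamma)
    return make_hs(g, np.full(j, 0.005), np.array(ratios) * g, np.full(j, se_Gamma))


class TestWaldRatio:
    def test_arithmetic(self):
        hs = make_hs([0.1], [0.01], [0.05], [0.02])
        est = wald_ratio(hs.instruments[0])
        assert est.b == pytest.approx(0.5) and est.se == pytest.approx(0.2)

    def test_null_outcome_gives_unit_or(self):
        hs = make_hs([0.1], [0.01], [0.0], [0.02])
        est = wald_ratio(hs.instruments[0])
        assert est.b == 0.0 and est.odds_ratio == 1.0

    def test_zero_gamma_rejected(self):
        hs = make_hs([0.0], [0.01], [0.05], [0.02])
        with pytest.raises(ValueError):
            wald_ratio(hs.instruments[0])

    def test_matches_direct_arithmetic_on_random_inputs(self, rng):
        for _ in range(50):
            g, G, sG = rng.normal(0.1, 0.03), rng.normal(0, 0.05), rng.uniform(0.01, 0.05)
            if abs(g) < 1e-3:
                continue
            est = wald_ratio(make_hs([g], [0.01], [G], [sG]).instruments[0])
            assert est.b == pytest.approx(G / g, rel=1e-12)
            assert est.se == pytest.approx(sG / abs(g), rel=1e-12)


class TestIVW:
    def test_consensus_ratio_reproduced_exactly(self):
        hs = hs_from_ratios([0.4, 0.4])
        for model in ("fixed", "random"):
            est = ivw(hs, model)
            assert est.b == pytest.approx(0.4, rel=1e-12)
        # no heterogeneity → Q = 0 → random-effects SE equals fixed
        assert ivw(hs, "fixed").se == ivw(hs, "random").se

    def test_single_instrument_delegates_to_wald(self):
        hs = make_hs([0.1], [0.01], [0.05], [0.02])
        est = ivw(hs)
        ref = wald_ratio(hs.instruments[0])
        assert (est.b, est.se, est.method) == (ref.b, ref.se, "wald_ratio")

    def test_equal_weights_equal_mean_of_ratios(self):
        ratios = [0.1, 0.3, 0.8, -0.2]
        hs = hs_from_ratios(ratios)
        assert ivw(hs, "fixed").b == pytest.approx(np.mean(ratios), rel=1e-12)

    def test_matches_weight_normalized_mean(self, noisy_hs):
        terms = ratio_terms(noisy_hs)
        expected = sum(t.weight * t.ratio for t in terms) / sum(t.weight for t in terms)
        assert ivw(noisy_hs).b == pytest.approx(expected, rel=1e-12)

    def test_simulation_recovery(self):
        """Mean IVW estimate over replicates tracks the true θ = 0.3."""
        bs = []
        for s in range(300):
            cfg = dataclasses.replace(m.scenario("clean_causal"), seed=140_000 + s)
            exp, out, truth = m.simulate_pair(cfg)
            bs.append(ivw(m.harmonized_from_truth(exp, out, truth)).b)
        assert abs(np.mean(bs) - 0.3) < 0.02

    def test_unknown_model_rejected(self, noisy_hs):
        with pytest.raises(ValueError):
            ivw(noisy_hs, "bayesian")


class TestEgger:
    def test_noise_free_proportional(self):
        hs = hs_from_ratios([0.5] * 5, gamma=0.1)
        # vary gamma so the regression has leverage
        g = np.array([0.05, 0.08, 0.11, 0.14, 0.17])
        hs = make_hs(g, np.full(5, 0.005), 0.5 * g, np.full(5, 0.01))
        est = egger(hs)
        assert est.b == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)

    def test_noise_free_affine(self):
        g = np.array([0.05, 0.08, 0.11, 0.14, 0.17])
        alpha, theta = 0.02, 0.5
        hs = make_hs(g, np.full(5, 0.005), alpha + theta * g, np.full(5, 0.01))
        est = egger(hs)
        assert est.b == pytest.approx(theta, abs=1e-10)
        assert est.intercept == pytest.approx(alpha, abs=1e-10)

    def test_orientation_convention_gamma_positive(self):
        """Flipping the reported allele of an instrument (negating γ and Γ)
        must not change the Egger fit."""
        g = np.array([0.05, 0.08, -0.11, 0.14, -0.17])
        G = 0.02 + 0.5 * np.abs(g)
        G = np.where(g < 0, -G, G)
        est = egger(make_hs(g, np.full(5, 0.005), G, np.full(5, 0.01)))
        ref = egger(make_hs(np.abs(g), np.full(5, 0.005), np.abs(G), np.full(5, 0.01)))
        assert est.b == pytest.approx(ref.b, rel=1e-12)
        assert est.intercept == pytest.approx(ref.intercept, rel=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger(hs_from_ratios([0.1, 0.2]))


class TestMedians:
    def test_equal_weight_median_identity(self):
        est = simple_median(hs_from_ratios([0.1, 0.5, 0.9]), n_boot=50, seed=1)
        assert est.b == pytest.approx(0.5, abs=1e-10)

    def test_concentrated_weight_pins_estimate(self):
        # one instrument carries ~98% of the weight (tiny outcome SE)
        g = np.full(4, 0.1)
        G = np.array([0.01, 0.05, 0.09, 0.05])
        sG = np.array([0.1, 0.1, 0.1, 0.01])
        est = weighted_median(make_hs(g, np.full(4, 0.005), G, sG), n_boot=50, seed=1)
        assert est.b == pytest.approx(0.5, abs=0.02)

    def test_robust_to_minority_invalid(self):
        bs = []
        for s in range(200):
            cfg = dataclasses.replace(
                m.scenario("clean_causal"), seed=150_000 + s, n_variants=10,
                n_causal=10, equal_strength=True, n_invalid=4, invalid_ratio_offset=1.0)
            exp, out, truth = m.simulate_pair(cfg)
            bs.append(weighted_median(m.harmonized_from_truth(exp, out, truth),
                                      n_boot=100, seed=s).b)
        bs = np.array(bs)
        assert abs(bs.mean() - 0.3) < 3 * bs.std(ddof=1)

    def test_seeded_bootstrap_reproducible(self, noisy_hs):
        a = weighted_median(noisy_hs, n_boot=200, seed=7)
        b = weighted_median(noisy_hs, n_boot=200, seed=7)
        assert a == b


class TestModeBased:
    def test_majority_cluster_wins(self):
        est = mode_based(hs_from_ratios([0.3, 0.3, 0.3, 0.9]), weighted=False,
                         n_boot=50, seed=1)
        assert est.b == pytest.approx(0.3, abs=0.05)

    def test_all_identical_ratios_exact(self):
        est = mode_based(hs_from_ratios([0.42, 0.42, 0.42]), weighted=True,
                         n_boot=50, seed=1)
        assert est.b == pytest.approx(0.42, abs=1e-12)

    def test_cluster_recovery_with_scatter(self, rng):
        ratios = np.concatenate([rng.normal(0.3, 0.01, 6), [0.9, -0.4, 1.5, 0.05]])
        est = mode_based(hs_from_ratios(list(ratios)), weighted=False, n_boot=50, seed=1)
        assert abs(est.b - 0.3) < 0.1

    def test_bandwidth_factor_must_be_positive(self, noisy_hs):
        with pytest.raises(ValueError):
            mode_based(noisy_hs, bandwidth_factor=0.0)


class TestEstimateAll:
    def test_method_sets_by_instrument_count(self, noisy_hs):
        cfg = EstimatorConfig(n_boot=50)
        one = make_hs([0.1], [0.01], [0.05], [0.02])
        assert [e.method for e in estimate_all(one, cfg)] == ["wald_ratio"]
        two = hs_from_ratios([0.2, 0.4])
        assert [e.method for e in estimate_all(two, cfg)] == ["ivw"]
        assert [e.method for e in estimate_all(noisy_hs, cfg)] == [
            "ivw", "egger", "weighted_median", "simple_median",
            "weighted_mode", "simple_mode"]

    def test_all_estimates_carry_same_n_snp(self, noisy_hs):
        ests = estimate_all(noisy_hs, EstimatorConfig(n_boot=50))
        assert {e.n_snp for e in ests} == {len(noisy_hs)}


class TestEstimatorProperties:
    def test_order_invariance(self, noisy_hs, rng):
        cfg = EstimatorConfig(n_boot=100, seed=3)
        base = estimate_all(noisy_hs, cfg)
        shuffled = dataclasses.replace(noisy_hs)
        shuffled.instruments = list(noisy_hs.instruments)
        rng.shuffle(shuffled.instruments)
        again = estimate_all(shuffled, cfg)
        for a, b in zip(base, again):
            assert a.b == pytest.approx(b.b, rel=1e-9), a.method

    def test_sign_equivariance(self, noisy_hs):
        negated = make_hs(
            [i.gamma for i in noisy_hs.instruments],
            [i.se_gamma for i in noisy_hs.instruments],
            [-i.Gamma for i in noisy_hs.instruments],
            [i.se_Gamma for i in noisy_hs.instruments],
        )
        for fn in (lambda h: ivw(h), lambda h: egger(h),
                   lambda h: weighted_median(h, 50, 1), lambda h: simple_median(h, 50, 1)):
            assert fn(negated).b == pytest.approx(-fn(noisy_hs).b, rel=1e-9)

    def test_scale_equivariance(self, noisy_hs):
        c = 2.5
        scaled = make_hs(
            [c * i.gamma for i in noisy_hs.instruments],
            [c * i.se_gamma for i in noisy_hs.instruments],
            [i.Gamma for i in noisy_hs.instruments],
            [i.se_Gamma for i in noisy_hs.instruments],
        )
        assert ivw(scaled).b == pytest.approx(ivw(noisy_hs).b / c, rel=1e-9)
        assert egger(scaled).b == pytest.approx(egger(noisy_hs).b / c, rel=1e-9)
        assert weighted_median(scaled, 50, 1).b == pytest.approx(
            weighted_median(noisy_hs, 50, 1).b / c, rel=1e-9)

    def test_ci_is_symmetric_on_log_scale(self, noisy_hs):
        for est in estimate_all(noisy_hs, EstimatorConfig(n_boot=50)):
            assert est.ci_low * est.ci_high == pytest.approx(math.exp(2 * est.b), rel=1e-9)
            assert est.odds_ratio == pytest.approx(math.exp(est.b), rel=1e-12)
            assert est.ci_low < est.odds_ratio < est.ci_high
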