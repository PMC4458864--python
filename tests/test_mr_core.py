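"""Wald ratios, inverse-variance pooling, DL random effects, heterogeneity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrpool.exceptions import InputError, WeakInstrumentError
from mrpool.mr_core import (
    WaldRatio,
    dl_tau2,
    fixed_effects_pool,
    heterogeneity_stats,
    random_effects_pool,
    wald_ratio,
)
from mrpool.summary_data import InstrumentRecord, reconstruct_se


def _instr(snp="rs1", gamma=0.1, se_gamma=0.01, beta=0.05, se_beta=0.02):
    return InstrumentRecord(snp_id=snp, gamma=gamma, se_gamma=se_gamma,
                            beta=beta, se_beta=se_beta)


def _ratio(snp, alpha, v):
    return WaldRatio(snp_id=snp, alpha_i=alpha, v_i=v, w_i=1.0 / v)


class TestWaldRatio:
    def test_zero_numerator(self):
        r = wald_ratio(_instr(beta=0.0, gamma=0.1, se_beta=0.02))
        assert r.alpha_i == 0.0
        assert r.v_i == pytest.approx(0.04)

    def test_zero_gamma_is_weak_instrument(self):
        with pytest.raises(WeakInstrumentError, match="rs1"):
            wald_ratio(_instr(gamma=0.0))

    def test_bcar1_row_against_direct_arithmetic(self):
        # independent re-evaluation from the printed T2D/CHD summary values
        gamma, beta, p_chd = math.log(1.12), math.log(1.07), 2.7e-5
        se_beta = reconstruct_se(beta, p_chd)
        r = wald_ratio(_instr("rs7202877", gamma=gamma, beta=beta, se_beta=se_beta))
        assert r.alpha_i == pytest.approx(beta / gamma, rel=1e-12)
        assert r.v_i == pytest.approx(se_beta**2 / gamma**2, rel=1e-12)
        assert r.alpha_i * r.v_i**-0.5 == pytest.approx(beta / se_beta, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scaling_homogeneity(self, c):
        base = wald_ratio(_instr())
        scaled = wald_ratio(_instr(beta=0.05 * c, se_beta=0.02 * c))
        assert scaled.alpha_i == pytest.approx(c * base.alpha_i, rel=1e-12)
        assert scaled.v_i == pytest.approx(c**2 * base.v_i, rel=1e-12)

    def test_weight_is_reciprocal_variance(self):
        r = wald_ratio(_instr())
        assert r.w_i * r.v_i == pytest.approx(1.0, rel=1e-14)


class TestFixedEffectsPool:
    def test_single_ratio_identity(self):
        est = fixed_effects_pool([_ratio("a", 0.2, 0.01)])
        assert est.alpha == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_two_equal_variance_ratios_average(self):
        est = fixed_effects_pool([_ratio("a", 0.1, 0.04), _ratio("b", 0.3, 0.04)])
        assert est.alpha == pytest.approx(0.2)
        assert est.se == pytest.approx(math.sqrt(0.02))

    def test_matches_wls_through_origin(self):
        # the pooled estimate equals zero-intercept weighted regression of
        # beta_i on gamma_i with weights s(beta_i)^-2
        import statsmodels.api as sm

        gamma = np.array([0.8, 1.1, 0.9])
        alphas = np.array([0.1, 0.2, 0.3])
        v = np.array([0.01, 0.04, 0.09])
        beta = alphas * gamma
        se_beta = np.sqrt(v) * np.abs(gamma)
        wls = sm.WLS(beta, gamma, weights=se_beta**-2).fit()
        est = fixed_effects_pool([_ratio(f"s{i}", a, vv)
                                  for i, (a, vv) in enumerate(zip(alphas, v))])
        assert est.alpha == pytest.approx(wls.params[0], rel=1e-12)
        assert est.se == pytest.approx(wls.bse[0] / math.sqrt(wls.mse_resid), rel=1e-10)

    def test_empty_raises(self):
        with pytest.raises(InputError):
            fixed_effects_pool([])

    def test_ci_brackets_or(self):
        est = fixed_effects_pool([_ratio("a", 0.1, 0.02), _ratio("b", -0.2, 0.05)])
        assert est.ci_low <= est.or_scale <= est.ci_high
        assert 0.0 < est.p_value <= 1.0


class TestRandomEffectsPool:
    def test_homogeneous_set_equals_fixed_exactly(self):
        # Q <= df forces tau2 = 0 and identical weights
        ratios = [_ratio("a", 0.10, 0.04), _ratio("b", 0.11, 0.04),
                  _ratio("c", 0.10, 0.05)]
        assert dl_tau2(ratios) == 0.0
        fx, rd = fixed_effects_pool(ratios), random_effects_pool(ratios)
        assert rd.alpha == fx.alpha
        assert rd.se == fx.se

    def test_matches_step_by_step_dl_arithmetic(self):
        # spreadsheet-style DL on a deliberately heterogeneous 3-study set
        alphas, v = [0.0, 0.5, 1.0], [0.01, 0.02, 0.04]
        w = [1 / x for x in v]
        a_fx = sum(wi * ai for wi, ai in zip(w, alphas)) / sum(w)
        q = sum(wi * (ai - a_fx) ** 2 for wi, ai in zip(w, alphas))
        c = sum(w) - sum(wi**2 for wi in w) / sum(w)
        tau2 = max(0.0, (q - 2) / c)
        ws = [1 / (x + tau2) for x in v]
        a_dl = sum(wi * ai for wi, ai in zip(ws, alphas)) / sum(ws)
        se_dl = sum(ws) ** -0.5

        est = random_effects_pool([_ratio(f"s{i}", a, x)
                                   for i, (a, x) in enumerate(zip(alphas, v))])
        assert est.alpha == pytest.approx(a_dl, rel=1e-12)
        assert est.se == pytest.approx(se_dl, rel=1e-12)
        assert est.het.tau2 == pytest.approx(tau2, rel=1e-12)

    def test_single_ratio_degrades_to_fixed_with_warning(self):
        with pytest.warns(UserWarning, match="single instrument"):
            est = random_effects_pool([_ratio("a", 0.2, 0.01)])
        assert est.model == "fixed"

    def test_random_se_at_least_fixed_se(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            ratios = [_ratio(f"s{i}", rng.normal(0, 1), float(rng.uniform(0.01, 0.2)))
                      for i in range(n)]
            fx, rd = fixed_effects_pool(ratios), random_effects_pool(ratios)
            assert rd.se >= fx.se - 1e-15
            assert fx.se <= min(math.sqrt(r.v_i) for r in ratios) + 1e-15

    def test_permutation_leaves_result_bit_identical(self):
        rng = np.random.default_rng(1)
        ratios = [_ratio(f"s{i}", rng.normal(0, 1), float(rng.uniform(0.01, 0.2)))
                  for i in range(8)]
        perm = [ratios[i] for i in rng.permutation(8)]
        a, b = random_effects_pool(ratios), random_effects_pool(perm)
        assert a.alpha == b.alpha
        assert a.se == b.se
        assert a.het.q == b.het.q


class TestHeterogeneityStats:
    def test_identical_alphas_give_zero_q_and_i2(self):
        ratios = [_ratio(s, 0.2, v) for s, v in [("a", 0.01), ("b", 0.02), ("c", 0.04)]]
        h = heterogeneity_stats(ratios)
        assert h.q == pytest.approx(0.0, abs=1e-25)
        assert h.i2 == 0.0
        assert h.tau2 == 0.0

    def test_toy_set_against_direct_formula_arithmetic(self):
        alphas, v = [0.1, 0.4, -0.2, 0.3], [0.01, 0.02, 0.05, 0.01]
        w = [1 / x for x in v]
        a_fx = sum(wi * ai for wi, ai in zip(w, alphas)) / sum(w)
        q = sum(wi * (ai - a_fx) ** 2 for wi, ai in zip(w, alphas))
        i2 = max(0.0, (q - 3) / q) * 100
        h = heterogeneity_stats([_ratio(f"s{i}", a, x)
                                 for i, (a, x) in enumerate(zip(alphas, v))])
        assert h.q == pytest.approx(q, rel=1e-12)
        assert h.df == 3
        assert h.i2 == pytest.approx(i2, rel=1e-12)
        # Higgins-Thompson test-based CI recomputed by hand
        ln_h = 0.5 * (math.log(q) - math.log(3))
        se = 0.5 * (math.log(q) - math.log(3)) / (math.sqrt(2 * q) - math.sqrt(5))
        hi = math.exp(2 * (ln_h + 1.959964 * se))
        assert h.i2_ci_high == pytest.approx((hi - 1) / hi * 100, rel=1e-9)

    def test_fewer_than_two_raises(self):
        with pytest.raises(InputError):
            heterogeneity_stats([_ratio("a", 0.1, 0.01)])

    def test_i2_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ratios = [_ratio(f"s{i}", rng.normal(0, 2), float(rng.uniform(0.001, 1)))
                      for i in range(int(rng.integers(2, 10)))]
            h = heterogeneity_stats(ratios)
            assert 0.0 <= h.i2 <= 100.0
            assert 0.0 <= h.i2_ci_low <= 100.0
            assert 0.0 <= h.i2_ci_high <= 100.0
            assert h.i2_ci_low <= h.i2_ci_high
            if h.q <= h.df:
                assert h.tau2 == 0.0
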