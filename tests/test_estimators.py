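import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.errors import AnalysisError
from mrkit.estimators import (
    cochran_q,
    ivw,
    leave_one_out,
    mr_egger,
    or_from_beta,
    p_from_z,
    wald_ratio,
    weighted_median,
)

from conftest import make_variant, make_variants


class TestWaldRatio:
    def test_unit_denominator(self):
        r = wald_ratio(make_variant(bx=1.0, by=0.5, se_by=0.1))
        assert (r.ratio, r.se_ratio) == (0.5, 0.1)

    def test_scaling(self):
        r = wald_ratio(make_variant(bx=2.0, by=1.0, se_by=0.2))
        assert r.ratio == pytest.approx(0.5)
        assert r.se_ratio == pytest.approx(0.1)

    def test_negative_denominator(self):
        r = wald_ratio(make_variant(bx=-0.5, by=0.25, se_by=0.05))
        assert r.ratio == pytest.approx(-0.5)
        assert r.se_ratio == pytest.approx(0.1)

    def test_zero_bx_names_snp(self):
        with pytest.raises(AnalysisError, match="rsX"):
            wald_ratio(make_variant(rsid="rsX", bx=0.0))

    def test_second_order_term(self):
        v = make_variant(bx=1.0, se_bx=0.2, by=0.5, se_by=0.1)
        first = wald_ratio(v).se_ratio
        second = wald_ratio(v, second_order=True).se_ratio
        # sqrt(0.1^2 + 0.25*0.04) = sqrt(0.02)
        assert second == pytest.approx(math.sqrt(0.02))
        assert second > first


class TestIvw:
    def test_single_variant_equals_wald(self):
        v = make_variant(bx=2.0, by=1.0, se_by=0.2)
        res = ivw([v])
        r = wald_ratio(v)
        assert res.theta == pytest.approx(r.ratio)
        assert res.se == pytest.approx(r.se_ratio)
        assert res.n_snp == 1

    def test_two_ratio_hand_computation(self):
        # ratios 0.4, 0.6 each with se 0.1: theta 0.5, fixed SE 0.1/sqrt(2)
        vs = make_variants(bx=[1.0, 1.0], by=[0.4, 0.6], se_by=[0.1, 0.1])
        res = ivw(vs, model="fixed")
        assert res.theta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1 / math.sqrt(2))
        assert res.q_df == 1

    def test_homogeneous_random_equals_fixed(self):
        vs = make_variants(bx=[1.0, 1.0, 1.0], by=[0.5, 0.5, 0.5], se_by=[0.1, 0.1, 0.1])
        fixed = ivw(vs, model="fixed")
        random = ivw(vs, model="random")
        assert random.se == pytest.approx(fixed.se)  # Q = 0, inflation floor 1
        assert random.q == pytest.approx(0.0)

    def test_auto_switches_on_heterogeneity(self):
        vs = make_variants(bx=[1.0, 1.0, 1.0], by=[0.1, 0.9, 0.5], se_by=[0.01, 0.01, 0.01])
        res = ivw(vs, model="auto")
        assert res.q_pvalue < 0.05
        assert res.method == "ivw_random"
        assert res.se > ivw(vs, model="fixed").se

    def test_wls_through_origin_oracle(self, rng):
        """IVW must equal weighted least squares of by on bx through the
        origin, solved independently via lstsq on the weighted design."""
        for _ in range(100):
            j = int(rng.integers(2, 11))
            bx = rng.uniform(0.05, 0.5, j) * rng.choice([-1, 1], j)
            by = rng.normal(0.1 * bx, 0.05)
            se_by = rng.uniform(0.01, 0.1, j)
            vs = make_variants(bx=bx, by=by, se_by=se_by)
            res = ivw(vs, model="fixed")
            w_sqrt = np.abs(bx) / se_by  # sqrt of ratio weights
            ratios = by / bx
            coef, *_ = np.linalg.lstsq(
                (w_sqrt)[:, None], w_sqrt * ratios, rcond=None
            )
            assert res.theta == pytest.approx(float(coef[0]), rel=1e-10)

    def test_order_and_sign_invariance(self, rng):
        bx = rng.uniform(0.1, 0.3, 6)
        by = rng.normal(0.05 * bx, 0.02)
        vs = make_variants(bx=bx, by=by)
        base = ivw(vs, model="fixed")
        perm = [vs[i] for i in rng.permutation(6)]
        flipped = [v.flip_signs() if i % 2 else v for i, v in enumerate(perm)]
        res = ivw(flipped, model="fixed")
        assert res.theta == pytest.approx(base.theta)
        assert res.se == pytest.approx(base.se)

    def test_empty_errors(self):
        with pytest.raises(AnalysisError):
            ivw([])


class TestCochranQ:
    def test_identical_ratios(self):
        vs = make_variants(bx=[1.0, 1.0], by=[0.5, 0.5], se_by=[0.1, 0.1])
        ratios = [wald_ratio(v) for v in vs]
        q, df, p = cochran_q(ratios, 0.5)
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_direct_substitution(self):
        # Q = 100*(0.4-0.5)^2 + 100*(0.6-0.5)^2 = 2, df = 1
        vs = make_variants(bx=[1.0, 1.0], by=[0.4, 0.6], se_by=[0.1, 0.1])
        ratios = [wald_ratio(v) for v in vs]
        q, df, p = cochran_q(ratios, 0.5)
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_permutation_symmetry(self):
        vs = make_variants(bx=[1.0, 2.0, 1.5], by=[0.4, 0.9, 0.8], se_by=[0.1, 0.2, 0.15])
        ratios = [wald_ratio(v) for v in vs]
        q1, *_ = cochran_q(ratios, 0.5)
        q2, *_ = cochran_q(ratios[::-1], 0.5)
        assert q1 == pytest.approx(q2)

    def test_direct_summation_oracle(self, rng):
        for _ in range(100):
            j = int(rng.integers(2, 11))
            vs = make_variants(
                bx=rng.uniform(0.1, 0.5, j),
                by=rng.normal(0.0, 0.1, j),
                se_by=rng.uniform(0.01, 0.1, j),
            )
            ratios = [wald_ratio(v) for v in vs]
            theta = float(rng.normal())
            q, df, _ = cochran_q(ratios, theta)
            oracle = sum(
                (r.ratio - theta) ** 2 / r.se_ratio**2 for r in ratios
            )
            assert q == pytest.approx(oracle, rel=1e-12)
            assert df == j - 1

    def test_fewer_than_two_errors(self):
        vs = make_variants(bx=[1.0], by=[0.5])
        with pytest.raises(AnalysisError):
            cochran_q([wald_ratio(vs[0])], 0.5)


class TestMrEgger:
    def test_exact_linear_data(self, rng):
        bx = np.linspace(0.1, 0.5, 6)
        by = 0.02 + 0.5 * bx
        vs = make_variants(bx=bx, by=by, se_by=rng.uniform(0.01, 0.05, 6))
        res = mr_egger(vs)
        assert res.theta == pytest.approx(0.5, abs=1e-10)
        assert res.intercept == pytest.approx(0.02, abs=1e-10)

    def test_orientation_invariance(self, rng):
        bx = rng.uniform(0.1, 0.5, 8)
        by = rng.normal(0.02 + 0.3 * bx, 0.02)
        vs = make_variants(bx=bx, by=by)
        base = mr_egger(vs)
        flipped = [v.flip_signs() if i in (1, 4, 6) else v for i, v in enumerate(vs)]
        res = mr_egger(flipped)
        assert res.theta == pytest.approx(base.theta)
        assert res.intercept == pytest.approx(base.intercept)
        assert res.se == pytest.approx(base.se)

    def test_requires_three(self):
        vs = make_variants(bx=[0.1, 0.2], by=[0.01, 0.02])
        with pytest.raises(AnalysisError, match="IVW"):
            mr_egger(vs)

    def test_directional_pleiotropy_recovered(self):
        from mrkit.harmonize import harmonize
        from mrkit.simulate import SimulationConfig, simulate_pair

        ex, out, _ = simulate_pair(
            SimulationConfig(
                j_snps=200, theta=0.1, pleiotropy_prob=1.0,
                pleiotropy_mean=0.05, pleiotropy_sd=0.01, seed=99,
            )
        )
        res = mr_egger(harmonize(ex, out).variants)
        assert abs(res.intercept - 0.05) < 3 * res.se_intercept


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        vs = make_variants(bx=[1.0, 1.0, 1.0], by=[0.1, 0.5, 0.9], se_by=[0.1, 0.1, 0.1])
        res = weighted_median(vs, n_boot=10, seed=1)
        assert res.theta == pytest.approx(0.5)

    def test_unequal_weights_brute_force_oracle(self):
        # weights proportional to (1, 1, 8) on ratios (0.1, 0.5, 0.9):
        # normalized weights (0.1, 0.1, 0.8); s = cumsum - w/2 = (0.05, 0.15, 0.6);
        # interpolate 0.5 between s2=0.15 (r=0.5) and s3=0.6 (r=0.9):
        # 0.5 + (0.5-0.15)/(0.6-0.15)*0.4 = 0.811111...
        se = [0.1, 0.1, 0.1 / math.sqrt(8)]
        vs = make_variants(bx=[1.0, 1.0, 1.0], by=[0.1, 0.5, 0.9], se_by=se)
        res = weighted_median(vs, n_boot=10, seed=1)
        assert 0.5 < res.theta < 0.9
        assert res.theta == pytest.approx(0.5 + 0.35 / 0.45 * 0.4)

    def test_equal_weights_reproduce_plain_median(self, rng):
        for _ in range(10):
            j = int(rng.integers(3, 10))
            by = rng.normal(0.0, 0.2, j)
            vs = make_variants(bx=np.ones(j), by=by, se_by=np.full(j, 0.1))
            res = weighted_median(vs, n_boot=2, seed=1)
            assert res.theta == pytest.approx(float(np.median(by)))

    def test_seed_determinism(self):
        vs = make_variants(bx=[0.1, 0.2, 0.3], by=[0.01, 0.03, 0.02])
        a = weighted_median(vs, n_boot=200, seed=7)
        b = weighted_median(vs, n_boot=200, seed=7)
        assert a.se == b.se
        c = weighted_median(vs, n_boot=200, seed=8)
        assert c.se != a.se

    def test_requires_three_and_seed(self):
        vs = make_variants(bx=[0.1, 0.2], by=[0.01, 0.02])
        with pytest.raises(AnalysisError):
            weighted_median(vs, seed=1)
        vs3 = make_variants(bx=[0.1, 0.2, 0.3], by=[0.01, 0.02, 0.03])
        with pytest.raises(AnalysisError, match="seed"):
            weighted_median(vs3, seed=None)


class TestLeaveOneOut:
    def test_two_variants(self):
        vs = make_variants(bx=[1.0, 2.0], by=[0.4, 1.6], se_by=[0.1, 0.2])
        loo = leave_one_out(vs)
        assert loo["rs0"].theta == pytest.approx(wald_ratio(vs[1]).ratio)
        assert loo["rs1"].theta == pytest.approx(wald_ratio(vs[0]).ratio)

    def test_homogeneous_equals_full(self):
        vs = make_variants(bx=[1.0, 1.0, 1.0], by=[0.5, 0.5, 0.5])
        full = ivw(vs)
        for res in leave_one_out(vs).values():
            assert res.theta == pytest.approx(full.theta)

    def test_outlier_exclusion_moves_toward_truth(self):
        from mrkit.harmonize import harmonize
        from mrkit.simulate import SimulationConfig, simulate_pair, displace_outcome

        ex, out, _ = simulate_pair(SimulationConfig(j_snps=10, theta=0.05, seed=5))
        vs = displace_outcome(harmonize(ex, out).variants, 3, 15.0)
        full = ivw(vs, model="fixed")
        loo = leave_one_out(vs, model="fixed")
        assert abs(loo[vs[3].rsid].theta - 0.05) < abs(full.theta - 0.05)

    def test_requires_two(self):
        with pytest.raises(AnalysisError):
            leave_one_out(make_variants(bx=[1.0], by=[0.5]))


class TestEffectConversions:
    def test_reported_urinary_hypertension_or(self):
        res = or_from_beta(0.035563214, 0.0033559)
        assert round(res.or_point, 3) == 1.036
        assert round(res.ci_low, 3) == 1.029
        assert round(res.ci_high, 3) == 1.043

    def test_reported_serum_hypertension_or(self):
        res = or_from_beta(0.013084182, 0.001551856)
        assert round(res.or_point, 3) == 1.013

    def test_null_theta_symmetric(self):
        res = or_from_beta(0.0, 0.1)
        assert res.or_point == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    def test_p_null(self):
        assert p_from_z(0.0, 1.0) == pytest.approx(1.0)

    def test_p_at_critical_z(self):
        assert p_from_z(1.959964, 1.0) == pytest.approx(0.05, rel=1e-5)

    def test_p_reported_sbp_row(self):
        assert p_from_z(1.09960196, 0.247554764) == pytest.approx(8.92e-06, rel=5e-3)

    def test_far_tail_stability(self):
        p = p_from_z(20.0, 1.0)
        assert 0.0 < p < 1e-80

    @given(theta=st.floats(-5, 5), se=st.floats(0.01, 10))
    @settings(max_examples=50)
    def test_or_ci_ordering(self, theta, se):
        res = or_from_beta(theta, se)
        assert res.ci_low <= res.or_point <= res.ci_high
        assert res.ci_low > 0
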