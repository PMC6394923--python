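"""Freeman-Tukey pooling and exponential-hazard median pooling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdacpath.pooling import (
    ft_inverse,
    ft_transform,
    pool_random_effects,
    pooled_median,
)


class TestFreemanTukeyTransform:
    def test_zero_events_single_patient(self):
        # t = (asin(sqrt(0/2)) + asin(sqrt(1/2))) / 2 = pi/8
        assert ft_transform(0, 1).t == pytest.approx(0.5 * math.asin(math.sqrt(0.5)))
        assert ft_transform(0, 1).t == pytest.approx(0.39269908, abs=1e-6)

    def test_worked_mid_sample(self):
        expected = 0.5 * (math.asin(math.sqrt(5 / 11)) + math.asin(math.sqrt(6 / 11)))
        assert ft_transform(5, 10).t == pytest.approx(expected, abs=1e-12)

    def test_variance_is_size_only(self):
        assert ft_transform(3, 10).var_t == pytest.approx(1.0 / 42.0)

    @given(st.integers(min_value=1, max_value=500))
    def test_symmetry_about_quarter_pi(self, n):
        assert ft_transform(0, n).t + ft_transform(n, n).t == pytest.approx(math.pi / 2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ft_transform(5, 4)
        with pytest.raises(ValueError):
            ft_transform(0, 0)


class TestBackTransform:
    def test_symmetry_point_maps_to_half(self):
        for n in (10, 50, 400):
            assert ft_inverse(math.pi / 4, 1.0 / n) == pytest.approx(0.5, abs=0.02)

    def test_boundaries_clamp(self):
        assert ft_inverse(-0.01, 0.01) == 0.0
        assert ft_inverse(math.pi / 2 + 0.01, 0.01) == 1.0

    @given(
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=200, max_value=2000),
    )
    def test_round_trip_recovers_proportion(self, r, n):
        r = min(r, n)
        t = ft_transform(r, n)
        assert ft_inverse(t.t, 1.0 / n) == pytest.approx(r / n, abs=1.0 / n)


class TestRandomEffectsPooling:
    def test_identical_studies_recover_common_proportion(self):
        studies = [ft_transform(30, 100) for _ in range(8)]
        est = pool_random_effects(studies)
        assert est.point == pytest.approx(0.30, abs=0.01)

    def test_two_study_hand_computed_oracle(self):
        # independent step-by-step DerSimonian-Laird computation
        data = [(30, 100), (60, 100)]
        t = [0.5 * (math.asin(math.sqrt(r / (n + 1))) + math.asin(math.sqrt((r + 1) / (n + 1))))
             for r, n in data]
        v = [1.0 / (4 * n + 2) for _, n in data]
        w = [1 / vi for vi in v]
        t_fixed = sum(wi * ti for wi, ti in zip(w, t)) / sum(w)
        q = sum(wi * (ti - t_fixed) ** 2 for wi, ti in zip(w, t))
        tau2 = max(0.0, (q - 1) / (sum(w) - sum(wi**2 for wi in w) / sum(w)))
        w_star = [1 / (vi + tau2) for vi in v]
        t_pooled = sum(wi * ti for wi, ti in zip(w_star, t)) / sum(w_star)
        expected = ft_inverse(t_pooled, np.mean([1 / 100, 1 / 100]))

        est = pool_random_effects([ft_transform(r, n) for r, n in data])
        assert est.point == pytest.approx(expected, abs=1e-12)
        assert est.ci_low < est.point < est.ci_high

    def test_matches_statsmodels_combine_effects(self):
        # independent route: statsmodels DL pooling on the transformed scale
        from statsmodels.stats.meta_analysis import combine_effects

        # heterogeneous pool so the DL tau^2 is positive (statsmodels does not
        # floor a negative moment estimate at zero, this implementation does)
        data = [(10, 100), (50, 100), (12, 60), (90, 120)]
        studies = [ft_transform(r, n) for r, n in data]
        res = combine_effects(
            np.array([s.t for s in studies]),
            np.array([s.var_t for s in studies]),
            method_re="chi2",
        )
        assert res.tau2 > 0
        t_re = float(res.summary_frame().loc["random effect", "eff"])
        mine = pool_random_effects(studies)
        n_inv_mean = float(np.mean([1.0 / n for _, n in data]))
        assert mine.point == pytest.approx(ft_inverse(t_re, n_inv_mean), abs=1e-10)

    def test_pooled_point_within_observed_range(self):
        data = [(5, 50), (30, 60), (10, 20), (1, 30)]
        est = pool_random_effects([ft_transform(r, n) for r, n in data])
        props = [r / n for r, n in data]
        assert min(props) - 0.02 <= est.point <= max(props) + 0.02

    def test_order_invariance(self):
        data = [(5, 50), (30, 60), (10, 20)]
        a = pool_random_effects([ft_transform(r, n) for r, n in data])
        b = pool_random_effects([ft_transform(r, n) for r, n in reversed(data)])
        assert a.point == pytest.approx(b.point, abs=1e-12)

    def test_split_half_invariance(self):
        # replacing a study by two identical halves barely moves the estimate
        whole = [(30, 100), (20, 80)]
        split = [(30, 100), (10, 40), (10, 40)]
        a = pool_random_effects([ft_transform(r, n) for r, n in whole])
        b = pool_random_effects([ft_transform(r, n) for r, n in split])
        assert a.point == pytest.approx(b.point, abs=0.01)

    def test_single_study_returns_own_estimate(self, caplog):
        est = pool_random_effects([ft_transform(30, 100)])
        assert est.point == pytest.approx(0.30, abs=0.01)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([])


class TestPooledMedian:
    def test_single_study_identity(self):
        assert pooled_median([(17.4, 33)]).m_p == pytest.approx(17.4)

    def test_two_study_harmonic_oracle(self):
        # w = (2/3, 1/3); m_p = 1 / (2/3/12 + 1/3/24) = 14.4
        pm = pooled_median([(12.0, 100), (24.0, 50)])
        assert pm.m_p == pytest.approx(14.4, abs=1e-12)
        assert pm.weights.tolist() == pytest.approx([2 / 3, 1 / 3])

    def test_equal_medians_pool_to_that_median(self):
        assert pooled_median([(18.0, 10), (18.0, 200)]).m_p == pytest.approx(18.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=2.0, max_value=50.0),
                st.integers(min_value=5, max_value=500),
            ),
            min_size=2,
            max_size=10,
        )
    )
    def test_harmonic_below_arithmetic_and_within_range(self, pairs):
        pm = pooled_median(pairs)
        m = np.array([p[0] for p in pairs])
        w = np.array([p[1] for p in pairs], dtype=float)
        w /= w.sum()
        assert pm.m_p <= float(np.sum(w * m)) + 1e-9
        assert m.min() - 1e-9 <= pm.m_p <= m.max() + 1e-9

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            pooled_median([(0.0, 10)])
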