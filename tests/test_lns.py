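"""Lognormal Shrinkage: scaling, mixture fitting, assignment, shrinkage."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braque.io_core import RunConfig
from braque.lns import (
    MarkerMixtureFit,
    assign_to_component,
    convert_contraction_factor,
    fit_bayesian_mixture,
    lns_transform_marker,
    lns_transform_table,
    log_shift,
    lognormal_moments,
    responsibilities,
    robust_scale,
    saturation_report,
    shrink_values,
)


def _toy_fit(means, variances, weights=None, assignments=None):
    means = np.asarray(means, dtype=float)
    k = len(means)
    return MarkerMixtureFit(
        means=means,
        variances=np.asarray(
            variances if variances is not None else np.ones(k), dtype=float
        ),
        weights=np.asarray(weights if weights is not None else np.full(k, 1 / k)),
        n_components_requested=k,
        assignments=np.asarray(assignments if assignments is not None else [0]),
        used_component_count=k,
        mad_pre=1.0,
        shift=1e-3,
        converged=True,
    )


class TestRobustScale:
    def test_hand_computed_mad(self):
        out, mad = robust_scale(np.array([0.0, 2.0, 4.0, 6.0, 8.0]))
        assert mad == 2.0
        np.testing.assert_allclose(out, [0, 1, 2, 3, 4])

    def test_constant_marker_degenerate_passthrough(self):
        values = np.array([5.0, 5.0, 5.0, 5.0])
        out, mad = robust_scale(values)
        assert mad == 0.0
        np.testing.assert_array_equal(out, values)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.01, 100),
        seed=st.integers(0, 1000),
    )
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        values = rng.gamma(2.0, 3.0, size=30)
        base, _ = robust_scale(values)
        scaled, _ = robust_scale(values * scale)
        np.testing.assert_allclose(scaled, base, rtol=1e-9)


class TestLogShift:
    def test_zero_maps_to_log_of_epsilon(self):
        out = log_shift(np.array([0.0]), 1e-3, 2)
        assert out[0] == pytest.approx(math.log2(1e-3))
        assert out[0] == pytest.approx(-9.9658, abs=1e-4)

    def test_one_minus_epsilon_near_zero(self):
        assert log_shift(np.array([1 - 1e-3]), 1e-3, 2)[0] == pytest.approx(0.0)

    def test_base_change_is_constant_rescale(self):
        values = np.array([0.0, 0.5, 3.0, 10.0])
        np.testing.assert_allclose(
            log_shift(values, 1e-3, 2) / math.log2(10),
            log_shift(values, 1e-3, 10),
            rtol=1e-12,
        )


class TestMixtureFit:
    def test_single_normal_uses_few_components(self):
        rng = np.random.default_rng(0)
        fit = fit_bayesian_mixture(rng.normal(0, 1, 1000), k_max=15, seed=0)
        assert fit.used_component_count <= 3

    def test_two_separated_modes_recovered(self):
        rng = np.random.default_rng(1)
        data = np.concatenate(
            [rng.normal(0, 0.1, 500), rng.normal(10, 0.1, 500)]
        )
        fit = fit_bayesian_mixture(data, k_max=15, seed=1)
        assert fit.used_component_count == 2

    def test_responsibilities_sum_to_one(self):
        fit = _toy_fit([0.0, 3.0, 7.0], [1.0, 0.5, 2.0], [0.2, 0.5, 0.3])
        x = np.linspace(-5, 12, 200)
        resp = responsibilities(x, fit.means, fit.variances, fit.weights)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)


class TestAssignment:
    def test_nearby_component_wins(self):
        fit = _toy_fit([0.0, 10.0], [1.0, 1.0])
        assert assign_to_component(0.3, fit) == 0
        assert assign_to_component(9.1, fit) == 1

    def test_exact_tie_takes_lowest_index(self):
        fit = _toy_fit([0.0, 10.0], [1.0, 1.0])
        assert assign_to_component(5.0, fit) == 0

    def test_single_component(self):
        fit = _toy_fit([2.0], [1.0])
        assert assign_to_component(-100.0, fit) == 0


class TestShrink:
    def test_arithmetic(self):
        fit = _toy_fit([2.0], [1.0])
        out = shrink_values(np.array([7.0]), np.array([0]), fit, 5.0)
        assert out[0] == pytest.approx(3.0)

    def test_gamma_one_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 3, 100)
        fit = _toy_fit([0.0, 5.0], [1.0, 1.0])
        a = rng.integers(0, 2, 100)
        np.testing.assert_allclose(shrink_values(x, a, fit, 1.0), x, atol=1e-12)

    def test_gamma_infinity_collapses_to_means(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 3, 100)
        fit = _toy_fit([0.0, 5.0], [1.0, 1.0])
        a = rng.integers(0, 2, 100)
        out = shrink_values(x, a, fit, 1e9)
        np.testing.assert_allclose(out, fit.means[a], atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), gamma=st.floats(1.0, 50.0))
    def test_within_component_order_preserved(self, seed, gamma):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 2, 60)
        a = rng.integers(0, 3, 60)
        fit = _toy_fit([-2.0, 0.0, 2.0], [1.0, 1.0, 1.0])
        out = shrink_values(x, a, fit, gamma)
        for comp in range(3):
            mask = a == comp
            assert np.array_equal(
                np.argsort(x[mask], kind="stable"),
                np.argsort(out[mask], kind="stable"),
            )

    def test_gamma_below_one_rejected(self):
        fit = _toy_fit([0.0], [1.0])
        with pytest.raises(ValueError):
            shrink_values(np.array([1.0]), np.array([0]), fit, 0.5)


class TestContractionFactorConversion:
    def test_base10_rule(self):
        gamma = convert_contraction_factor(5, 10)
        assert gamma == pytest.approx(5 / math.log(10))
        assert round(gamma) == 2

    def test_natural_base(self):
        assert convert_contraction_factor(5, math.e) == pytest.approx(5.0)

    def test_linear_in_gamma(self):
        assert convert_contraction_factor(10, 10) == pytest.approx(
            2 * convert_contraction_factor(5, 10)
        )


class TestTransformMarker:
    def test_gamma_one_no_rescale_recovers_scaled_input(self):
        rng = np.random.default_rng(4)
        values = rng.gamma(2.0, 5.0, 400)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = RunConfig(contraction_factor=1.0, rescale_after_lns=False)
        res = lns_transform_marker(values, cfg, seed=0)
        scaled, _ = robust_scale(values)
        expected = (scaled + cfg.shift_epsilon) - (scaled.min() + cfg.shift_epsilon)
        np.testing.assert_allclose(res.values_out, expected, atol=1e-9)

    def test_three_mode_marker_shrinks_each_mode(self):
        rng = np.random.default_rng(5)
        modes = [0.0, 4.0, 8.0]
        logv = np.concatenate([rng.normal(m, 0.3, 400) for m in modes])
        values = rng.permutation(np.power(2.0, logv))
        cfg = RunConfig()
        res = lns_transform_marker(values, cfg, seed=0)
        fit = res.fit
        assert fit.used_component_count == 3
        # per-mode spread in log space shrinks by ~gamma; the final MAD
        # rescale is a constant factor, invisible to log-space SDs.  The
        # cell at the output minimum (exactly 0) is excluded from the log.
        scaled, _ = robust_scale(values)
        in_log = np.log2(scaled + cfg.shift_epsilon)
        pos = res.values_out > 0
        ratios = []
        for comp in np.unique(fit.assignments):
            mask = (fit.assignments == comp) & pos
            out_sd = np.log2(res.values_out[mask]).std()
            if out_sd > 0:
                ratios.append(in_log[mask].std() / out_sd)
        assert np.median(ratios) == pytest.approx(5.0, rel=0.35)

    def test_output_minimum_is_zero(self):
        rng = np.random.default_rng(6)
        res = lns_transform_marker(rng.gamma(2.0, 5.0, 300), RunConfig(), seed=1)
        assert res.values_out.min() == 0.0

    def test_all_zero_marker_passthrough(self):
        res = lns_transform_marker(np.zeros(50), RunConfig(), seed=0)
        assert res.degenerate
        assert res.fit is None
        np.testing.assert_array_equal(res.values_out, np.zeros(50))


@pytest.fixture(scope="module")
def small_table():
    rng = np.random.default_rng(7)
    return np.column_stack(
        [
            rng.gamma(2.0, 5.0, 300),
            np.full(300, 3.0),  # constant marker
            np.power(2.0, rng.normal(2, 0.5, 300)),
        ]
    )


class TestTransformTable:
    def test_constant_marker_does_not_abort(self, small_table):
        out, fits = lns_transform_table(small_table, RunConfig(), seed=1)
        assert fits[1] is None
        np.testing.assert_array_equal(out[:, 1], small_table[:, 1])
        assert fits[0] is not None and fits[2] is not None

    def test_deterministic_given_seed(self, small_table):
        out1, _ = lns_transform_table(small_table, RunConfig(), seed=9)
        out2, _ = lns_transform_table(small_table, RunConfig(), seed=9)
        np.testing.assert_array_equal(out1, out2)

    def test_one_fit_record_per_marker(self, small_table):
        _, fits = lns_transform_table(small_table, RunConfig(), seed=1)
        assert len(fits) == small_table.shape[1]


class TestSaturationReport:
    def _fits(self, counts, k_max=15):
        out = []
        for c in counts:
            if c is None:
                out.append(None)
            else:
                f = _toy_fit([0.0], [1.0])
                f.used_component_count = c
                f.n_components_requested = k_max
                out.append(f)
        return out

    def test_all_markers_discard(self):
        rep = saturation_report(self._fits([3, 5, 14]), 15)
        assert rep.fraction_with_discard == 1.0
        assert not rep.saturated
        assert rep.histogram == {3: 1, 5: 1, 14: 1}

    def test_saturated_flag(self):
        rep = saturation_report(self._fits([15, 15, 4]), 15)
        assert rep.fraction_with_discard == pytest.approx(1 / 3)
        assert rep.saturated

    def test_degenerate_markers_excluded(self):
        rep = saturation_report(self._fits([3, None, 15]), 15)
        assert rep.n_markers == 2
        assert rep.fraction_with_discard == pytest.approx(0.5)


class TestLognormalMoments:
    def test_point_mass(self):
        assert lognormal_moments(0.0, 0.0) == (1.0, 0.0)

    def test_unit_normal_closed_form(self):
        mean, var = lognormal_moments(0.0, 1.0)
        assert mean == pytest.approx(math.exp(0.5))
        assert var == pytest.approx((math.e - 1) * math.e)

    @pytest.mark.parametrize("mu,var,base", [(0.5, 0.8, math.e), (1.0, 0.25, 2.0)])
    def test_monte_carlo_oracle(self, mu, var, base):
        rng = np.random.default_rng(11)
        n = 200_000
        samples = np.power(base, rng.normal(mu, math.sqrt(var), n))
        mean, variance = lognormal_moments(mu, var, base=base)
        se_mean = samples.std() / math.sqrt(n)
        assert samples.mean() == pytest.approx(mean, abs=3 * se_mean)
        assert samples.var() == pytest.approx(variance, rel=0.05)
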