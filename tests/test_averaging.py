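import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import NOISE_FREE, constant_torque_stride
from stridecost.averaging import average_gait_pattern, estimate_methods, time_normalize
from stridecost.effort import TorqueSquaredCost
from stridecost.io import SignalChannel
from stridecost.preprocess import StrideSeries
from stridecost.synthetic import SyntheticGaitConfig, generate_stride_series


def ramp_stride(duration=1.0, rate=100.0, n=None):
    n = int(round(duration * rate)) + 1 if n is None else n
    ch = SignalChannel("hip_moment", np.linspace(0.0, 1.0, n))
    return StrideSeries(
        channels={"hip_moment": ch}, t_start=0.0, duration=(n - 1) / rate, sampling_rate=rate
    )


class TestTimeNormalize:
    def test_identity_when_sample_count_matches_grid(self):
        stride = ramp_stride(n=101)
        ns = time_normalize(stride, n_grid=101)
        np.testing.assert_allclose(
            ns.channels["hip_moment"].samples, stride.channel("hip_moment").samples
        )

    def test_linear_ramp_resampled_exactly(self):
        # linear interpolation is exact on affine signals
        stride = ramp_stride(n=137)
        ns = time_normalize(stride, n_grid=101)
        np.testing.assert_allclose(ns.channels["hip_moment"].samples, ns.grid, atol=1e-12)

    def test_original_duration_retained(self):
        stride = ramp_stride(duration=1.1)
        assert time_normalize(stride).original_duration == pytest.approx(1.1)

    def test_endpoints_equal_stride_endpoints(self):
        stride = generate_stride_series(
            SyntheticGaitConfig(seed=3), np.random.default_rng(3)
        )
        ns = time_normalize(stride)
        for name, ch in stride.channels.items():
            assert ns.channels[name].samples[0] == ch.samples[0]
            assert ns.channels[name].samples[-1] == ch.samples[-1]

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="n_grid"):
            time_normalize(ramp_stride(), n_grid=1)


class TestAverageGaitPattern:
    def test_mean_of_identical_strides_is_the_stride(self):
        ns = [time_normalize(ramp_stride()) for _ in range(5)]
        avg = average_gait_pattern(ns)
        np.testing.assert_allclose(
            avg.channels["hip_moment"].samples, ns[0].channels["hip_moment"].samples
        )
        assert avg.n_members == 5

    def test_constant_strides_average_values_and_durations(self):
        a = time_normalize(constant_torque_stride(1.0, duration=1.0))
        b = time_normalize(constant_torque_stride(3.0, duration=1.2))
        avg = average_gait_pattern([a, b])
        np.testing.assert_allclose(avg.channels["hip_moment"].samples, 2.0)
        assert avg.duration == pytest.approx(1.1)

    def test_averaging_is_idempotent(self):
        rng = np.random.default_rng(0)
        cfg = SyntheticGaitConfig(seed=0, sigma_period=0.0)
        ns = [time_normalize(generate_stride_series(cfg, rng)) for _ in range(5)]
        avg = average_gait_pattern(ns)
        again = average_gait_pattern([avg.as_normalized()] * 3)
        for name in avg.channels:
            np.testing.assert_allclose(
                again.channels[name].samples, avg.channels[name].samples, rtol=1e-12
            )

    def test_mismatched_channels_rejected(self):
        a = time_normalize(ramp_stride())
        b = time_normalize(constant_torque_stride(1.0))
        b.channels["extra_moment"] = b.channels["hip_moment"]
        with pytest.raises(ValueError, match="channel names"):
            average_gait_pattern([a, b])


class TestEstimateMethods:
    def test_zero_variability_collapses_all_methods(self):
        strides = [constant_torque_stride(2.0) for _ in range(5)]
        cmp = estimate_methods(strides, TorqueSquaredCost(), rng_seed=0)
        assert cmp.method1_cost == pytest.approx(cmp.method3_cost, rel=1e-12)
        assert cmp.method2_cost == pytest.approx(cmp.method3_cost, rel=1e-12)
        assert cmp.percent_error_m2 == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_mean_squared_versus_squared_mean(self):
        strides = [constant_torque_stride(1.0), constant_torque_stride(2.0)]
        cmp = estimate_methods(strides, TorqueSquaredCost(), rng_seed=0)
        assert cmp.method2_cost == pytest.approx(2.25, abs=1e-12)
        assert cmp.method3_cost == pytest.approx(2.5, abs=1e-12)
        assert cmp.percent_error_m2 == pytest.approx(-10.0, abs=1e-9)

    def test_method3_invariant_to_stride_order(self):
        rng = np.random.default_rng(1)
        cfg = SyntheticGaitConfig(seed=1, sigma_period=0.0)
        strides = [generate_stride_series(cfg, rng) for _ in range(5)]
        a = estimate_methods(strides, TorqueSquaredCost(), rng_seed=0)
        b = estimate_methods(strides[::-1], TorqueSquaredCost(), rng_seed=0)
        assert a.method3_cost == pytest.approx(b.method3_cost, rel=1e-12)
        assert a.method2_cost == pytest.approx(b.method2_cost, rel=1e-12)

    def test_duration_weighted_variant(self):
        strides = [
            constant_torque_stride(1.0, duration=1.0),
            constant_torque_stride(2.0, duration=3.0),
        ]
        cmp = estimate_methods(strides, TorqueSquaredCost(), rng_seed=0, duration_weighted=True)
        assert cmp.method3_cost == pytest.approx((1.0 * 1 + 4.0 * 3) / 4.0, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_jensen_direction_for_equal_duration_strides(self, seed):
        """Convex cost + equal durations: the averaged pattern can never cost
        more than the mean of per-stride costs."""
        rng = np.random.default_rng(seed)
        cfg = SyntheticGaitConfig(seed=seed, sigma_period=0.0)
        strides = [generate_stride_series(cfg, rng) for _ in range(5)]
        cmp = estimate_methods(strides, TorqueSquaredCost(), rng_seed=seed)
        assert cmp.method2_cost <= cmp.method3_cost + 1e-9 * abs(cmp.method3_cost)
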