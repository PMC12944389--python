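import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semgdenoise.signal_model import Signal
from semgdenoise.thresholding import (
    ThresholdConfig,
    detect_rest,
    estimate_sigma,
    improved_threshold,
    interval_threshold,
    universal_threshold,
    zero_cross_partition,
)


def brute_force_partition(mode):
    """Enumeration oracle: walk the series carrying the last non-zero
    sign; start a new interval whenever the carried sign flips."""
    n = len(mode)
    signs = []
    last = 0.0
    for v in mode:
        s = math.copysign(1.0, v) if v != 0 else last
        signs.append(s)
        last = s if s != 0 else last
    # leading zeros adopt the first non-zero sign
    first_nz = next((i for i, s in enumerate(signs) if s != 0), None)
    if first_nz is None:
        signs = [1.0] * n
    else:
        for i in range(first_nz):
            signs[i] = signs[first_nz]
    intervals, start = [], 0
    for i in range(1, n):
        if signs[i] != signs[i - 1]:
            intervals.append((start, i))
            start = i
    intervals.append((start, n))
    return intervals


class TestZeroCrossPartition:
    def test_worked_example(self):
        p = zero_cross_partition(np.array([1.0, 1.0, -1.0, -1.0, 1.0]))
        assert p.intervals == [(0, 2), (2, 4), (4, 5)]
        assert p.extremum_value.tolist() == [1.0, -1.0, 1.0]

    def test_all_positive_single_interval(self):
        p = zero_cross_partition(np.ones(7))
        assert p.intervals == [(0, 7)]

    def test_alternating_one_sample_intervals(self):
        p = zero_cross_partition(np.array([1.0, -1.0] * 3))
        assert p.intervals == [(i, i + 1) for i in range(6)]

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(-5, 5, allow_nan=False)),
            min_size=2,
            max_size=40,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, values):
        mode = np.array(values)
        p = zero_cross_partition(mode)
        assert p.intervals == brute_force_partition(mode)
        # tiling invariant + extrema inside their intervals
        assert p.intervals[0][0] == 0 and p.intervals[-1][1] == len(mode)
        for (a, b), q, v in zip(p.intervals, p.extremum_index, p.extremum_value):
            assert a <= q < b
            assert abs(v) == np.max(np.abs(mode[a:b]))


class TestSigmaEstimator:
    def test_monte_carlo_calibration(self):
        """The 0.6745 constant makes the median-|x| estimator unbiased
        for Gaussian noise: within 3% of truth in >= 95% of 200 draws at
        N_rest = 7500."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rest = rng.normal(0.0, 1.0, 7500)
            hits += abs(estimate_sigma(rest, (0, 7500)) - 1.0) <= 0.03
        assert hits >= 190

    def test_direct_formula(self):
        rest = np.full(100, 0.6745)
        assert estimate_sigma(rest, (0, 100)) == pytest.approx(1.0)

    def test_all_zero_rest_gives_zero(self):
        assert estimate_sigma(np.zeros(50), (0, 50)) == 0.0

    def test_empty_or_bad_span_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.zeros(50), (10, 10))
        with pytest.raises(ValueError):
            estimate_sigma(np.zeros(50), (0, 100))


class TestThresholdFormulas:
    def test_improved_threshold_values(self):
        assert improved_threshold(2.0, 7, 1.0) == pytest.approx(
            2.0 * math.sqrt(2 * math.log(7))
        )
        assert improved_threshold(1.0, 7500, 0.3) == pytest.approx(
            0.3 * math.sqrt(2 * math.log(7500))
        )
        assert improved_threshold(0.0, 100, 0.3) == 0.0

    def test_universal_threshold_values(self):
        assert universal_threshold(1.0, 2) == pytest.approx(math.sqrt(2 * math.log(2)))
        assert universal_threshold(0.0, 100) == 0.0
        assert universal_threshold(1.0, 10**6) > universal_threshold(1.0, 10**3)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            improved_threshold(1.0, 1, 0.3)
        with pytest.raises(ValueError):
            improved_threshold(1.0, 100, 0.0)
        with pytest.raises(ValueError):
            universal_threshold(1.0, 1)


class TestIntervalThreshold:
    def lobe_signal(self):
        # two lobes: extrema 0.5 and 2.0
        return np.array([0.3, 0.5, 0.3, -1.0, -2.0, -1.5])

    def test_sub_threshold_interval_zeroed(self):
        mode = np.array([0.3, 0.5, 0.3])
        p = zero_cross_partition(mode)
        for op in ("hard", "soft"):
            assert np.array_equal(interval_threshold(mode, p, 1.0, op), np.zeros(3))

    def test_soft_factor_half(self):
        mode = np.array([1.0, 2.0, 1.0])
        p = zero_cross_partition(mode)
        out = interval_threshold(mode, p, 1.0, "soft")
        np.testing.assert_allclose(out, mode * 0.5)

    def test_hard_passthrough(self):
        mode = np.array([1.0, 2.0, 1.0])
        p = zero_cross_partition(mode)
        assert np.array_equal(interval_threshold(mode, p, 1.0, "hard"), mode)

    def test_mixed_lobes(self):
        mode = self.lobe_signal()
        p = zero_cross_partition(mode)
        hard = interval_threshold(mode, p, 1.0, "hard")
        assert np.array_equal(hard[:3], np.zeros(3))  # extremum 0.5 <= 1
        assert np.array_equal(hard[3:], mode[3:])  # extremum |-2| > 1

    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=60),
        st.floats(0, 12),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_energy_never_increases_and_hard_dominates_soft(self, values, T):
        mode = np.array(values)
        p = zero_cross_partition(mode)
        hard = interval_threshold(mode, p, T, "hard")
        soft = interval_threshold(mode, p, T, "soft")
        assert np.linalg.norm(hard) <= np.linalg.norm(mode) + 1e-12
        assert np.linalg.norm(soft) <= np.linalg.norm(mode) + 1e-12
        assert np.all(np.abs(hard) >= np.abs(soft) - 1e-12)

    def test_zero_threshold_is_identity(self):
        mode = self.lobe_signal()
        p = zero_cross_partition(mode)
        for op in ("hard", "soft"):
            np.testing.assert_allclose(interval_threshold(mode, p, 0.0, op), mode)

    def test_mismatched_partition_rejected(self):
        p = zero_cross_partition(np.ones(5))
        with pytest.raises(ValueError):
            interval_threshold(np.ones(6), p, 0.5)


class TestThresholdConfig:
    def test_operator_defaults(self):
        assert ThresholdConfig(operator="soft").C == 0.3
        assert ThresholdConfig(operator="hard").C == 0.7

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(operator="medium")
        with pytest.raises(ValueError):
            ThresholdConfig(scheme="T5")
        with pytest.raises(ValueError):
            ThresholdConfig(scheme="T4", C=-1.0)


class TestDetectRest:
    def test_finds_quiet_prefix(self):
        from semgdenoise.synthetic import SyntheticConfig, generate_keystroke_semg

        clean = generate_keystroke_semg(SyntheticConfig(seed=3))
        stripped = Signal(clean.samples, clean.fs)  # drop the known span
        start, end = detect_rest(stripped)
        true_start, true_end = clean.rest_span
        overlap = max(0, min(end, true_end) - max(start, true_start))
        assert overlap >= 0.9 * (end - start)

    def test_constant_zero_returns_whole_record(self):
        s = Signal(np.zeros(3000), 100.0)
        assert detect_rest(s, window=0.5) == (0, 3000)

    def test_loud_noise_still_returns_a_span(self):
        rng = np.random.default_rng(0)
        s = Signal(rng.standard_normal(5000), 100.0)
        start, end = detect_rest(s, window=0.5)
        assert 0 <= start < end <= 5000

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_rest(Signal(np.zeros(30), 100.0), window=0.5)
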