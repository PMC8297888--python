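"""Topological index definitions: worked examples and identities."""

import math

import numpy as np
import pytest

from topohrv import (
    compute_persistence,
    entropy_indices,
    length_indices,
    location_indices,
    threshold_indices,
    topological_indices,
)
from conftest import diagram_from_pairs


def diagram_with_lengths(lengths):
    """A diagram whose interval lengths are exactly ``lengths``."""
    return diagram_from_pairs([(0.0, l) for l in lengths])


class TestLengthIndices:
    def test_worked_example(self):
        out = length_indices(diagram_with_lengths([1, 2, 2, 5]))
        assert out.longest_interval == 5
        assert out.length_mean == pytest.approx(2.5)
        assert out.length_median == pytest.approx(2)
        assert out.length_sum == pytest.approx(10)
        assert out.ratio_2_1 == pytest.approx(0.4)
        assert out.ratio_3_1 == pytest.approx(0.4)

    def test_single_pair_ratios_missing(self):
        out = length_indices(diagram_with_lengths([7.0]))
        assert out.longest_interval == 7.0
        assert out.length_sum == 7.0
        assert math.isnan(out.ratio_2_1)
        assert math.isnan(out.ratio_3_1)

    def test_equal_lengths(self):
        out = length_indices(diagram_with_lengths([3.0] * 5))
        assert out.length_stdev == 0.0
        assert out.ratio_2_1 == 1.0
        assert out.ratio_3_1 == 1.0

    def test_zero_longest_ratios_missing(self):
        out = length_indices(diagram_from_pairs([(800, 800), (900, 900)]))
        assert math.isnan(out.ratio_2_1)

    def test_per_rr_normalisation(self):
        dgm = compute_persistence([3, 1, 2, 0, 4])
        out = length_indices(dgm)
        assert out.length_sum_per_rr == pytest.approx(out.length_sum / 5)


class TestEntropyIndices:
    def test_uniform_distribution_maximal(self):
        out = entropy_indices(diagram_with_lengths([1, 1, 1, 1]))
        assert out.pers_entropy == pytest.approx(2.0)
        assert out.normed_entropy == pytest.approx(1.0)

    def test_worked_example(self):
        out = entropy_indices(diagram_with_lengths([1, 3]))
        assert out.pers_entropy == pytest.approx(0.811278, abs=1e-6)
        assert out.normed_entropy == pytest.approx(0.405639, abs=1e-6)

    def test_single_interval_zero_entropy(self):
        out = entropy_indices(diagram_with_lengths([42.0]))
        assert out.pers_entropy == 0.0

    def test_zero_total_length_missing(self):
        out = entropy_indices(diagram_from_pairs([(800, 800)]))
        assert math.isnan(out.pers_entropy)

    def test_unit_total_length_normed_missing(self):
        out = entropy_indices(diagram_with_lengths([0.5, 0.5]))
        assert out.pers_entropy == pytest.approx(1.0)
        assert math.isnan(out.normed_entropy)

    def test_zero_length_pairs_excluded_from_sum(self):
        with_zero = entropy_indices(diagram_with_lengths([0.0, 1, 3]))
        without = entropy_indices(diagram_with_lengths([1, 3]))
        assert with_zero.pers_entropy == pytest.approx(without.pers_entropy)

    @pytest.mark.parametrize("lengths", [[1, 2, 3], [5, 5, 90], [0.1, 40]])
    def test_entropy_bounded_by_log_k(self, lengths):
        out = entropy_indices(diagram_with_lengths(lengths))
        assert 0.0 <= out.pers_entropy <= math.log2(len(lengths)) + 1e-12


class TestThresholdIndices:
    def test_worked_example(self):
        out = threshold_indices(diagram_with_lengths([1, 2, 40, 100]))
        assert out.length_threshold == pytest.approx(5.0)
        assert out.frac5 == pytest.approx(0.5)
        assert out.frac100 == pytest.approx(0.25)
        assert out.frac200 == 0.0
        assert out.signal_to_noise == pytest.approx(140 / 3)

    def test_no_noise_intervals_infinite_snr(self):
        out = threshold_indices(diagram_with_lengths([10, 10, 10]))
        assert out.length_threshold == pytest.approx(0.5)
        assert out.frac5 == 1.0
        assert math.isinf(out.signal_to_noise)

    def test_frac100_threshold_inclusive(self):
        out = threshold_indices(diagram_with_lengths([100, 100]))
        assert out.frac100 == 1.0
        assert out.frac200 == 0.0

    def test_tie_at_threshold_counts_as_noise(self):
        # threshold = 5; the interval of length exactly 5 is noise
        out = threshold_indices(diagram_with_lengths([5, 50, 100]))
        assert out.frac5 == pytest.approx(2 / 3)
        assert out.signal_to_noise == pytest.approx(150 / 5)

    def test_frac5_independent_check(self):
        lengths = [0.5, 2, 3, 3, 40, 100]
        out = threshold_indices(diagram_with_lengths(lengths))
        expect = sum(1 for l in lengths if l > 5) / len(lengths)
        assert out.frac5 == pytest.approx(expect)

    def test_snr_lower_bound(self):
        lengths = [1, 2, 3, 50, 80]
        out = threshold_indices(diagram_with_lengths(lengths))
        noise = sum(l for l in lengths if l <= 0.05 * 80)
        assert out.signal_to_noise >= 80 / noise


class TestLocationIndices:
    def test_worked_example(self):
        out = location_indices(diagram_from_pairs([(0, 4), (1, 2)]))
        assert out.middle_mean == pytest.approx(1.75)
        assert out.middle_stdev == pytest.approx(0.353553, abs=1e-6)
        assert out.birth_mean == pytest.approx(0.5)
        assert out.death_mean == pytest.approx(3.0)

    def test_single_qualifying_pair(self):
        dgm = diagram_from_pairs([(700, 900), (750, 751)])
        out = location_indices(dgm)  # threshold = 10, short pair excluded
        assert out.middle_mean == pytest.approx(800)
        assert out.middle_stdev == 0.0
        assert out.birth_stdev == 0.0

    def test_translation_equivariance(self):
        base = location_indices(diagram_from_pairs([(0, 4), (1, 2)]))
        moved = location_indices(diagram_from_pairs([(100, 104), (101, 102)]))
        for name in ("middle_mean", "birth_mean", "death_mean"):
            assert getattr(moved, name) == pytest.approx(
                getattr(base, name) + 100
            )
        for name in ("middle_stdev", "birth_stdev", "death_stdev"):
            assert getattr(moved, name) == pytest.approx(getattr(base, name))


def test_scale_equivariance_of_index_set():
    """Scaling RRs by s scales ms-valued indices by s, leaves the
    dimensionless ratios/counts/entropy unchanged, and moves frac100
    as predicted by the rescaled lengths."""
    rng = np.random.default_rng(3)
    v = rng.normal(800, 60, 120)
    s = 2.5
    a = topological_indices(compute_persistence(v))
    b = topological_indices(compute_persistence(v * s))
    for name in ("longest_interval", "length_mean", "length_median",
                 "length_stdev", "length_sum", "length_threshold",
                 "middle_mean", "middle_stdev", "birth_mean", "death_mean"):
        assert getattr(b, name) == pytest.approx(s * getattr(a, name))
    for name in ("number_of_intervals", "ratio_2_1", "ratio_3_1",
                 "frac5", "pers_entropy", "signal_to_noise"):
        assert getattr(b, name) == pytest.approx(getattr(a, name))
    lengths = compute_persistence(v).lengths * s
    assert b.frac100 == pytest.approx((lengths >= 100).mean())


def test_entropy_maximal_iff_equal_lengths():
    eq = entropy_indices(diagram_with_lengths([2, 2, 2, 2]))
    assert eq.pers_entropy == pytest.approx(2.0)
    uneq = entropy_indices(diagram_with_lengths([1, 2, 3, 4]))
    assert uneq.pers_entropy < 2.0
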