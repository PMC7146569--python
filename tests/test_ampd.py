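import numpy as np
import pytest

from tdhr.ampd import (
    AmpdParams,
    BinaryLMS,
    GammaVector,
    column_sums,
    compute_binary_lms,
    compute_gamma,
    detect_peaks,
    detect_peaks_original_ampd,
    flat_peak_positions,
    quality_gate,
)

FS = 32.0


def lms_oracle(x, lambda_max):
    """Literal triple-loop evaluation of the 1-based binary LMS definition.

    Cell (k, i) for 1-based i = k+2 .. N-k+1 tests sample x_{i-1}; the bit
    is stored in the column of the tested sample (0-based index i-2).
    """
    n = len(x)
    bits = np.ones((lambda_max, n), dtype=np.uint8)
    for k in range(1, lambda_max + 1):
        for i in range(k + 2, n - k + 2):
            if x[i - 2] > x[i - k - 2] and x[i - 2] > x[i + k - 2]:
                bits[k - 1, i - 2] = 0
    return bits


class TestBinaryLMS:
    def test_matches_literal_oracle_on_random_window(self, rng):
        x = rng.normal(0, 1, 64)
        params = AmpdParams(n=64, lambda_max=17)
        got = compute_binary_lms(x, params).bits
        np.testing.assert_array_equal(got, lms_oracle(x, 17))

    def test_sinusoid_zero_columns_at_crests(self):
        # 2 Hz at 32 Hz: period 16 samples, crest exactly at i = 4 mod 16
        i = np.arange(128)
        x = np.sin(2 * np.pi * 2.0 * i / FS)
        params = AmpdParams(n=128, lambda_max=17)
        lms = compute_binary_lms(x, params)
        np.testing.assert_array_equal(lms.bits, lms_oracle(x, 17))
        # the selected scale is the half period, and at that scale the zero
        # columns are exactly the crests with full scale support
        gv = compute_gamma(lms)
        assert gv.lam == 8
        s = column_sums(lms, gv.lam)
        crests = np.array([j for j in range(4, 128, 16) if 8 <= j <= 127 - 8])
        np.testing.assert_array_equal(np.flatnonzero(s == 0), crests)

    def test_triangular_peak_column_all_zero(self):
        x = -np.abs(np.arange(64) - 31.0)  # single triangular peak at 31
        bits = compute_binary_lms(x, AmpdParams(n=64, lambda_max=17)).bits
        for k in range(1, 18):
            assert bits[k - 1, 31] == 0  # in range for every stored scale

    def test_monotone_input_has_no_zeros(self):
        bits = compute_binary_lms(np.arange(64.0), AmpdParams(n=64)).bits
        assert bits.min() == 1

    def test_window_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_binary_lms(np.zeros(100), AmpdParams(n=64))

    def test_window_too_short_for_scales(self):
        with pytest.raises(ValueError):
            AmpdParams(n=20, lambda_max=17)


class TestGammaAndGate:
    def test_uniform_rows_tie_break_smallest(self):
        gv = compute_gamma(BinaryLMS(np.ones((3, 8), dtype=np.uint8)))
        np.testing.assert_array_equal(gv.gamma, [8, 8, 8])
        assert gv.lam == 1

    def test_interior_argmin(self):
        bits = np.ones((3, 30), dtype=np.uint8)
        bits[1, :18] = 0  # row 2 sums to 12; rows 1 and 3 sum to 30
        bits[2, :11] = 0
        gv = compute_gamma(BinaryLMS(bits))
        np.testing.assert_array_equal(gv.gamma, [30, 12, 19])
        assert gv.lam == 2

    def test_gate_rejects_boundary_minimum(self):
        gamma = np.arange(17, 0, -1)  # strictly decreasing: min on last row
        assert not quality_gate(GammaVector(gamma, lam=17), AmpdParams(n=64))

    def test_gate_accepts_interior_minimum(self):
        gamma = np.full(17, 50)
        gamma[8] = 10
        assert quality_gate(GammaVector(gamma, lam=9), AmpdParams(n=64))

    def test_clean_windows_pass_gate(self, conditioned_window):
        # typical daily-life rates sit well inside the stored scale range
        passed = 0
        for seed in range(20):
            hr = 60.0 + 3.0 * seed  # 60..117 bpm
            w, _ = conditioned_window(hr=hr, seed=seed)
            passed += detect_peaks(w, AmpdParams(n=1024)).valid
        assert passed >= 19

    def test_gate_rejects_slow_periodicity(self, conditioned_window):
        # a clean 45 bpm signal has half-period ~21 samples > lambda_max:
        # its best scale is not storable, so the window reads as too noisy
        w, _ = conditioned_window(hr=45.0, seed=0)
        res = detect_peaks(w, AmpdParams(n=1024))
        assert res.lam == 17 and not res.valid and res.n_peaks == 0


class TestColumnSums:
    def test_lambda_one_equals_first_row(self, rng):
        bits = (rng.random((17, 64)) < 0.5).astype(np.uint8)
        np.testing.assert_array_equal(column_sums(BinaryLMS(bits), 1), bits[0])

    def test_matches_brute_force(self, rng):
        bits = (rng.random((17, 64)) < 0.5).astype(np.uint8)
        lam = 9
        expected = [sum(int(bits[k, i]) for k in range(lam)) for i in range(64)]
        np.testing.assert_array_equal(column_sums(BinaryLMS(bits), lam), expected)

    def test_zero_column_gives_zero(self):
        bits = np.ones((5, 16), dtype=np.uint8)
        bits[:3, 7] = 0
        assert column_sums(BinaryLMS(bits), 3)[7] == 0

    def test_out_of_range_lambda(self):
        with pytest.raises(ValueError):
            column_sums(BinaryLMS(np.ones((5, 16), dtype=np.uint8)), 6)


class TestFlatPeakRule:
    def test_signature_emits_midpoint(self):
        s = np.array([5, 4, 3, 1, 1, 4, 5])
        np.testing.assert_array_equal(flat_peak_positions(s), [3.5])

    def test_no_adjacent_ones_no_output(self):
        s = np.array([3, 1, 2, 1, 3, 0, 2])
        assert flat_peak_positions(s).size == 0

    def test_flat_top_periodic_signal(self):
        # crest realised as two equal samples every 20 samples
        period = np.concatenate([np.arange(10.0), [9.0], 9.0 - np.arange(1, 10.0)])
        x = np.tile(period, 8)
        res = detect_peaks(x - x.mean(), AmpdParams(n=len(x)))
        assert res.valid
        # no strict local maxima exist, so every peak is a flat midpoint
        assert np.all(res.peaks % 1 == 0.5)
        # every crest with full scale support (lam samples on both sides)
        crest_mid = np.arange(9.5, len(x), 20.0)
        supported = crest_mid[(crest_mid - 0.5 >= res.lam)
                              & (crest_mid + 0.5 <= len(x) - 1 - res.lam)]
        np.testing.assert_array_equal(res.peaks, supported)


class TestDetectPeaks:
    def test_clean_ppg_inter_peak_median(self, conditioned_window):
        w, _ = conditioned_window(hr=75.0, seed=1)
        res = detect_peaks(w, AmpdParams(n=1024))
        assert res.valid
        med = np.median(np.diff(res.peaks))
        assert med == pytest.approx(60 * FS / 75.0, abs=1.0)  # 25.6 samples

    def test_constant_window_yields_no_peaks(self):
        res = detect_peaks(np.full(128, 3.0), AmpdParams(n=128))
        assert res.n_peaks == 0

    def test_integer_peaks_have_zero_column_sum(self, conditioned_window):
        w, _ = conditioned_window(hr=90.0, seed=2)
        res = detect_peaks(w, AmpdParams(n=1024))
        ints = res.peaks[res.peaks % 1 == 0].astype(int)
        assert np.all(res.column_sums[ints] == 0)

    def test_peaks_strictly_increasing(self, conditioned_window):
        w, _ = conditioned_window(hr=110.0, seed=3)
        res = detect_peaks(w, AmpdParams(n=1024))
        assert np.all(np.diff(res.peaks) > 0)


class TestOriginalAmpd:
    def test_monotone_no_peaks(self):
        res = detect_peaks_original_ampd(np.arange(64.0), rng_seed=0)
        assert res.n_peaks == 0

    def test_single_global_peak_found(self):
        x = -np.abs(np.arange(33) - 16.0)
        res = detect_peaks_original_ampd(x, rng_seed=0)
        np.testing.assert_array_equal(res.peaks, [16.0])

    def test_zero_pattern_equivalence(self, conditioned_window):
        # the 0-cells of the real-valued and binary scalograms share one
        # comparison condition, so sigma_i = 0 iff s_i = 0 at equal lambda
        checked = 0
        for seed in range(10):
            w, _ = conditioned_window(hr=70.0 + 5 * seed, seed=40 + seed)
            binary = detect_peaks(w, AmpdParams(n=1024, enable_flat_peak_rule=False))
            orig = detect_peaks_original_ampd(w, rng_seed=seed)
            if binary.lam != orig.lam or not binary.valid:
                continue
            np.testing.assert_array_equal(binary.peaks, orig.peaks)
            checked += 1
        assert checked >= 8
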