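"""Unit and property tests for the direct entropy-rate estimator."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entropix.shannon_direct import (
    DiscreteSignal,
    ProbabilitySpaceParams,
    SymbolSequence,
    TrialMatrix,
    entropy_grid,
    entropy_rate_direct,
    information_rate,
    make_words,
    noise_entropy_rate,
    quadratic_extrapolate,
    quantize,
    shannon_entropy,
)

WORKED = DiscreteSignal([0, 4, 0, 5, 0, 4, 0, 5])


class TestQuantize:
    def test_binary_quantization_of_digit_string(self):
        assert quantize(WORKED, 2).symbols.tolist() == [0, 1, 0, 1, 0, 1, 0, 1]

    def test_six_levels_preserve_digits(self):
        assert quantize(WORKED, 6).symbols.tolist() == [0, 4, 0, 5, 0, 4, 0, 5]

    def test_constant_signal_all_zeros(self):
        seq = quantize(DiscreteSignal([3.3] * 7), 16)
        assert seq.symbols.tolist() == [0] * 7

    def test_full_ramp_hits_every_bin_in_order(self):
        seq = quantize(DiscreteSignal(np.arange(256.0)), 256)
        assert seq.symbols.tolist() == list(range(256))

    def test_rejects_v_below_two(self):
        with pytest.raises(ValueError):
            quantize(WORKED, 1)


class TestMakeWords:
    def test_pairs_of_digit_string_have_two_words(self):
        words = make_words(quantize(WORKED, 6), 2)
        assert len(words) == 4
        assert len(set(words.symbols.tolist())) == 2

    def test_binary_pairs_collapse_to_one_word(self):
        words = make_words(quantize(WORKED, 2), 2)
        assert len(set(words.symbols.tolist())) == 1

    def test_t1_is_identity(self):
        seq = quantize(WORKED, 6)
        assert make_words(seq, 1) is seq

    def test_remainder_discarded(self):
        seq = SymbolSequence(np.array([0, 1, 0, 1, 1]), 2)
        assert len(make_words(seq, 2)) == 2

    def test_oversized_t_warns_and_returns_empty(self):
        seq = SymbolSequence(np.array([0, 1]), 2)
        with pytest.warns(UserWarning):
            assert len(make_words(seq, 5)) == 0


class TestShannonEntropy:
    @pytest.mark.parametrize("v,T,expected", [
        (6, 1, 1.5), (2, 1, 1.0), (6, 2, 1.0), (2, 2, 0.0),
    ])
    def test_worked_example_entropies(self, v, T, expected):
        h = shannon_entropy(make_words(quantize(WORKED, v), T))
        assert h == pytest.approx(expected, abs=1e-12)

    def test_uniform_256_symbols_reach_8_bits(self):
        assert shannon_entropy(np.arange(256)) == pytest.approx(8.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(SymbolSequence(np.empty(0, dtype=int), 2))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=12))
    def test_matches_exhaustive_count_oracle(self, symbols):
        """Plug-in entropy equals the definition computed from raw counts."""
        counts = Counter(symbols)
        expected = -sum(
            (c / len(symbols)) * math.log2(c / len(symbols))
            for c in counts.values()
        )
        got = shannon_entropy(SymbolSequence(np.array(symbols), 4))
        assert got == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 3), min_size=4, max_size=60),
           st.integers(2, 4))
    def test_block_entropy_subadditive(self, symbols, T):
        """Grouping into T-words never exceeds T times the symbol entropy."""
        seq = SymbolSequence(np.array(symbols), 4)
        words = make_words(seq, T)
        if len(words) == 0:
            return
        assert shannon_entropy(words) <= T * shannon_entropy(seq) + 1e-9


class TestQuadraticExtrapolate:
    def test_exact_parabola_recovers_intercept(self):
        x = np.array([0.2, 0.5, 1.0, 1.5, 2.0])
        fit = quadratic_extrapolate(x, 3 + x - 2 * x**2)
        assert fit.intercept == pytest.approx(3.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_use_linear_fallback(self):
        fit = quadratic_extrapolate([1.0, 0.5], [2.0, 1.5])
        assert fit.degree == 1
        assert fit.intercept == pytest.approx(1.0)

    def test_noisy_parabola_matches_normal_equations(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0.1, 2.0, 9)
        y = 1.5 - 0.7 * x + 0.3 * x**2 + rng.normal(0, 0.05, x.size)
        fit = quadratic_extrapolate(x, y)
        design = np.column_stack([np.ones_like(x), x, x**2])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            quadratic_extrapolate([1.0], [1.0])


class TestEntropyGrid:
    def test_default_grid_has_384_entries(self):
        rng = np.random.default_rng(0)
        sig = DiscreteSignal(rng.integers(0, 256, 2000).astype(float))
        grid = entropy_grid(sig)
        assert len(grid.entries) == 6 * 8 * 8

    def test_single_cell_grid_is_plugin_entropy(self):
        params = ProbabilitySpaceParams((1.0,), (2,), (1,))
        grid = entropy_grid(WORKED, params)
        assert grid.entries[(1.0, 2, 1)] == pytest.approx(1.0)

    def test_constant_signal_grid_all_zero(self):
        grid = entropy_grid(DiscreteSignal(np.full(400, 2.0)))
        vals = [v for k, v in grid.entries.items() if k not in grid.unreliable]
        assert all(v == 0 for v in vals)

    def test_too_few_words_flagged_not_dropped(self):
        params = ProbabilitySpaceParams((1.0, 0.5), (2,), (1, 8))
        sig = DiscreteSignal(np.tile([0.0, 1.0], 6))  # 12 samples
        grid = entropy_grid(sig, params)
        assert (0.5, 2, 8) in grid.unreliable
        assert (0.5, 2, 8) in grid.entries

    def test_entries_bounded_by_t_log_v(self):
        rng = np.random.default_rng(5)
        sig = DiscreteSignal(rng.normal(size=1500))
        grid = entropy_grid(sig)
        for (s, v, t), h in grid.entries.items():
            if (s, v, t) not in grid.unreliable:
                assert 0 <= h <= t * np.log2(v) + 1e-9


class TestEntropyRateDirect:
    def test_constant_signal_rate_zero(self):
        est = entropy_rate_direct(DiscreteSignal(np.full(500, 1.0)))
        assert est.rate == pytest.approx(0.0, abs=1e-9)

    def test_sampling_rate_scales_to_bits_per_second(self):
        rng = np.random.default_rng(1)
        sig = DiscreteSignal(rng.integers(0, 2, 600).astype(float),
                             sampling_rate=100.0)
        est = entropy_rate_direct(sig)
        assert est.rate_bits_per_s == pytest.approx(100.0 * est.rate)

    @pytest.mark.parametrize("v,tol", [(2, 0.02), (4, 0.02), (8, 0.04)])
    def test_long_uniform_noise_recovers_log2_v(self, v, tol):
        """100k-sample uniform noise lands near log2(v).

        v=8 carries a slightly wider band: with two unsaturated and six
        saturated quantization points the 1/v extrapolation stage has an
        intrinsic positive bias of ~3% that no amount of data removes.
        """
        rng = np.random.default_rng(42)
        sig = DiscreteSignal(rng.integers(0, v, 100_000).astype(float))
        est = entropy_rate_direct(sig)
        assert est.rate == pytest.approx(np.log2(v), rel=tol)

    def test_method_tag_reports_fallback(self):
        rng = np.random.default_rng(3)
        sig = DiscreteSignal(rng.integers(0, 256, 10_000).astype(float))
        est = entropy_rate_direct(sig)
        assert est.method_tag in {"quadratic", "linear_last2"}
        assert "stage3_inv_T" in est.diagnostics


class TestTrialRates:
    def test_identical_rows_have_zero_noise_entropy(self):
        rng = np.random.default_rng(7)
        row = rng.integers(0, 4, 400).astype(float)
        tm = TrialMatrix(np.tile(row, (6, 1)))
        assert noise_entropy_rate(tm).rate == pytest.approx(0.0, abs=1e-9)

    def test_identical_rows_information_equals_signal(self):
        rng = np.random.default_rng(8)
        row = rng.integers(0, 4, 400).astype(float)
        tm = TrialMatrix(np.tile(row, (6, 1)))
        est = information_rate(tm)
        assert est.rate == pytest.approx(est.diagnostics["signal_rate"])

    def test_iid_square_matrix_noise_matches_signal(self):
        """For an i.i.d. matrix both axes sample the same source."""
        rng = np.random.default_rng(9)
        tm = TrialMatrix(rng.integers(0, 2, (200, 200)).astype(float))
        rn = noise_entropy_rate(tm).rate
        rs = entropy_rate_direct(DiscreteSignal(tm.trials[0])).rate
        assert rn == pytest.approx(rs, rel=0.1)

    def test_iid_matrix_information_near_zero(self):
        rng = np.random.default_rng(10)
        tm = TrialMatrix(rng.integers(0, 2, (200, 200)).astype(float))
        est = information_rate(tm)
        assert abs(est.rate) < 0.05 * est.diagnostics["signal_rate"]

    def test_one_column_matrix_equals_column_signal_rate(self):
        rng = np.random.default_rng(12)
        col = rng.integers(0, 3, 24).astype(float)
        tm = TrialMatrix(col[:, None])
        rn = noise_entropy_rate(tm).rate
        rs = entropy_rate_direct(DiscreteSignal(col)).rate
        assert rn == pytest.approx(max(rs, 0.0), abs=1e-9)

    def test_partial_information_between_extremes(self):
        """Frozen pattern with rare flips: 0 < R < R_S."""
        rng = np.random.default_rng(13)
        base = rng.integers(0, 2, 600).astype(float)
        rows = np.tile(base, (8, 1))
        flips = rng.random(rows.shape) < 0.05
        rows[flips] = 1 - rows[flips]
        est = information_rate(TrialMatrix(rows))
        assert 0.0 < est.rate < est.diagnostics["signal_rate"]

    def test_single_trial_rejected(self):
        tm = TrialMatrix(np.zeros((1, 50)))
        with pytest.raises(ValueError):
            noise_entropy_rate(tm)
        with pytest.raises(ValueError):
            information_rate(tm)

    def test_column_stride_estimates_same_mean(self):
        rng = np.random.default_rng(14)
        tm = TrialMatrix(rng.integers(0, 2, (20, 500)).astype(float))
        full = noise_entropy_rate(tm).rate
        strided = noise_entropy_rate(tm, column_stride=2).rate
        assert strided == pytest.approx(full, rel=0.05)


class TestParamsValidation:
    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            ProbabilitySpaceParams(size_fractions=(1.0, 1.0))

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            ProbabilitySpaceParams(size_fractions=(1.5,))

    def test_signal_validation(self):
        with pytest.raises(ValueError):
            DiscreteSignal([])
        with pytest.raises(ValueError):
            DiscreteSignal([1.0, np.nan])
        with pytest.raises(ValueError):
            DiscreteSignal([1.0], sampling_rate=0.0)
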