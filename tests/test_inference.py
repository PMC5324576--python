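"""Permutation schemes, maximum-statistics thresholding, mass-univariate runs."""

import json

import numpy as np
import pytest

from copulainfo import (
    gcmi_cc,
    gcmi_cd,
    max_stat_threshold,
    permute_blocks,
    permute_labels,
    run_mass_univariate,
)
from copulainfo.simulate import gen_continuous_lagged, gen_event_related


class TestPermuteLabels:
    def test_bijection_and_determinism(self, rng):
        y = rng.integers(0, 3, 40)
        p1 = permute_labels(y, seed=5)
        p2 = permute_labels(y, seed=5)
        np.testing.assert_array_equal(np.sort(p1), np.sort(y))
        np.testing.assert_array_equal(p1, p2)
        assert not np.array_equal(p1, y)

    def test_mean_permuted_statistic_is_null_level(self):
        rng = np.random.default_rng(81)
        n = 300
        y = rng.integers(0, 2, n)
        x = rng.standard_normal(n) + 1.2 * y
        observed = gcmi_cd(x, y, bias_correct=False).bits
        perm_vals = [
            gcmi_cd(x, permute_labels(y, seed=s), bias_correct=False).bits
            for s in range(100)
        ]
        assert observed > 10 * np.mean(perm_vals)
        assert np.mean(perm_vals) < 0.02


class TestPermuteBlocks:
    def test_circular_shift_is_rotation(self, rng):
        x = rng.standard_normal(50)
        out = permute_blocks(x, block_length=10, mode="circular_shift", seed=3)
        # some rotation of x
        assert any(
            np.array_equal(out, np.roll(x, k)) for k in range(50)
        )

    def test_block_permutation_preserves_short_lag_autocorrelation(self):
        rng = np.random.default_rng(83)
        # AR(1) series; blockwise shuffling must keep lag-1 autocorrelation
        n, rho = 5000, 0.9
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for t in range(1, n):
            x[t] = rho * x[t - 1] + rng.standard_normal()
        def lag1(v):
            return np.corrcoef(v[:-1], v[1:])[0, 1]

        perm = permute_blocks(x, block_length=500, seed=4)
        full = permute_labels(x, seed=4)
        assert lag1(perm) == pytest.approx(lag1(x), abs=0.05)
        assert abs(lag1(full)) < 0.1  # destroyed by full permutation

    def test_trailing_partial_block_kept(self):
        x = np.arange(10)
        out = permute_blocks(x, block_length=4, seed=1)
        np.testing.assert_array_equal(np.sort(out), x)

    def test_block_longer_than_series(self):
        with pytest.raises(ValueError, match="exceeds"):
            permute_blocks(np.arange(5), block_length=9, seed=0)


class TestMaxStatThreshold:
    def test_order_statistic_convention(self):
        null = np.arange(1, 1001, dtype=float)
        # ceil(0.99 * 1001) = 991st sorted value (identity permutation counted)
        assert max_stat_threshold(null, 0.01) == 991.0

    def test_alpha_one_returns_minimum(self):
        null = np.array([3.0, 1.0, 2.0])
        assert max_stat_threshold(null, 1.0) == 1.0

    def test_warns_on_too_few_permutations(self):
        with pytest.warns(RuntimeWarning, match="recommended"):
            max_stat_threshold(np.arange(10.0), 0.01)

    def test_empty_null(self):
        with pytest.raises(ValueError, match="empty"):
            max_stat_threshold(np.array([]), 0.05)


class TestRunMassUnivariate:
    def test_planted_effect_recovered(self):
        data, y = gen_event_related(
            150, 6, 4, seed=91, effect_channel=2, effect_times=(3,), effect_size=2.0
        )
        res = run_mass_univariate(data, y, n_perm=200, alpha=0.05, seed=1)
        assert res.mask[2, 3]
        assert res.mask.sum() <= 2  # at most the planted cell and a neighbour

    def test_mask_monotone_in_alpha(self):
        data, y = gen_event_related(
            120, 5, 3, seed=92, effect_channel=1, effect_times=(2,), effect_size=1.0
        )
        strict = run_mass_univariate(data, y, n_perm=200, alpha=0.01, seed=2)
        loose = run_mass_univariate(data, y, n_perm=200, alpha=0.05, seed=2)
        assert np.all(loose.mask >= strict.mask)

    def test_seeded_determinism_bitwise(self):
        data, y = gen_event_related(80, 4, 2, seed=93)
        a = run_mass_univariate(data, y, n_perm=50, alpha=0.05, seed=7)
        b = run_mass_univariate(data, y, n_perm=50, alpha=0.05, seed=7)
        np.testing.assert_array_equal(a.observed, b.observed)
        np.testing.assert_array_equal(a.null_max, b.null_max)
        assert a.threshold == b.threshold

    def test_threshold_dominates_per_cell_percentile(self):
        data, y = gen_event_related(100, 4, 3, seed=94)
        res = run_mass_univariate(data, y, n_perm=100, alpha=0.05, seed=3)
        assert res.threshold >= np.quantile(res.null_max, 0.5)

    def test_fast_cd_path_matches_generic_callable(self):
        data, y = gen_event_related(
            60, 3, 2, seed=95, effect_channel=0, effect_times=(1,), effect_size=1.0
        )
        fast = run_mass_univariate(data, y, estimator="gcmi_cd", n_perm=30, seed=11)

        def slow_cd(x, labels):
            return gcmi_cd(x, labels, bias_correct=False).bits

        slow = run_mass_univariate(data, y, estimator=slow_cd, n_perm=30, seed=11)
        np.testing.assert_allclose(fast.observed, slow.observed, atol=1e-10)
        np.testing.assert_allclose(fast.null_max, slow.null_max, atol=1e-10)

    def test_fast_cc_path_matches_generic_callable(self):
        rng = np.random.default_rng(96)
        data = rng.standard_normal((70, 2, 3))
        s = rng.standard_normal(70) + data[:, 1, 2]
        fast = run_mass_univariate(data, s, estimator="gcmi_cc", n_perm=30, seed=12)

        def slow_cc(x, feat):
            return gcmi_cc(x, feat, bias_correct=False).bits

        slow = run_mass_univariate(data, s, estimator=slow_cc, n_perm=30, seed=12)
        np.testing.assert_allclose(fast.observed, slow.observed, atol=1e-10)
        np.testing.assert_allclose(fast.null_max, slow.null_max, atol=1e-10)

    def test_block_scheme_widens_null_for_autocorrelated_series(self):
        """Naive permutation understates the null spread on autocorrelated data."""
        feature, response = gen_continuous_lagged(4000, lag=5, gain=0.0, seed=97)
        grid = response[:, None]  # single-cell grid, continuous estimator
        naive = run_mass_univariate(
            grid, feature, estimator="gcmi_cc", scheme="labels", n_perm=150, seed=13,
            alpha=0.05,
        )
        block = run_mass_univariate(
            grid, feature, estimator="gcmi_cc", scheme="block", block_length=400,
            n_perm=150, seed=13, alpha=0.05,
        )
        assert np.mean(block.null_max) > 2 * np.mean(naive.null_max)

    def test_serialization_round_trip(self, tmp_path):
        data, y = gen_event_related(
            100, 3, 2, seed=98, effect_channel=1, effect_times=(0,), effect_size=1.5
        )
        res = run_mass_univariate(data, y, n_perm=60, alpha=0.05, seed=14,
                                  axes=("channel", "time"))
        tsv, sidecar = res.save(tmp_path, stem="run")
        meta = json.loads(sidecar.read_text())
        assert meta["alpha"] == 0.05 and meta["n_perm"] == 60 and meta["seed"] == 14
        import pandas as pd

        table = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
        assert list(table.columns) == ["channel", "time", "statistic", "significant"]
        got = table["statistic"].to_numpy().reshape(res.observed.shape)
        np.testing.assert_array_equal(got, res.observed)  # 17 digits round-trips
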