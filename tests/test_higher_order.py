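"""Interaction information, redundancy, directed (feature) information, novel MI."""

import numpy as np
import pytest

from copulainfo import (
    LagSpec,
    directed_feature_information,
    directed_information,
    gcmi_cd,
    gcmi_cc,
    interaction_information,
    normalized_redundancy,
    novel_information,
    pairwise_interaction_matrix,
)


@pytest.fixture
def redundant_pair(rng):
    """Two responses sharing the same stimulus projection, discrete labels."""
    n = 1500
    y = rng.integers(0, 2, n)
    common = 1.2 * y + rng.standard_normal(n)
    r1 = common + 0.3 * rng.standard_normal(n)
    r2 = common + 0.3 * rng.standard_normal(n)
    return r1, r2, y


class TestInteractionInformation:
    def test_exact_copy_is_fully_redundant(self, rng):
        n = 800
        y = rng.integers(0, 2, n)
        r1 = 0.9 * y + rng.standard_normal(n)
        ii = interaction_information(r1, r1.copy(), y).bits
        assert ii == pytest.approx(-gcmi_cd(r1, y).bits, abs=1e-12)

    def test_monotone_copy_is_fully_redundant(self, rng):
        n = 800
        y = rng.integers(0, 2, n)
        r1 = 0.9 * y + rng.standard_normal(n)
        ii = interaction_information(r1, np.exp(r1), y).bits
        assert ii == pytest.approx(-gcmi_cd(r1, y).bits, abs=1e-12)

    def test_independent_triple_near_zero(self, rng):
        r1, r2 = rng.standard_normal((2, 2000))
        y = rng.integers(0, 2, 2000)
        assert abs(interaction_information(r1, r2, y).bits) < 0.01

    def test_xor_like_sum_is_synergistic(self):
        # S = R1 + R2 + small noise, R1 independent of R2: each response alone
        # carries little, the pair carries nearly everything
        rng = np.random.default_rng(42)
        n = 5000
        r1, r2 = rng.standard_normal((2, n))
        s = r1 + r2 + 0.3 * rng.standard_normal(n)
        ii = interaction_information(r1, r2, s).bits
        assert ii > 0.3

    def test_symmetry_exact(self, redundant_pair):
        r1, r2, y = redundant_pair
        assert (
            interaction_information(r1, r2, y).bits
            == interaction_information(r2, r1, y).bits
        )

    def test_continuous_stimulus_dispatch(self, rng):
        n = 3000
        s = rng.standard_normal(n)
        r1 = s + rng.standard_normal(n)
        r2 = s + rng.standard_normal(n)
        assert interaction_information(r1, r2, s).bits < -0.05  # redundant


class TestNormalizedRedundancy:
    def test_identical_copy_is_100_percent(self, rng):
        n = 600
        y = rng.integers(0, 2, n)
        r1 = y + rng.standard_normal(n)
        red = normalized_redundancy(r1, r1.copy(), y)
        assert red.percent == pytest.approx(100.0, abs=1e-9)
        assert not red.synergy

    def test_orthogonal_channels_near_zero_percent(self):
        rng = np.random.default_rng(8)
        n = 20_000
        s = rng.standard_normal((n, 2))
        r1 = s[:, 0] + 0.5 * rng.standard_normal(n)
        r2 = s[:, 1] + 0.5 * rng.standard_normal(n)
        red = normalized_redundancy(r1, r2, s)
        assert abs(red.percent) < 5.0

    def test_synergy_clamps_to_zero_with_flag(self):
        rng = np.random.default_rng(43)
        n = 4000
        r1, r2 = rng.standard_normal((2, n))
        s = r1 + r2 + 0.3 * rng.standard_normal(n)
        red = normalized_redundancy(r1, r2, s)
        assert red.percent == 0.0
        assert red.synergy

    def test_redundant_pair_high_percent(self, redundant_pair):
        r1, r2, y = redundant_pair
        red = normalized_redundancy(r1, r2, y)
        assert 50.0 < red.percent <= 100.0 + 5.0


class TestDirectedInformation:
    def test_independent_white_noise_near_zero(self, rng):
        x, y = rng.standard_normal((2, 3000))
        assert abs(directed_information(x, y, 3).bits) < 0.01

    def test_lagged_coupling_detected_with_direction(self):
        rng = np.random.default_rng(17)
        t = 5000
        x = rng.standard_normal(t)
        y = np.zeros(t)
        y[5:] = 0.8 * x[:-5]
        y += 0.6 * rng.standard_normal(t)
        fwd = directed_information(x, y, 5).bits
        bwd = directed_information(y, x, 5).bits
        assert fwd > 0.15
        assert fwd > bwd + 0.1
        # analytic oracle: corr(x_{t-5}, y_t) = 0.8/sqrt(0.64+0.36) = 0.8,
        # y's own past is independent of y_t at lag 5 given x white
        assert fwd == pytest.approx(-0.5 * np.log2(1 - 0.8**2), abs=0.05)

    def test_embedding_dimension_accepted(self, rng):
        x, y = rng.standard_normal((2, 2000))
        di = directed_information(x, y, LagSpec(lag=2, embedding=3))
        assert abs(di.bits) < 0.02

    def test_too_short_series_raises(self, rng):
        with pytest.raises(ValueError, match="too short"):
            directed_information(rng.standard_normal(8), rng.standard_normal(8), 5)


class TestDirectedFeatureInformation:
    def test_constant_stimulus_gives_exact_zero(self, rng):
        x, y = rng.standard_normal((2, 1000))
        s = np.full(1000, 3.14)
        assert directed_feature_information(x, y, s, 2).bits == 0.0

    def test_relay_model_positive(self):
        # x carries the stimulus, y receives x after a delay: the DI is about s
        rng = np.random.default_rng(19)
        t, d = 6000, 4
        s = rng.standard_normal(t)
        x = s + 0.4 * rng.standard_normal(t)
        y = np.zeros(t)
        y[d:] = x[:-d]
        y += 0.4 * rng.standard_normal(t)
        dfi = directed_feature_information(x, y, s, d).bits
        assert dfi > 0.2

    def test_stimulus_independent_noise_near_zero(self, rng):
        t = 4000
        s = rng.standard_normal(t)
        x = rng.standard_normal(t)
        y = np.zeros(t)
        y[3:] = 0.7 * x[:-3]
        y += 0.5 * rng.standard_normal(t)
        dfi = directed_feature_information(x, y, s, 3).bits
        assert abs(dfi) < 0.02


class TestNovelInformation:
    def test_stationary_response_has_no_new_information(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        col = 0.8 * y + rng.standard_normal(n)
        r = np.tile(col[:, None], (1, 5))  # identical copies at every time point
        out = novel_information(r, y)
        assert out[0] > 0.05
        np.testing.assert_allclose(out[1:], 0.0, atol=1e-12)

    def test_single_entry_time_produces_single_peak(self):
        rng = np.random.default_rng(23)
        n, t_star = 1500, 4
        y = rng.integers(0, 2, n)
        r = rng.standard_normal((n, 8))
        r[:, t_star] += 1.5 * y
        out = novel_information(r, y)
        assert np.argmax(out) == t_star
        assert out[t_star] > 0.15
        others = np.delete(out, t_star)
        assert np.all(np.abs(others) < 0.05)

    def test_conditioning_on_independent_noise_leaves_mi(self, rng):
        n = 2000
        s = rng.standard_normal(n)
        r = rng.standard_normal((n, 2))
        r[:, 1] += s
        out = novel_information(r, s)
        direct = gcmi_cc(r[:, 1], s).bits
        assert out[1] == pytest.approx(direct, abs=0.02)

    def test_anchor_conditioning_removes_repeated_information(self):
        rng = np.random.default_rng(29)
        n = 2000
        y = rng.integers(0, 2, n)
        burst = 1.2 * y + rng.standard_normal(n)
        r = rng.standard_normal((n, 5))
        r[:, 1] += burst
        r[:, 3] += burst  # same information re-appears later
        plain = novel_information(r, y)
        anchored = novel_information(r, y, accumulate=True, anchor_times=(1,))
        assert plain[3] > 0.1  # re-appearance looks novel without anchors
        assert anchored[3] < 0.05  # anchored out


class TestPairwiseInteractionMatrix:
    def test_diagonal_and_symmetry(self, rng):
        n = 600
        y = rng.integers(0, 2, n)
        r = rng.standard_normal((n, 4))
        r[:, 2] += 1.0 * y
        m = pairwise_interaction_matrix(r, y)
        np.testing.assert_array_equal(m, m.T)
        for t in range(4):
            assert m[t, t] == pytest.approx(-gcmi_cd(r[:, t], y).bits, abs=1e-12)

    def test_shared_projection_strongly_redundant(self):
        rng = np.random.default_rng(31)
        n = 2500
        y = rng.integers(0, 2, n)
        shared = 1.5 * y + rng.standard_normal(n)
        r = rng.standard_normal((n, 3))
        r[:, 0] += shared
        r[:, 2] += shared
        m = pairwise_interaction_matrix(r, y)
        assert m[0, 2] < -0.1

    def test_stimulus_independent_data_near_zero(self, rng):
        y = rng.integers(0, 2, 1200)
        m = pairwise_interaction_matrix(rng.standard_normal((1200, 3)), y)
        assert np.abs(m).max() < 0.02
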