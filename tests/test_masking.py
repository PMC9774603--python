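"""Quartile channel selection, core masks and DropBlock shielding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painattn.masking import (
    DropBlockConfig,
    apply_region_mask,
    dropblock_gamma,
    dropblock_shield,
    make_core_mask,
    q1_position,
    select_filter_channels,
    spatial_threshold,
)


class TestQ1Position:
    @pytest.mark.parametrize("n, pos", [(7, 2.0), (3, 1.0), (511, 128.0), (4, 1.25)])
    def test_values(self, n, pos):
        assert q1_position(n) == pos

    def test_invalid(self):
        with pytest.raises(ValueError):
            q1_position(0)


class TestSelectFilterChannels:
    def test_two_smallest_of_seven(self):
        weights = [0.9, 0.1, 0.5, 0.7, 0.3, 0.2, 0.8]
        assert list(select_filter_channels(weights)) == [1, 5]

    def test_tie_break_by_index(self):
        assert list(select_filter_channels([0.5] * 7)) == [0, 1]

    def test_single_channel_selects_nothing(self):
        # Q1 position of one value is 0.5; round-half-down gives cardinality 0
        assert select_filter_channels([0.3]).size == 0

    @given(st.integers(2, 16), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=250)
    def test_matches_sort_oracle(self, n_channels, seed):
        rng = np.random.default_rng(seed)
        weights = rng.uniform(0.01, 0.99, n_channels)
        got = select_filter_channels(weights)
        count = int(np.ceil((n_channels + 1) * 0.25 - 0.5))
        oracle = sorted(sorted(range(n_channels), key=lambda i: (weights[i], i))[:count])
        assert list(got) == oracle

    def test_thousand_random_vectors_against_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 17))
            weights = rng.uniform(0, 1, n)
            got = select_filter_channels(weights)
            count = int(np.ceil((n + 1) * 0.25 - 0.5))
            oracle = sorted(np.argsort(weights, kind="stable")[:count])
            assert list(got) == list(oracle)


class TestSpatialThreshold:
    def test_position_two_of_seven(self):
        assert spatial_threshold(np.array([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]])) == pytest.approx(0.2)

    def test_constant_map(self):
        assert spatial_threshold(np.full((5, 5), 0.42)) == pytest.approx(0.42)

    def test_fractional_position_interpolates(self):
        # n=4: Q1 position 1.25 -> 0.75*0.1 + 0.25*0.2
        assert spatial_threshold(np.array([[0.1, 0.2], [0.3, 0.4]])) == pytest.approx(0.125)

    def test_alternative_quantile_moves_cut(self):
        sw = np.array([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]])
        # third-quartile position of 7 values is 6 -> value 0.6
        assert spatial_threshold(sw, quantile=0.75) == pytest.approx(0.6)
        assert list(select_filter_channels(sw.ravel(), quantile=0.75)) == [0, 1, 2, 3, 4, 5]


class TestCoreMask:
    def test_everything_above(self):
        sw = np.array([[0.5, 0.6], [0.7, 0.8]])
        assert make_core_mask(sw, 0.1).tolist() == [[1, 1], [1, 1]]

    def test_nothing_reaches_threshold(self):
        sw = np.array([[0.5, 0.6]])
        assert make_core_mask(sw, sw.max() + 1e-9).tolist() == [[0, 0]]

    def test_threshold_is_inclusive(self):
        sw = np.array([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]])
        assert make_core_mask(sw, 0.2).tolist() == [[0, 1, 1, 1, 1, 1, 1]]

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_q1_threshold_retains_at_least_three_quarters(self, seed):
        rng = np.random.default_rng(seed)
        sw = rng.permutation(np.linspace(0.01, 0.99, 64)).reshape(8, 8)
        mask = make_core_mask(sw, spatial_threshold(sw))
        assert mask.mean() >= 0.75


class TestApplyRegionMask:
    def test_empty_channel_set_is_identity(self):
        fmap = np.arange(24, dtype=float).reshape(2, 3, 4)
        out = apply_region_mask(fmap, np.ones((3, 4)), np.array([], dtype=int))
        assert np.array_equal(out, fmap)

    def test_all_ones_mask_is_identity(self):
        fmap = np.arange(24, dtype=float).reshape(2, 3, 4)
        out = apply_region_mask(fmap, np.ones((3, 4)), np.array([0, 1]))
        assert np.array_equal(out, fmap)

    def test_checkerboard_zeroes_only_selected_channel(self):
        fmap = np.ones((2, 4, 4))
        mask = np.indices((4, 4)).sum(axis=0) % 2
        out = apply_region_mask(fmap, mask, np.array([0]))
        assert np.array_equal(out[0], mask.astype(float))
        assert np.array_equal(out[1], np.ones((4, 4)))

    def test_out_of_range_channel_rejected(self):
        with pytest.raises(ValueError):
            apply_region_mask(np.ones((2, 3, 3)), np.ones((3, 3)), np.array([2]))


class TestDropBlockGamma:
    def test_block_size_one_is_plain_dropout_rate(self):
        cfg = DropBlockConfig(keep_prob=0.9, block_size=1)
        assert dropblock_gamma(cfg, 10) == pytest.approx(0.1)

    def test_keep_prob_one_gives_zero(self):
        cfg = DropBlockConfig(keep_prob=1.0, block_size=3)
        assert dropblock_gamma(cfg, 10) == 0.0

    def test_direct_formula(self):
        cfg = DropBlockConfig(keep_prob=0.9, block_size=3)
        assert dropblock_gamma(cfg, 10) == pytest.approx(0.1 / 9 * 100 / 64)

    def test_block_larger_than_feature_rejected(self):
        with pytest.raises(ValueError):
            dropblock_gamma(DropBlockConfig(block_size=8), 4)

    def test_monotone_decreasing_in_keep_prob(self):
        gammas = [
            dropblock_gamma(DropBlockConfig(keep_prob=kp, block_size=3), 12)
            for kp in (0.5, 0.7, 0.9, 0.99)
        ]
        assert all(a > b for a, b in zip(gammas, gammas[1:]))

    def test_empirical_block_rate_matches_gamma(self):
        """At block_size=1 the dropped-unit fraction estimates gamma."""
        cfg = DropBlockConfig(keep_prob=0.9, block_size=1, variant="gamma_stamp")
        rng = np.random.default_rng(11)
        n_units = 0
        n_dropped = 0
        x = np.ones((1, 10, 10))
        for _ in range(100):  # 100 draws x 100 units = 10,000 Bernoulli trials
            out = dropblock_shield(x, cfg, rng)
            n_units += out[0].size
            n_dropped += int((out[0] == 0).sum())
        gamma = dropblock_gamma(cfg, 10)
        rate = n_dropped / n_units
        se = np.sqrt(gamma * (1 - gamma) / n_units)
        assert abs(rate - gamma) <= 3 * se


class TestDropblockShield:
    def test_inference_mode_identity(self):
        cfg = DropBlockConfig(mode="inference")
        x = np.random.default_rng(0).normal(0, 1, (3, 6, 6))
        assert np.array_equal(dropblock_shield(x, cfg, np.random.default_rng(1)), x)

    def test_constant_channel_unchanged(self):
        cfg = DropBlockConfig()
        x = np.full((1, 5, 5), 2.5)
        out = dropblock_shield(x, cfg, np.random.default_rng(2))
        assert np.array_equal(out, x)

    def test_single_spike_survives_alone(self):
        cfg = DropBlockConfig()
        x = np.zeros((1, 5, 5))
        x[0, 2, 3] = 4.0
        out = dropblock_shield(x, cfg, np.random.default_rng(3))
        expected = np.zeros((1, 5, 5))
        expected[0, 2, 3] = 4.0
        assert np.array_equal(out, expected)

    def test_never_increases_magnitude(self):
        rng = np.random.default_rng(4)
        cfg = DropBlockConfig()
        for _ in range(20):
            x = np.abs(rng.normal(0, 1, (4, 7, 7)))
            out = dropblock_shield(x, cfg, rng)
            assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    def test_mask_broadcast_from_max_mean_channel(self):
        cfg = DropBlockConfig(fixed_theta=0.7)
        x = np.zeros((2, 4, 4))
        x[0] = 0.1           # low-mean channel
        x[1, 1, 1] = 10.0    # anchor channel: only its peak survives
        out = dropblock_shield(x, cfg, np.random.default_rng(5))
        assert out[1, 1, 1] == 10.0
        assert np.count_nonzero(out[1]) == 1
        # the same mask is broadcast onto channel 0
        assert np.count_nonzero(out[0]) == 1
        assert out[0, 1, 1] == pytest.approx(0.1)

    def test_per_channel_variant_masks_each_channel_against_own_peak(self):
        cfg = DropBlockConfig(fixed_theta=0.7, broadcast=False)
        x = np.zeros((2, 4, 4))
        x[0, 0, 0] = 1.0   # channel-0 peak elsewhere than channel 1's
        x[1, 2, 2] = 5.0
        out = dropblock_shield(x, cfg, np.random.default_rng(8))
        assert out[0, 0, 0] == 1.0 and np.count_nonzero(out[0]) == 1
        assert out[1, 2, 2] == 5.0 and np.count_nonzero(out[1]) == 1

    def test_all_nonpositive_warns_and_passes_through(self):
        cfg = DropBlockConfig()
        x = np.zeros((1, 3, 3))
        with pytest.warns(UserWarning):
            out = dropblock_shield(x, cfg, np.random.default_rng(6))
        assert np.array_equal(out, x)

    def test_empty_channel_set_identity(self):
        cfg = DropBlockConfig()
        x = np.zeros((0, 3, 3))
        assert dropblock_shield(x, cfg, np.random.default_rng(7)).size == 0


class TestDropBlockConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"keep_prob": 0.0},
            {"keep_prob": 1.5},
            {"block_size": 0},
            {"threshold_range": (0.9, 0.6)},
            {"mode": "test"},
            {"variant": "other"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DropBlockConfig(**kwargs)
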