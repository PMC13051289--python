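import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subtypebench.corpus import SubtypeLabel
from subtypebench.losses import (
    ClassStats,
    DualPassLogits,
    LossConfig,
    class_balanced_weights,
    focal_ldam_loss,
    ldam_margins,
    pairwise_margin_penalty,
    rdrop_loss,
    softmax,
    total_loss,
    total_loss_and_grads,
)

UNIT_STATS = ClassStats(
    counts=np.ones(6, dtype=int), weights=np.ones(6), margins=np.zeros(6)
)


class TestClassBalancedWeights:
    def test_equal_counts_give_unit_weights(self):
        assert np.allclose(class_balanced_weights([70] * 6, 0.999), 1.0)

    def test_two_class_value_against_direct_evaluation(self):
        # high-precision direct evaluation of the two raw terms and their mean
        raw10 = (1 - 0.999) / (1 - 0.999 ** 10)
        raw1000 = (1 - 0.999) / (1 - 0.999 ** 1000)
        mean = (raw10 + raw1000) / 2
        w = class_balanced_weights([10, 1000], 0.999)
        assert np.allclose(w, [raw10 / mean, raw1000 / mean], rtol=1e-12)
        assert np.round(w, 3).tolist() == [1.969, 0.031]

    def test_beta_zero_limit_is_uniform(self):
        assert np.allclose(class_balanced_weights([3, 1000, 5, 77, 2, 9], 0.0), 1.0)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            class_balanced_weights([0, 1, 1, 1, 1, 1], 0.999)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(min_value=1, max_value=50000), min_size=6, max_size=6),
        beta=st.floats(min_value=0.0, max_value=0.99999),
    )
    def test_mean_is_one_for_any_valid_input(self, counts, beta):
        assert abs(class_balanced_weights(counts, beta).mean() - 1.0) < 1e-9


class TestLdamMargins:
    @pytest.mark.parametrize(
        "n, expected", [(16, 0.25), (625, 0.10), (1, 0.5)]
    )
    def test_closed_forms(self, n, expected):
        assert ldam_margins([n] * 6, 0.5)[0] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(
            st.integers(min_value=1, max_value=10000), min_size=6, max_size=6, unique=True
        )
    )
    def test_rarer_classes_get_strictly_larger_margins(self, counts):
        margins = ldam_margins(counts)
        order = np.argsort(counts)
        assert np.all(np.diff(margins[order]) < 0)
        assert np.all(margins > 0)


class TestFocalLdam:
    def test_confident_correct_prediction_has_negligible_loss(self):
        z = np.array([50.0, 0, 0, 0, 0, 0])
        stats = ClassStats(np.ones(6, int), np.ones(6), np.full(6, 1.0))
        loss = focal_ldam_loss(z, SubtypeLabel.POSTPARTUM, stats, LossConfig())
        assert 0 <= loss < 1e-15

    def test_two_class_uniform_reduces_to_ln2_at_gamma_zero(self):
        z = np.array([0.0, 0.0, -1e9, -1e9, -1e9, -1e9])
        loss = focal_ldam_loss(z, SubtypeLabel.POSTPARTUM, UNIT_STATS, LossConfig(gamma=0.0))
        assert loss == pytest.approx(math.log(2), rel=1e-12)

    def test_two_class_uniform_gamma_two_quarters_the_loss(self):
        z = np.array([0.0, 0.0, -1e9, -1e9, -1e9, -1e9])
        loss = focal_ldam_loss(z, SubtypeLabel.POSTPARTUM, UNIT_STATS, LossConfig(gamma=2.0))
        assert loss == pytest.approx(0.25 * math.log(2), rel=1e-12)

    def test_margin_shift_against_explicit_softmax_oracle(self):
        # z = 0 everywhere, margin 0.15 on the true class: the loss must match
        # a brute-force evaluation of softmax([-0.15, 0, 0, 0, 0, 0])
        stats = ClassStats(np.ones(6, int), np.ones(6), np.full(6, 0.15))
        loss = focal_ldam_loss(
            np.zeros(6), SubtypeLabel.POSTPARTUM, stats, LossConfig(gamma=2.0)
        )
        shifted = np.array([-0.15, 0, 0, 0, 0, 0])
        p = np.exp(shifted) / np.exp(shifted).sum()
        expected = (1 - p[0]) ** 2 * (-math.log(p[0]))
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_gamma_zero_unit_weights_reduce_to_cross_entropy(self):
        # independent CE oracle on 100 random logit vectors
        rng = np.random.default_rng(42)
        config = LossConfig(gamma=0.0)
        for _ in range(100):
            z = rng.standard_normal(6) * 3
            label = SubtypeLabel(list(SubtypeLabel)[rng.integers(6)])
            loss = focal_ldam_loss(z, label, UNIT_STATS, config)
            ce = -np.log(softmax(z)[label.index])
            assert loss == pytest.approx(float(ce), rel=1e-10)

    def test_minority_class_contributes_more_at_identical_logits(self):
        stats = ClassStats.from_counts([1000, 10, 1000, 1000, 1000, 1000])
        z = np.zeros(6)
        config = LossConfig()
        minority = focal_ldam_loss(z, SubtypeLabel.MAJOR, stats, config)
        majority = focal_ldam_loss(z, SubtypeLabel.POSTPARTUM, stats, config)
        assert minority > majority

    def test_stable_for_extreme_logits(self):
        z = np.array([-1e4, 1e4, 0, 0, 0, 0])
        loss = focal_ldam_loss(z, SubtypeLabel.POSTPARTUM, UNIT_STATS, LossConfig())
        assert np.isfinite(loss) and loss > 0


class TestRDrop:
    def test_identical_distributions_give_zero(self):
        p = softmax(np.array([1.0, 2, 3, 4, 5, 6]))
        assert rdrop_loss(p, p) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(min_value=-4, max_value=4), min_size=6, max_size=6),
        b=st.lists(st.floats(min_value=-4, max_value=4), min_size=6, max_size=6),
    )
    def test_symmetry_and_non_negativity(self, a, b):
        p1, p2 = softmax(np.array(a)), softmax(np.array(b))
        v = rdrop_loss(p1, p2)
        assert v == pytest.approx(rdrop_loss(p2, p1), rel=1e-12)
        assert v >= 0

    def test_value_against_term_by_term_oracle(self):
        p1 = np.array([0.9, 0.1, 0, 0, 0, 0])
        p2 = np.array([0.5, 0.5, 0, 0, 0, 0])
        c1, c2 = np.clip(p1, 1e-12, None), np.clip(p2, 1e-12, None)
        kl12 = sum(a * math.log(a / b) for a, b in zip(c1, c2))
        kl21 = sum(b * math.log(b / a) for a, b in zip(c1, c2))
        expected = 0.5 * (kl12 + kl21)
        assert rdrop_loss(p1, p2) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.439, abs=5e-4)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            rdrop_loss(np.full(6, 0.3), np.full(6, 1 / 6))


class TestPairwisePenalty:
    def test_scoped_to_bipolar_only(self):
        rng = np.random.default_rng(1)
        for label in SubtypeLabel:
            if label is SubtypeLabel.BIPOLAR:
                continue
            assert pairwise_margin_penalty(rng.standard_normal(6), label) == 0.0

    def test_satisfied_margins_give_zero(self):
        z = np.zeros(6)
        z[SubtypeLabel.BIPOLAR.index] = 1.0
        assert pairwise_margin_penalty(z, SubtypeLabel.BIPOLAR, 0.15) == 0.0

    def test_all_zero_logits_give_two_delta(self):
        assert pairwise_margin_penalty(
            np.zeros(6), SubtypeLabel.BIPOLAR, 0.15
        ) == pytest.approx(0.30, rel=1e-12)


class TestTotalLoss:
    @pytest.fixture()
    def batch(self):
        rng = np.random.default_rng(7)
        labels = [
            SubtypeLabel.BIPOLAR,
            SubtypeLabel.MAJOR,
            SubtypeLabel.NO_DEPRESSION,
            SubtypeLabel.ATYPICAL,
        ]
        return [
            DualPassLogits(rng.standard_normal(6), rng.standard_normal(6), label)
            for label in labels
        ]

    @pytest.fixture()
    def stats(self):
        return ClassStats.from_counts([120, 80, 79, 74, 64, 63])

    def test_degenerate_config_equals_mean_focal(self, batch, stats):
        config = LossConfig(lambda_rdrop=0.0, lambda_pair=0.0)
        tied = [DualPassLogits(ex.z1, ex.z1, ex.label) for ex in batch]
        expected = np.mean(
            [focal_ldam_loss(ex.z1, ex.label, stats, config) for ex in batch]
        )
        assert total_loss(tied, stats, config) == pytest.approx(expected, rel=1e-12)

    def test_additivity_against_component_recomputation(self, batch, stats):
        config = LossConfig()
        expected = np.mean(
            [
                0.5
                * (
                    focal_ldam_loss(ex.z1, ex.label, stats, config)
                    + focal_ldam_loss(ex.z2, ex.label, stats, config)
                )
                + config.lambda_rdrop * rdrop_loss(softmax(ex.z1), softmax(ex.z2))
                + config.lambda_pair
                * 0.5
                * (
                    pairwise_margin_penalty(ex.z1, ex.label, config.delta)
                    + pairwise_margin_penalty(ex.z2, ex.label, config.delta)
                )
                for ex in batch
            ]
        )
        assert total_loss(batch, stats, config) == pytest.approx(expected, abs=1e-9)

    def test_single_non_bipolar_tied_passes_reduce_to_focal(self, stats):
        z = np.array([0.5, -0.2, 0.1, 0.0, 0.3, -0.1])
        batch = [DualPassLogits(z, z, SubtypeLabel.MAJOR)]
        config = LossConfig()
        assert total_loss(batch, stats, config) == pytest.approx(
            focal_ldam_loss(z, SubtypeLabel.MAJOR, stats, config), rel=1e-12
        )

    def test_non_negative(self, batch, stats):
        assert total_loss(batch, stats, LossConfig()) >= 0

    def test_empty_batch_rejected(self, stats):
        with pytest.raises(ValueError, match="non-empty"):
            total_loss([], stats, LossConfig())

    def test_analytic_gradients_match_finite_differences(self, batch, stats):
        config = LossConfig()
        loss, g1, g2 = total_loss_and_grads(batch, stats, config)
        eps = 1e-6
        for i, ex in enumerate(batch):
            for grad, z in ((g1, ex.z1), (g2, ex.z2)):
                for k in range(6):
                    z[k] += eps
                    up = total_loss(batch, stats, config)
                    z[k] -= 2 * eps
                    down = total_loss(batch, stats, config)
                    z[k] += eps
                    fd = (up - down) / (2 * eps)
                    assert grad[i, k] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestLossConfig:
    def test_round_trips_through_dict(self):
        config = LossConfig(beta=0.99, gamma=1.5)
        assert LossConfig.from_dict(config.to_dict()) == config

    def test_defaults_are_study_values(self):
        config = LossConfig()
        assert (
            config.beta,
            config.gamma,
            config.c0,
            config.delta,
            config.lambda_rdrop,
            config.lambda_pair,
        ) == (0.999, 2.0, 0.5, 0.15, 0.5, 0.15)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(beta=1.0)
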