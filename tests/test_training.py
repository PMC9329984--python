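import numpy as np
import pytest

from smearopt.architecture import ArchitectureConfig, build_architecture
from smearopt.training import (
    DivergenceError,
    TrainingConfig,
    evaluate_objective,
    lr_schedule,
    regularized_loss,
    sgdm_step,
    train_network,
)


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(1, 0.01), (40, 0.01), (41, 0.001), (80, 0.001), (81, 1e-4),
         (121, 1e-5), (150, 1e-5)],
    )
    def test_piecewise_drop_every_40_epochs(self, epoch, expected):
        cfg = TrainingConfig(initial_learning_rate=0.01)
        assert lr_schedule(epoch, cfg) == pytest.approx(expected, rel=1e-12)

    def test_exactly_four_distinct_rates_over_150_epochs(self):
        cfg = TrainingConfig(initial_learning_rate=0.3)
        rates = sorted({lr_schedule(e, cfg) for e in range(1, 151)})
        sigma = 0.3
        assert rates == pytest.approx(
            [0.001 * sigma, 0.01 * sigma, 0.1 * sigma, sigma]
        )

    def test_epoch_below_one_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(0, TrainingConfig())


class TestUpdateRule:
    def test_zero_momentum_is_plain_gradient_descent(self):
        out = sgdm_step([1.0], [2.0], [1.0], lr=0.1, momentum=0.0)
        assert out[0] == pytest.approx(0.8)

    def test_two_hand_iterations_on_quadratic(self):
        # L(b) = b^2, grad = 2b, sigma=0.1, M=0.5, b0 = b_{-1} = 1
        b_prev, b = 1.0, 1.0
        b1 = sgdm_step([b], [2 * b], [b_prev], lr=0.1, momentum=0.5)[0]
        assert b1 == pytest.approx(0.8)
        b2 = sgdm_step([b1], [2 * b1], [b], lr=0.1, momentum=0.5)[0]
        assert b2 == pytest.approx(0.54)

    def test_pure_momentum_coast(self):
        out = sgdm_step([1.2], [0.0], [1.0], lr=0.1, momentum=0.5)
        assert out[0] == pytest.approx(1.3)

    def test_vanilla_sgd_equality_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            beta = rng.standard_normal(6)
            grad = rng.standard_normal(6)
            prev = rng.standard_normal(6)
            lr = rng.random()
            assert np.array_equal(
                sgdm_step(beta, grad, prev, lr, 0.0), beta - lr * grad
            )

    def test_velocity_form_equals_two_point_form(self):
        """v <- Mv - sigma*grad; beta <- beta + v reproduces the two-point
        update exactly over a whole trajectory."""
        rng = np.random.default_rng(1)
        grads = rng.standard_normal((30, 4))
        lr, M = 0.05, 0.9
        beta_tp_prev = beta_tp = beta_v = rng.standard_normal(4)
        v = np.zeros(4)
        for g in grads:
            new = sgdm_step(beta_tp, g, beta_tp_prev, lr, M)
            beta_tp_prev, beta_tp = beta_tp, new
            v = M * v - lr * g
            beta_v = beta_v + v
            assert np.allclose(beta_tp, beta_v, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sgdm_step([1.0, 2.0], [1.0], [1.0, 2.0], 0.1, 0.5)


class TestRegularizedLoss:
    def test_zero_coefficient_leaves_loss(self):
        assert regularized_loss(0.7, [3.0, 4.0], 0.0) == 0.7

    def test_hand_example(self):
        assert regularized_loss(0.5, [1.0, 2.0], 0.1) == pytest.approx(0.75)

    def test_zero_weights(self):
        assert regularized_loss(0.33, np.zeros(10), 5.0) == pytest.approx(0.33)


class TestTrainNetwork:
    def test_learns_separable_data(self, separable_images):
        train, val = separable_images
        plan = build_architecture(
            ArchitectureConfig(cbd=1, base_filters=8, input_height=16,
                               input_width=16)
        )
        cfg = TrainingConfig(initial_learning_rate=0.05, momentum=0.9,
                             regularization=1e-6, batch_size=32,
                             max_epochs=10, seed=0)
        model, history = train_network(plan, train, val, cfg)
        assert history.train_accuracy[-1] >= 0.95
        assert evaluate_objective(model, val) <= 0.1

    def test_identical_seed_identical_history(self, separable_images):
        train, val = separable_images
        plan = build_architecture(
            ArchitectureConfig(cbd=1, base_filters=4, input_height=16,
                               input_width=16)
        )
        cfg = TrainingConfig(initial_learning_rate=0.02, momentum=0.85,
                             batch_size=32, max_epochs=3, seed=5)
        _, h1 = train_network(plan, train, val, cfg)
        _, h2 = train_network(plan, train, val, cfg)
        assert h1 == h2

    def test_objective_is_one_minus_accuracy(self, separable_images):
        train, val = separable_images

        class Stub:
            def __init__(self, preds):
                self.preds = np.asarray(preds)

            def predict(self, X):
                return self.preds

        y = val[1]
        assert evaluate_objective(Stub(y), val) == 0.0
        assert evaluate_objective(Stub(1 - y), val) == 1.0
        off = y.copy()
        off[:3] = 1 - off[:3]
        assert evaluate_objective(Stub(off), val) == pytest.approx(3 / len(y))

    def test_empty_partition_rejected(self, separable_images):
        train, _ = separable_images
        plan = build_architecture(
            ArchitectureConfig(cbd=1, input_height=16, input_width=16)
        )
        empty = (np.empty((0, 3, 16, 16)), np.empty(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            train_network(plan, train, empty, TrainingConfig())
        with pytest.raises(ValueError, match="empty"):
            evaluate_objective(None, empty)

    def test_huge_learning_rate_never_silently_propagates_nan(self, separable_images):
        train, val = separable_images
        plan = build_architecture(
            ArchitectureConfig(cbd=1, base_filters=8, input_height=16,
                               input_width=16)
        )
        cfg = TrainingConfig(initial_learning_rate=1e4, momentum=0.99,
                             batch_size=32, max_epochs=5, seed=0)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                _, history = train_network(plan, train, val, cfg)
        except DivergenceError as err:
            assert 1 <= err.epoch <= 5
        else:
            assert np.all(np.isfinite(history.train_loss))
            assert np.all(np.isfinite(history.val_loss))

    def test_history_csv_export(self, tmp_path, separable_images):
        import pandas as pd

        train, val = separable_images
        plan = build_architecture(
            ArchitectureConfig(cbd=1, base_filters=4, input_height=16,
                               input_width=16)
        )
        cfg = TrainingConfig(initial_learning_rate=0.02, batch_size=32,
                             max_epochs=2, seed=0)
        _, history = train_network(plan, train, val, cfg)
        history.to_csv(tmp_path / "h.csv")
        df = pd.read_csv(tmp_path / "h.csv")
        assert list(df.columns) == [
            "epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc"
        ]
        assert len(df) == 2


class TestLearnabilityAtDeskScale:
    def test_cbd2_reaches_high_validation_accuracy_across_seeds(self, desk_data):
        """On clearly separated synthetic smears, a depth-2-per-block network
        trained 30 epochs should classify the validation set almost
        perfectly for nearly every initialization."""
        Xtr, ytr = desk_data["train"]
        Xval, yval = desk_data["val"]
        # a balanced 100-image subsample keeps the check quick
        sub = np.random.default_rng(0).permutation(len(ytr))[:100]
        plan = build_architecture(
            ArchitectureConfig(cbd=2, input_height=32, input_width=32)
        )
        successes = 0
        for seed in range(10):
            cfg = TrainingConfig(initial_learning_rate=0.05, momentum=0.9,
                                 regularization=1e-6, batch_size=128,
                                 max_epochs=30, seed=seed)
            model, _ = train_network(plan, (Xtr[sub], ytr[sub]),
                                     (Xval, yval), cfg)
            if 1 - evaluate_objective(model, (Xval, yval)) >= 0.95:
                successes += 1
        assert successes >= 9
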