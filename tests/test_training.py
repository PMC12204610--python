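import numpy as np
import pytest

from primenet import autodiff as ad
from primenet.autodiff import Tensor
from primenet.network import PrimeNet
from primenet.training import (Adam, Lookahead, SplitSpec, TrainConfig,
                               merge_and_shuffle, orthogonal_init, split_dataset,
                               train, tune_hyperparameters)
from tests.conftest import SMALL_CONFIG


class TestOrthogonalInit:
    def test_weights_orthogonal_biases_zero(self, small_model):
        orthogonal_init(small_model, seed=5)
        for name, t in small_model.params.items():
            if name.endswith(".b"):
                assert np.all(t.data == 0.0), name
                continue
            w = t.data.reshape(t.data.shape[0], -1).astype(np.float64)
            rows, cols = w.shape
            gram = w.T @ w if rows >= cols else w @ w.T
            dev = np.abs(gram - np.eye(gram.shape[0])).max()
            assert dev < 1e-5, f"{name}: max|WtW - I| = {dev:.2e}"

    def test_tall_matrix_column_orthogonality(self):
        rng_model = PrimeNet(SMALL_CONFIG, seed=0)
        orthogonal_init(rng_model, seed=1)
        w = rng_model.params["trunk0.W"].data  # (in, out) with in > out here?
        m = w.reshape(w.shape[0], -1).astype(np.float64)
        rows, cols = m.shape
        gram = m.T @ m if rows >= cols else m @ m.T
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-5

    def test_square_weight_determinant_unit(self):
        # build a square weight by hand through the same code path
        model = PrimeNet(SMALL_CONFIG, seed=0)
        model.params["sq.W"] = Tensor(np.zeros((16, 16), dtype="f4"),
                                      requires_grad=True)
        orthogonal_init(model, seed=2)
        det = abs(np.linalg.det(model.params["sq.W"].data.astype(np.float64)))
        assert abs(det - 1.0) < 1e-4
        del model.params["sq.W"]

    def test_deterministic_given_seed(self):
        m1 = orthogonal_init(PrimeNet(SMALL_CONFIG, seed=0), seed=3)
        m2 = orthogonal_init(PrimeNet(SMALL_CONFIG, seed=9), seed=3)
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data)


class _SGD:
    """Plain gradient-descent inner rule for the Lookahead oracle tests."""

    def __init__(self, params, lr):
        self.params, self.lr = params, lr

    def step(self):
        for p in self.params.values():
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad


def _quadratic_grad(theta):
    return 2.0 * theta  # d/dtheta theta^2


class TestLookahead:
    def test_worked_scalar_quadratic(self):
        """theta0=1, loss theta^2, SGD lr 0.1, k=2, alpha=0.5:
        theta1=0.8, theta2=0.64, phi1 = 1 + 0.5*(0.64-1) = 0.82."""
        p = {"w": Tensor(np.array([1.0]), requires_grad=True)}
        la = Lookahead(p, _SGD(p, 0.1), k=2, alpha=0.5)
        inner_values = []
        for _ in range(2):
            p["w"].grad = _quadratic_grad(p["w"].data)
            la.step()
            inner_values.append(float(p["w"].data[0]))
        assert inner_values[0] == pytest.approx(0.8, abs=1e-12)
        # after the 2nd inner step the outer update fires and resets theta
        assert float(p["w"].data[0]) == pytest.approx(0.82, abs=1e-12)
        assert la.outer_iteration == 1

    def test_alpha_one_reduces_to_inner_optimizer(self):
        rng = np.random.default_rng(0)
        w0 = rng.standard_normal(5).astype("f4")
        grads = [rng.standard_normal(5).astype("f4") for _ in range(6)]
        pa = {"w": Tensor(w0.copy(), requires_grad=True)}
        pb = {"w": Tensor(w0.copy(), requires_grad=True)}
        la = Lookahead(pa, _SGD(pa, 0.05), k=3, alpha=1.0)
        sgd = _SGD(pb, 0.05)
        for g in grads:
            pa["w"].grad = g.copy()
            pb["w"].grad = g.copy()
            la.step()
            sgd.step()
        assert np.allclose(pa["w"].data, pb["w"].data, atol=1e-6)

    def test_alpha_to_zero_limit_keeps_slow_weights(self):
        p = {"w": Tensor(np.array([1.0], dtype="f4"), requires_grad=True)}
        la = Lookahead(p, _SGD(p, 0.1), k=2, alpha=1e-7)
        for _ in range(2):
            p["w"].grad = _quadratic_grad(p["w"].data)
            la.step()
        assert float(p["w"].data[0]) == pytest.approx(1.0, abs=1e-5)

    def test_matches_hand_stepped_reference_over_random_trials(self):
        """Oracle: directly iterate the two printed update equations."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            k = int(rng.integers(1, 5))
            alpha = float(rng.uniform(0.05, 1.0))
            lr = float(rng.uniform(0.01, 0.3))
            steps = k * int(rng.integers(1, 4))
            w0 = rng.standard_normal(n)
            grads = [rng.standard_normal(n) for _ in range(steps)]

            # reference: explicit slow/fast bookkeeping in float64
            phi = w0.copy()
            theta = w0.copy()
            for i, g in enumerate(grads, start=1):
                theta = theta + (-lr * g)        # theta_i = theta_{i-1} + A(...)
                if i % k == 0:
                    phi = phi + alpha * (theta - phi)
                    theta = phi.copy()           # reset fast to slow

            p = {"w": Tensor(w0.copy(), requires_grad=True)}  # float64
            la = Lookahead(p, _SGD(p, lr), k=k, alpha=alpha)
            for g in grads:
                p["w"].grad = g.copy()
                la.step()
            assert np.abs(la.slow["w"] - phi).max() < 1e-10
            assert np.abs(p["w"].data - phi).max() < 1e-10

    def test_invalid_settings_rejected(self):
        p = {"w": Tensor(np.zeros(1, dtype="f4"), requires_grad=True)}
        with pytest.raises(ValueError):
            Lookahead(p, _SGD(p, 0.1), k=0)
        with pytest.raises(ValueError):
            Lookahead(p, _SGD(p, 0.1), alpha=0.0)


class TestSplit:
    def test_8_1_1_counts(self):
        tr, va, te = split_dataset(list(range(1000)), SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (800, 100, 100)

    def test_partition_is_disjoint_and_exhaustive(self):
        items = list(range(137))
        tr, va, te = split_dataset(items, SplitSpec(seed=4))
        assert sorted(tr + va + te) == items
        assert not (set(tr) & set(va)) and not (set(va) & set(te))

    def test_seed_determinism(self):
        a = split_dataset(list(range(50)), SplitSpec(seed=9))
        b = split_dataset(list(range(50)), SplitSpec(seed=9))
        assert a == b

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(5)))

    def test_merge_and_shuffle_conserves_multiset(self):
        a, b = list(range(100)), list(range(100, 150))
        merged = merge_and_shuffle([a, b], seed=1)
        assert len(merged) == 150
        assert sorted(merged) == sorted(a + b)
        assert merge_and_shuffle([a, b], seed=1) == merged
        assert merge_and_shuffle([a, b], seed=2) != merged


@pytest.fixture(scope="module")
def encoded_smoke(smoke_dataset):
    from primenet.workflows import encode_records

    records, dnase, methyl, _ = smoke_dataset
    X, y, _, _ = encode_records(records, dnase, methyl)
    return X, y


class TestTrainLoop:
    def test_loss_decreases_on_planted_signal(self, encoded_smoke):
        X, y = encoded_smoke
        model = PrimeNet(SMALL_CONFIG, seed=0)
        cfg = TrainConfig(max_epochs=5, seed=0, batch_size=64)
        _, history = train(model, (X[:240], y[:240]), (X[240:], y[240:]), cfg)
        losses = [h["train_loss"] for h in history]
        assert losses[-1] < losses[0]
        assert len(history) <= cfg.max_epochs

    def test_lookahead_k1_alpha1_equals_plain_adam(self, encoded_smoke):
        X, y = encoded_smoke
        preds = []
        for enabled in (True, False):
            model = PrimeNet(SMALL_CONFIG, seed=0)
            cfg = TrainConfig(max_epochs=2, seed=0, batch_size=64,
                              lookahead_enabled=enabled, lookahead_k=1,
                              lookahead_alpha=1.0, early_stop_patience=99)
            model, _ = train(model, (X[:240], y[:240]), (X[240:], y[240:]), cfg)
            preds.append(model.predict(X[:8]))
        assert np.allclose(preds[0], preds[1], atol=1e-5)

    def test_run_to_run_determinism(self, encoded_smoke):
        X, y = encoded_smoke
        preds = []
        for _ in range(2):
            model = PrimeNet(SMALL_CONFIG, seed=0)
            cfg = TrainConfig(max_epochs=2, seed=0, batch_size=64)
            model, _ = train(model, (X[:240], y[:240]), (X[240:], y[240:]), cfg)
            preds.append(model.predict(X[:8]))
        assert np.array_equal(preds[0], preds[1])


class TestTuning:
    def test_trials_logged_and_best_is_max(self, smoke_dataset):
        from primenet.workflows import encode_records

        records, dnase, methyl, _ = smoke_dataset
        X, y, _, _ = encode_records(records, dnase, methyl)
        space = {
            "learning_rate": (1e-4, 1e-2),
            "conv_attention_enabled": [True, False],
        }
        data = ((X[:200], y[:200]), (X[200:260], y[200:260]))
        best, trials = tune_hyperparameters(
            space, n_trials=3, seed=1, data=data,
            train_config=TrainConfig(max_epochs=1, seed=0, batch_size=64),
        )
        assert len(trials) == 3
        best_score = max(t["score"] for t in trials)
        assert any(t["params"] == best and t["score"] == best_score for t in trials)
        # coverage of the boolean flag across trials is possible but not
        # guaranteed at 3 trials; check the sampler explored the space at all
        assert len({t["params"]["learning_rate"] for t in trials}) == 3

    def test_reproducible_under_seed(self, smoke_dataset):
        from primenet.workflows import encode_records

        records, dnase, methyl, _ = smoke_dataset
        X, y, _, _ = encode_records(records, dnase, methyl)
        data = ((X[:100], y[:100]), (X[100:140], y[100:140]))
        kwargs = dict(space={"learning_rate": (1e-4, 1e-2)}, n_trials=2, seed=3,
                      data=data,
                      train_config=TrainConfig(max_epochs=1, seed=0, batch_size=64))
        _, t1 = tune_hyperparameters(**kwargs)
        _, t2 = tune_hyperparameters(**kwargs)
        assert [t["params"] for t in t1] == [t["params"] for t in t2]
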