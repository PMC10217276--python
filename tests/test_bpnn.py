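import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visbrix import bpnn as bp


class TestHiddenSize:
    def test_reproduces_published_topology(self):
        # 35 inputs, 3 outputs: admissible h over a in [1,10] is 7..16
        sizes = {bp.hidden_size(35, 3, a) for a in range(1, 11)}
        assert sizes == set(range(7, 17))
        assert bp.hidden_size(35, 3, 8) == 14  # the selected classification net
        assert bp.hidden_size(35, 1, 4) == 10  # the selected regression net

    def test_small_example(self):
        assert bp.hidden_size(2, 2, 1) == 3

    def test_a_out_of_range(self):
        with pytest.raises(ValueError):
            bp.hidden_size(35, 3, 11)
        with pytest.raises(ValueError):
            bp.hidden_size(35, 3, 0)


class TestSchedules:
    def test_closed_forms(self):
        eta0, T = 0.4, 1000
        gaus = bp.LRSchedule("gaussian", eta0=eta0, T=T)
        cosn = bp.LRSchedule("cosine", eta0=eta0, T=T)
        expo = bp.LRSchedule("exponential", eta0=eta0, T=T, p=1.0)
        sigm = bp.LRSchedule("sigmoid", eta0=eta0, T=T)
        assert bp.lr_at(gaus, 0) == pytest.approx(eta0, abs=1e-15)
        assert bp.lr_at(cosn, T) == pytest.approx(0.0, abs=1e-15)
        assert bp.lr_at(cosn, T / 2) == pytest.approx(0.5 * eta0, abs=1e-12)
        assert bp.lr_at(expo, T / 2) == pytest.approx(0.5 * eta0, abs=1e-12)
        assert bp.lr_at(expo, T) == pytest.approx(0.0, abs=1e-15)
        assert bp.lr_at(sigm, T / 2) == pytest.approx(0.5 * eta0, abs=1e-12)

    @pytest.mark.parametrize("kind", bp.SCHEDULE_KINDS)
    def test_non_increasing_over_horizon(self, kind):
        s = bp.LRSchedule(kind, eta0=0.3, T=500)
        rates = [bp.lr_at(s, t) for t in range(0, 501, 10)]
        assert all(b <= a + 1e-15 for a, b in zip(rates, rates[1:]))

    def test_t_outside_horizon_rejected(self):
        s = bp.LRSchedule("fixed", eta0=0.1, T=10)
        for t in (-1, 11):
            with pytest.raises(ValueError):
                bp.lr_at(s, t)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            bp.LRSchedule("linear")

    @given(st.floats(min_value=0.01, max_value=1.0), st.integers(min_value=2, max_value=5000))
    @settings(max_examples=50, deadline=None)
    def test_gaussian_starts_at_eta0_and_decays(self, eta0, T):
        s = bp.LRSchedule("gaussian", eta0=eta0, T=T)
        assert bp.lr_at(s, 0) == pytest.approx(eta0)
        assert bp.lr_at(s, T) <= bp.lr_at(s, T // 2) <= eta0


class TestInitForward:
    def test_init_deterministic_and_shapes(self):
        a = bp.init_bpnn(2, 3, 1, seed=42)
        b = bp.init_bpnn(2, 3, 1, seed=42)
        np.testing.assert_array_equal(a.hidden_weights, b.hidden_weights)
        assert a.hidden_weights.shape == (2, 3)
        assert a.output_weights.shape == (3, 1)
        assert np.all(np.abs(a.hidden_weights) <= 0.5)
        assert np.all(a.hidden_thresholds == 0)

    def test_different_seeds_differ(self):
        a = bp.init_bpnn(4, 5, 2, seed=1)
        b = bp.init_bpnn(4, 5, 2, seed=2)
        assert not np.array_equal(a.hidden_weights, b.hidden_weights)

    def test_zero_weights_sigmoid_gives_half(self):
        m = bp.init_bpnn(3, 4, 2, "sigmoid", seed=0)
        m.hidden_weights[:] = 0
        m.output_weights[:] = 0
        np.testing.assert_allclose(bp.forward(m, np.ones((5, 3))), 0.5, atol=1e-15)

    def test_zero_weights_linear_gives_zero(self):
        m = bp.init_bpnn(3, 4, 1, "linear", seed=0)
        m.hidden_weights[:] = 0
        m.output_weights[:] = 0
        np.testing.assert_allclose(bp.forward(m, np.ones((5, 3))), 0.0, atol=1e-15)

    def test_width_mismatch(self):
        m = bp.init_bpnn(3, 4, 1, seed=0)
        with pytest.raises(ValueError):
            bp.forward(m, np.ones((2, 5)))


def _numerical_gradient(model, x, t, eps=1e-6):
    """Central-difference oracle over every parameter."""
    grads = []
    for arr in (
        model.hidden_weights,
        model.hidden_thresholds,
        model.output_weights,
        model.output_thresholds,
    ):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            up = bp.sse_loss(model, x, t)
            arr[idx] = orig - eps
            down = bp.sse_loss(model, x, t)
            arr[idx] = orig
            g[idx] = (up - down) / (2 * eps)
        grads.append(g)
    return grads


class TestGradients:
    @pytest.mark.parametrize("activation", ["sigmoid", "linear"])
    def test_backprop_matches_central_differences(self, activation, rng):
        for seed in range(10):
            model = bp.init_bpnn(3, 4, 2, activation, seed=seed)
            x = rng.normal(size=(6, 3))
            t = rng.uniform(0, 1, size=(6, 2))
            analytic = bp.gradients(model, x, t)
            numeric = _numerical_gradient(model, x, t)
            for a, n in zip(analytic, numeric):
                np.testing.assert_allclose(a, n, rtol=1e-6, atol=1e-8)


class TestTrainGD:
    def test_zero_rate_leaves_model_unchanged(self, rng):
        model = bp.init_bpnn(2, 3, 1, seed=0)
        x, t = rng.normal(size=(5, 2)), rng.uniform(size=(5, 1))
        out, _ = bp.train_gd(model, x, t, bp.LRSchedule("fixed", eta0=0.0, T=10), epochs=10)
        np.testing.assert_array_equal(out.hidden_weights, model.hidden_weights)

    def test_separable_toy_reaches_full_accuracy(self):
        """Linearly separable 2-class toy with margin >= 1 trains to 100%."""
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal([-2, -2], 0.3, (20, 2)), rng.normal([2, 2], 0.3, (20, 2))])
        grades = np.array([1] * 20 + [2] * 20)
        t = np.zeros((40, 2))
        t[np.arange(40), grades - 1] = 1
        model = bp.init_bpnn(2, 4, 2, "sigmoid", seed=1)
        trained, trace = bp.train_gd(
            model, x, t, bp.LRSchedule("fixed", eta0=0.05, T=2000), epochs=2000
        )
        pred = np.argmax(bp.forward(trained, x), axis=1) + 1
        assert np.mean(pred == grades) == 1.0
        assert trace.mse[-1] < trace.mse[0]

    def test_trace_lengths_and_rates(self, rng):
        model = bp.init_bpnn(2, 3, 1, "linear", seed=0)
        sched = bp.LRSchedule("gaussian", eta0=0.001, T=50)
        _, trace = bp.train_gd(model, rng.normal(size=(4, 2)), rng.normal(size=(4, 1)), sched, epochs=50)
        assert trace.epochs == 50
        np.testing.assert_allclose(
            trace.learning_rate, [bp.lr_at(sched, e) for e in range(1, 51)]
        )

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_reported_with_epoch(self, rng):
        model = bp.init_bpnn(2, 3, 1, "linear", seed=0)
        x = rng.normal(size=(30, 2)) * 10
        y = rng.normal(size=(30, 1)) * 10
        with pytest.raises(bp.DivergenceError, match="epoch"):
            bp.train_gd(model, x, y, bp.LRSchedule("fixed", eta0=5.0, T=500), epochs=500)


class TestPredictGrade:
    def test_argmax_and_tie_rule(self):
        model = bp.init_bpnn(1, 2, 3, "sigmoid", seed=0)
        # craft outputs by monkeypatching forward via thresholds on zero weights
        model.hidden_weights[:] = 0
        model.output_weights[:] = 0
        model.output_thresholds[:] = [0.9, 0.3, 0.1]
        assert bp.predict_grade(model, np.zeros((1, 1)))[0] == 1
        model.output_thresholds[:] = [0.5, 0.5, 0.1]
        assert bp.predict_grade(model, np.zeros((1, 1)))[0] == 1  # tie -> lower grade

    def test_batch_equals_per_row(self, rng):
        model = bp.init_bpnn(4, 5, 3, "sigmoid", seed=3)
        x = rng.normal(size=(7, 4))
        batch = bp.predict_grade(model, x)
        single = [bp.predict_grade(model, row[None, :])[0] for row in x]
        assert list(batch) == single

    def test_regression_model_rejected(self):
        model = bp.init_bpnn(2, 3, 1, "linear", seed=0)
        with pytest.raises(ValueError):
            bp.predict_grade(model, np.zeros((1, 2)))


def test_one_hot_round_trip():
    g = np.array([1, 3, 2, 2, 1])
    oh = bp.one_hot(g)
    assert oh.shape == (5, 3)
    np.testing.assert_array_equal(np.argmax(oh, axis=1) + 1, g)
    with pytest.raises(ValueError):
        bp.one_hot(np.array([0, 1]))


def test_standardizer_round_trip(rng):
    x = rng.normal(5, 3, size=(20, 4))
    s = bp.Standardizer().fit(x)
    z = s.transform(x)
    np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)
    np.testing.assert_allclose(s.inverse(z), x, atol=1e-12)
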