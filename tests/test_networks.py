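"""Network engine: shapes, gradients, losses, training, inference."""

import numpy as np
import pytest

from t2relax.networks import (
    AdamW,
    NetworkConfig,
    TrainingConfig,
    build_network,
    desk_config,
    extracted_curve_count,
    load_model,
    predict_parameter_map,
    save_model,
    self_supervised_loss,
    supervised_loss,
    train_model,
)
from t2relax.networks.training import _self_supervised_grad
from t2relax.series import ImageSeries
from t2relax.signal_model import SamplingGrid, decay_signal, default_grid
from t2relax.synthetic import DatasetManifest, SyntheticDataset, generate_dataset


def tiny_dataset(style="urand", n=12, side=16, seed=0):
    return generate_dataset(
        DatasetManifest(n_series=n, shape=(side, side), style=style, master_seed=seed)
    )


class TestArchitectures:
    def test_nn1d_maps_vector_to_two_outputs(self):
        model = build_network(desk_config("nn1d"), seed=0)
        out = model(np.zeros((1, 10)))
        assert out.shape == (1, 2)
        assert np.all(np.isfinite(out))

    def test_cnn_output_shape(self):
        model = build_network(desk_config("cnn"), seed=0)
        out = model(np.zeros((1, 10, 32, 32)))
        assert out.shape == (1, 2, 32, 32)

    def test_same_seed_identical_weights(self):
        a = build_network(desk_config("cnn"), seed=3)
        b = build_network(desk_config("cnn"), seed=3)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_channel_mismatch_rejected(self):
        model = build_network(desk_config("cnn"), seed=0)
        with pytest.raises(ValueError):
            model(np.zeros((1, 7, 32, 32)))

    def test_parameter_count_pure_function_of_config(self):
        n = lambda m: sum(p.value.size for p in m.params())
        assert n(build_network(desk_config("cnn"), seed=0)) == n(
            build_network(desk_config("cnn"), seed=99)
        )

    def test_gradients_match_finite_differences(self):
        # end-to-end backprop check through the full U-Net
        rng = np.random.default_rng(0)
        model = build_network(desk_config("cnn"), seed=1)
        model.set_training(True)
        x = rng.standard_normal((2, 10, 8, 8))
        target = rng.standard_normal((2, 2, 8, 8))
        pred = model(x)
        model.zero_grad()
        model.backward(pred - target)

        def loss():
            return 0.5 * np.sum((model(x) - target) ** 2)

        check = np.random.default_rng(2)
        params = model.params()
        for k in check.choice(len(params), 6, replace=False):
            p = params[k]
            idx = tuple(check.integers(0, s) for s in p.value.shape) or ()
            orig = p.value[idx]
            eps = 1e-6
            p.value[idx] = orig + eps
            lp = loss()
            p.value[idx] = orig - eps
            lm = loss()
            p.value[idx] = orig
            fd = (lp - lm) / (2 * eps)
            # conv biases feeding batch norm have an exactly-zero gradient;
            # finite differences only see rounding noise there
            assert p.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestLosses:
    def test_supervised_zero_at_truth(self, rng):
        maps = rng.uniform(0, 1, (2, 2, 8, 8))
        assert supervised_loss(maps, maps) == 0.0

    def test_supervised_constant_offsets(self, rng):
        truth = rng.uniform(0, 1, (3, 2, 4, 4))
        assert supervised_loss(truth + 1.0, truth) == pytest.approx(1.0)
        t_only = truth.copy()
        t_only[:, 1] += 1.0
        assert supervised_loss(t_only, truth) == pytest.approx(0.5)

    def test_supervised_shape_mismatch(self):
        with pytest.raises(ValueError):
            supervised_loss(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_self_supervised_zero_on_exact_noiseless(self, grid, rng):
        s0 = rng.uniform(0.1, 1, (5, 5))
        t = rng.uniform(0.1, 4, (5, 5))
        series = decay_signal(s0, t, grid)
        assert self_supervised_loss(s0, t, series, grid) == pytest.approx(0.0, abs=1e-28)

    def test_self_supervised_positive_under_noise(self, grid):
        # at the true parameters the loss approaches E[(M - nu)^2] > 0,
        # computable in closed form from the Rice moments
        from t2relax.fitting import rician_expected_magnitude
        from t2relax.signal_model import rician_corrupt

        s0 = np.full((40, 40), 0.5)
        t = np.ones((40, 40))
        sigma = 0.1
        clean = decay_signal(s0, t, grid)
        noisy = rician_corrupt(clean, sigma, np.random.default_rng(0))
        loss = self_supervised_loss(s0, t, noisy, grid)
        nu = 0.5 * np.exp(-grid.eta)
        expected = np.mean(
            nu**2 + 2 * sigma**2 - 2 * nu * rician_expected_magnitude(nu, sigma) + nu**2
        )
        assert loss == pytest.approx(expected, rel=0.05)
        assert loss > 0

    def test_self_supervised_grad_matches_finite_difference(self, grid, rng):
        s0 = rng.uniform(0.2, 1, 6)
        t = rng.uniform(0.2, 3, 6)
        series = rng.uniform(0, 1, (6, grid.n))
        loss, gs0, gt = _self_supervised_grad(s0, t, series, grid.eta)
        eps = 1e-7
        for i in range(6):
            for vec, g in ((s0, gs0), (t, gt)):
                orig = vec[i]
                vec[i] = orig + eps
                lp = _self_supervised_grad(s0, t, series, grid.eta)[0]
                vec[i] = orig - eps
                lm = _self_supervised_grad(s0, t, series, grid.eta)[0]
                vec[i] = orig
                assert g[i] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5, abs=1e-9)


class TestTraining:
    def test_curve_extraction_count(self):
        assert extracted_curve_count(800, (128, 128)) == 13_107_200

    def test_nn1d_supervised_learns(self):
        ds = tiny_dataset(n=50, side=8)
        model = build_network(desk_config("nn1d"), seed=0)
        history = train_model(
            model, ds, TrainingConfig(strategy="supervised", epochs=5, batch_size=512, seed=0)
        )
        assert len(history.val_loss) == 5
        assert min(history.val_loss) < history.val_loss[0]
        assert history.n_train_curves == extracted_curve_count(history.n_train_series, (8, 8))

    def test_deterministic_training(self):
        ds = tiny_dataset(n=10, side=8)
        weights = []
        for _ in range(2):
            model = build_network(desk_config("nn1d"), seed=1)
            train_model(model, ds, TrainingConfig(epochs=2, batch_size=256, seed=4))
            weights.append(np.concatenate([p.value.ravel() for p in model.params()]))
        np.testing.assert_array_equal(weights[0], weights[1])

    def test_supervised_requires_truth(self):
        ds = tiny_dataset(n=8, side=8)
        truthless = SyntheticDataset(
            images=ds.images, s0=None, t=None, sigma=ds.sigma, grid=ds.grid
        )
        model = build_network(desk_config("nn1d"), seed=0)
        with pytest.raises(ValueError, match="truth"):
            train_model(model, truthless, TrainingConfig(strategy="supervised", epochs=1))

    def test_self_supervised_needs_no_truth(self):
        ds = tiny_dataset(n=10, side=8)
        truthless = SyntheticDataset(
            images=ds.images, s0=None, t=None, sigma=ds.sigma, grid=ds.grid
        )
        model = build_network(desk_config("nn1d"), seed=0)
        history = train_model(
            model,
            truthless,
            TrainingConfig(strategy="self_supervised", epochs=3, batch_size=256, seed=0),
        )
        assert min(history.val_loss) < history.val_loss[0]

    def test_cnn_supervised_smoke(self):
        ds = tiny_dataset(n=8, side=16)
        model = build_network(desk_config("cnn"), seed=0)
        history = train_model(
            model, ds, TrainingConfig(strategy="supervised", epochs=2, batch_size=4, seed=0)
        )
        assert len(history.train_loss) == 2
        assert np.isfinite(history.train_loss).all()


class TestInference:
    def test_untrained_model_finite_maps(self, grid, rng):
        model = build_network(desk_config("cnn"), seed=0)
        data = rng.uniform(0, 1, (16, 16, grid.n))
        pmap = predict_parameter_map(model, ImageSeries(data=data, grid=grid))
        assert np.all(np.isfinite(pmap.t)) and np.all(np.isfinite(pmap.s0))
        assert pmap.t.shape == (16, 16)

    def test_grid_mismatch_reports_both_grids(self, rng):
        ds = tiny_dataset(n=8, side=8)
        model = build_network(desk_config("nn1d"), seed=0)
        train_model(model, ds, TrainingConfig(epochs=1, batch_size=256, seed=0))
        other = SamplingGrid(eta=np.linspace(0.2, 1.0, 10))
        data = rng.uniform(0, 1, (8, 8, 10))
        with pytest.raises(ValueError, match="grid mismatch"):
            predict_parameter_map(model, ImageSeries(data=data, grid=other))

    def test_checkpoint_round_trip(self, tmp_path, grid, rng):
        ds = tiny_dataset(n=8, side=8)
        model = build_network(desk_config("nn1d"), seed=0)
        train_model(model, ds, TrainingConfig(epochs=1, batch_size=256, seed=0))
        save_model(model, tmp_path / "m.npz")
        reloaded = load_model(tmp_path / "m.npz")
        data = rng.uniform(0, 1, (8, 8, grid.n))
        series = ImageSeries(data=data, grid=grid)
        a = predict_parameter_map(model, series)
        b = predict_parameter_map(reloaded, series)
        np.testing.assert_array_equal(a.t, b.t)


class TestOptimizer:
    def test_adamw_converges_on_quadratic(self):
        from t2relax.networks.layers import Parameter

        p = Parameter(np.array([5.0, -3.0]))
        opt = AdamW([p], lr=0.1, weight_decay=0.0)
        for _ in range(500):
            p.grad[...] = 2 * p.value
            opt.step()
        assert np.allclose(p.value, 0, atol=1e-4)
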