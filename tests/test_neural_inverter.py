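"""Two-branch CNN: architecture contract, loss properties, gradient
correctness, training behaviour, inference."""

import numpy as np
import pytest

import cdinvert as ci
import cdinvert.neural_inverter as ni


class TestBuildModel:
    @pytest.mark.parametrize("size,depth", [(64, 3), (32, 3), (32, 2), (16, 2)])
    def test_output_is_quarter_area(self, size, depth):
        """Each head emits half the input size per dimension."""
        cfg = ni.ModelConfig(input_size=size, base_channels=4, depth=depth)
        model = ni.build_model(cfg, seed=0)
        x = np.zeros((2, size, size), dtype=np.float32)
        pa, pp = model.forward(x)
        assert pa.shape == (2, size // 2, size // 2)
        assert pp.shape == (2, size // 2, size // 2)

    def test_zero_input_finite_output(self):
        cfg = ni.ModelConfig(input_size=32, base_channels=4, depth=2)
        model = ni.build_model(cfg, seed=1)
        pa, pp = model.forward(np.zeros((1, 32, 32), dtype=np.float32))
        assert np.all(np.isfinite(pa)) and np.all(np.isfinite(pp))

    def test_outputs_nonnegative(self):
        """Final ReLU heads keep amplitude and scaled phase nonnegative."""
        cfg = ni.ModelConfig(input_size=32, base_channels=4, depth=2)
        model = ni.build_model(cfg, seed=2)
        rng = np.random.default_rng(0)
        pa, pp = model.forward(rng.uniform(size=(3, 32, 32)).astype(np.float32))
        assert pa.min() >= 0 and pp.min() >= 0

    def test_parameter_count_scales_quadratically(self):
        """Doubling base_channels grows conv parameters about 4x."""
        small = ni.build_model(ni.ModelConfig(32, base_channels=8, depth=2), seed=0)
        big = ni.build_model(ni.ModelConfig(32, base_channels=16, depth=2), seed=0)
        ratio = ni.count_parameters(big) / ni.count_parameters(small)
        assert 3.3 < ratio < 4.2

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ni.ModelConfig(input_size=36, depth=3)


class TestCompositeLoss:
    def _truth_sample(self):
        cfg = ci.SimulatorConfig(grid=ci.GridSpec(32, 32))
        obj, _ = ci.sample_random_particle(cfg, 5)
        s = ci.make_training_sample(obj)
        m = ni.normalize_pattern(s.pattern.intensity)
        return s, m

    def test_zero_at_truth(self):
        s, m = self._truth_sample()
        total, breakdown = ni.composite_loss(
            s.target_amplitude, s.target_phase_scaled,
            s.target_amplitude, s.target_phase_scaled, m,
        )
        assert breakdown["amp"] == 0 and breakdown["phase"] == 0
        assert total < 1e-6  # tiny residual from the target support threshold

    def test_real_space_closed_forms(self):
        """A constant offset delta on a fraction f of pixels contributes
        w_amp * delta * f under the L1 norm and w_amp * delta^2 * f under
        the default L2 norm."""
        s, m = self._truth_sample()
        pred = s.target_amplitude.copy()
        npix = pred.size
        k = npix // 4
        pred.flat[:k] += 0.2
        total, bd = ni.composite_loss(
            pred, s.target_phase_scaled, s.target_amplitude, s.target_phase_scaled,
            m, ni.LossWeights(2.0, 1.0, 0.0, real_norm="l1"),
        )
        assert bd["amp"] == pytest.approx(0.2 * k / npix)
        assert total == pytest.approx(2.0 * 0.2 * k / npix)
        total2, bd2 = ni.composite_loss(
            pred, s.target_phase_scaled, s.target_amplitude, s.target_phase_scaled,
            m, ni.LossWeights(2.0, 1.0, 0.0),
        )
        assert bd2["amp"] == pytest.approx(0.2**2 * k / npix)
        assert total2 == pytest.approx(2.0 * 0.2**2 * k / npix)

    def test_recip_term_detects_support_violation(self):
        s, m = self._truth_sample()
        pred = s.target_amplitude.copy()
        pred[0, 0] += 0.5  # corner pixel, outside any particle support
        _, bd_true = ni.composite_loss(
            s.target_amplitude, s.target_phase_scaled,
            s.target_amplitude, s.target_phase_scaled, m,
            ni.LossWeights(0.0, 0.0, 1.0),
        )
        _, bd_bad = ni.composite_loss(
            pred, s.target_phase_scaled,
            s.target_amplitude, s.target_phase_scaled, m,
            ni.LossWeights(0.0, 0.0, 1.0),
        )
        assert bd_bad["recip"] > 100 * bd_true["recip"]

    def test_terms_nonnegative(self):
        rng = np.random.default_rng(3)
        args = [rng.uniform(size=(16, 16)) for _ in range(4)]
        m = rng.uniform(0.1, 1.0, size=(32, 32))
        _, bd = ni.composite_loss(*args, m)
        assert all(v >= 0 for v in bd.values())

    def test_nonfinite_rejected(self):
        bad = np.full((16, 16), np.nan)
        ok = np.ones((16, 16))
        with pytest.raises(ValueError):
            ni.composite_loss(bad, ok, ok, ok, np.ones((32, 32)))


class TestGradients:
    def test_finite_difference_agreement(self):
        """End-to-end analytic gradients match central differences."""
        rng = np.random.default_rng(0)
        cfg = ni.ModelConfig(input_size=16, base_channels=4, depth=2)
        model = ni.build_model(cfg, seed=1, dtype=np.float64)
        W = ni.LossWeights(1.0, 1.0, 0.1)
        X = rng.uniform(size=(2, 16, 16))
        A = rng.uniform(size=(2, 8, 8))
        P = rng.uniform(size=(2, 8, 8))

        def loss_fn():
            pa, pp = model.forward(X, train=True)
            return ni._loss_and_grads(pa, pp, A, P, X, W)

        loss0, _, ga, gp = loss_fn()
        model.backward(ga, gp)
        grads = [g.copy() for g in model.gradients()]
        params = model.parameters()
        eps = 1e-6
        for pi in rng.choice(len(params), size=8, replace=False):
            flat, gflat = params[pi].ravel(), grads[pi].ravel()
            for k in rng.choice(flat.size, size=2, replace=False):
                old = flat[k]
                flat[k] = old + eps
                lp = loss_fn()[0]
                flat[k] = old - eps
                lm = loss_fn()[0]
                flat[k] = old
                fd = (lp - lm) / (2 * eps)
                an = gflat[k]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd) + abs(an))


class TestTraining:
    def test_overfits_tiny_dataset(self):
        """Capacity sanity check: real-space training loss collapses by at
        least 90% when memorizing 5 samples."""
        cfg = ci.SimulatorConfig(grid=ci.GridSpec(32, 32))
        ds = ci.simulate_dataset(cfg, 5, seed=1)
        ds.train_idx = np.arange(5)
        ds.val_idx = np.arange(0)
        mc = ni.ModelConfig(input_size=32, base_channels=8, depth=2)
        tm = ni.train(ds, mc, ni.LossWeights(1, 1, 0.0), epochs=300,
                      batch_size=5, lr=2e-3, seed=0)
        hist = tm.history["train_loss"]
        assert hist[-1] <= 0.1 * hist[0]

    def test_deterministic_first_epoch(self):
        cfg = ci.SimulatorConfig(grid=ci.GridSpec(32, 32))
        ds = ci.simulate_dataset(cfg, 12, seed=2)
        mc = ni.ModelConfig(input_size=32, base_channels=4, depth=2)
        a = ni.train(ds, mc, epochs=1, batch_size=4, seed=3)
        b = ni.train(ds, mc, epochs=1, batch_size=4, seed=3)
        assert a.history["train_loss"][0] == b.history["train_loss"][0]

    def test_history_lengths(self):
        cfg = ci.SimulatorConfig(grid=ci.GridSpec(32, 32))
        ds = ci.simulate_dataset(cfg, 12, seed=4)
        tm = ni.train(ds, ni.ModelConfig(32, 4, 2), epochs=3, batch_size=4, seed=0)
        assert len(tm.history["train_loss"]) == 3
        assert len(tm.history["val_loss"]) == 3


class TestInference:
    def test_scale_invariance(self):
        """Per-pattern max normalization makes predictions invariant to a
        constant intensity rescale."""
        cfg = ci.SimulatorConfig(grid=ci.GridSpec(32, 32))
        obj, _ = ci.sample_random_particle(cfg, 6)
        s = ci.make_training_sample(obj)
        mc = ni.ModelConfig(input_size=32, base_channels=4, depth=2)
        tm = ni.TrainedModel(config=mc, model=ni.build_model(mc, seed=0))
        img1, ps1 = ni.infer(tm, s.pattern)
        scaled = ci.DiffractionPattern(intensity=s.pattern.intensity * 7.3)
        img2, ps2 = ni.infer(tm, scaled)
        assert np.allclose(img1.amplitude, img2.amplitude, atol=1e-6)
        assert np.allclose(ps1, ps2, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        mc = ni.ModelConfig(input_size=32, base_channels=4, depth=2)
        tm = ni.TrainedModel(config=mc, model=ni.build_model(mc, seed=0))
        with pytest.raises(ValueError, match="input_size"):
            ni.infer(tm, ci.DiffractionPattern(intensity=np.ones((16, 16))))

    def test_phase_zeroed_outside_support(self):
        cfg = ci.SimulatorConfig(grid=ci.GridSpec(32, 32))
        obj, _ = ci.sample_random_particle(cfg, 8)
        s = ci.make_training_sample(obj)
        mc = ni.ModelConfig(input_size=32, base_channels=4, depth=2)
        tm = ni.TrainedModel(config=mc, model=ni.build_model(mc, seed=4))
        img, ps = ni.infer(tm, s.pattern)
        weak = img.amplitude < 0.05 * img.amplitude.max()
        assert np.all(img.phase[weak] == 0)
        assert ps.min() >= 0 and ps.max() <= 1


class TestEvaluateOnSplit:
    def test_perfect_oracle_gives_zero(self, corpus32):
        """A model returning the ground truth scores chi^2 == 0 everywhere."""

        class Oracle:
            def __init__(self, ds):
                self.ds = ds

            def forward(self, x, train=False):
                # look the sample up by its normalized pattern
                for s in self.ds.samples:
                    if np.allclose(
                        ni.normalize_pattern(s.pattern.intensity), x[0], atol=1e-12
                    ):
                        return (
                            s.target_amplitude[None],
                            s.target_phase_scaled[None],
                        )
                raise AssertionError("unknown pattern")

        mc = ni.ModelConfig(input_size=32, base_channels=4, depth=2)
        tm = ni.TrainedModel(config=mc, model=Oracle(corpus32))
        table = ni.evaluate_on_split(tm, corpus32, "val")
        assert np.allclose(table["chi2_amplitude"], 0.0, atol=1e-12)
        assert np.allclose(table["chi2_phase"], 0.0, atol=1e-12)
        assert np.all(table["chi2_modulus"] < 1e-5)
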