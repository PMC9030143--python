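"""Residual 1D-CNN encoder, LSTM cell/stack, classifier and training."""

import numpy as np
import pytest

from longconn import _engine as eng
from longconn._engine import Tensor
from longconn.connectome import pearson_fc
from longconn.evaluate import cohort_samples
from longconn.model import (CNNConfig, CNNEncoder, LongitudinalSample,
                            LSTMCellParams, SequenceClassifier, StackConfig,
                            TrainConfig, build_classifier, classify,
                            cnn_forward, load_model, lstm_cell_step, save_model,
                            train_model)

TINY_CNN = CNNConfig(blocks=((4, 3, 1), (6, 3, 1), (8, 3, 1)), feature_dim=5)
TINY_STACK = StackConfig(hidden_size=4, dropout=0.0)


def random_cell_params(rng, hidden, inp):
    mk = lambda shape: rng.standard_normal(shape) * 0.5
    return LSTMCellParams(W_f=mk((hidden, hidden + inp)), W_i=mk((hidden, hidden + inp)),
                          W_c=mk((hidden, hidden + inp)), W_o=mk((hidden, hidden + inp)),
                          b_f=mk(hidden), b_i=mk(hidden), b_c=mk(hidden), b_o=mk(hidden))


def reference_lstm_cell(x, h_prev, c_prev, p):
    """Textbook cell written against the split [W_h | W_x] block form,
    independently of the package implementation."""
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    h_sz = p.hidden_size
    out_h, out_c = np.zeros_like(h_prev), np.zeros_like(c_prev)
    W = {g: (getattr(p, f"W_{g}")[:, :h_sz], getattr(p, f"W_{g}")[:, h_sz:])
         for g in "fico"}
    f = sig(W["f"][0] @ h_prev + W["f"][1] @ x + p.b_f)
    i = sig(W["i"][0] @ h_prev + W["i"][1] @ x + p.b_i)
    c_t = np.tanh(W["c"][0] @ h_prev + W["c"][1] @ x + p.b_c)
    c = f * c_prev + i * c_t
    o = sig(W["o"][0] @ h_prev + W["o"][1] @ x + p.b_o)
    return o * np.tanh(c), c


class TestLSTMCell:
    def test_zero_parameters_give_half_gates(self):
        p = LSTMCellParams(*(np.zeros((2, 5)),) * 4, *(np.zeros(2),) * 4)
        h, c = lstm_cell_step(np.ones(3), np.zeros(2), np.zeros(2), p)
        np.testing.assert_array_equal(c, 0.0)
        np.testing.assert_array_equal(h, 0.0)

    def test_saturated_gates_preserve_memory(self):
        p = LSTMCellParams(*(np.zeros((2, 5)),) * 4,
                           np.full(2, 100.0), np.full(2, -100.0),
                           np.zeros(2), np.zeros(2))
        c_prev = np.array([0.3, -0.7])
        _, c = lstm_cell_step(np.ones(3), np.zeros(2), c_prev, p)
        np.testing.assert_allclose(c, c_prev, atol=1e-40)

    def test_matches_independent_reference(self, rng):
        for _ in range(100):
            hidden, inp = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            p = random_cell_params(rng, hidden, inp)
            x = rng.standard_normal(inp)
            h_prev = rng.standard_normal(hidden)
            c_prev = rng.standard_normal(hidden)
            h, c = lstm_cell_step(x, h_prev, c_prev, p)
            h_ref, c_ref = reference_lstm_cell(x, h_prev, c_prev, p)
            np.testing.assert_allclose(h, h_ref, atol=1e-6)
            np.testing.assert_allclose(c, c_ref, atol=1e-6)

    def test_gates_bounded(self, rng):
        p = random_cell_params(rng, 4, 3)
        h, c = lstm_cell_step(rng.standard_normal(3) * 10,
                              rng.standard_normal(4), rng.standard_normal(4), p)
        assert np.all(np.abs(h) < 1.0)

    def test_shape_mismatch_raises(self, rng):
        p = random_cell_params(rng, 4, 3)
        with pytest.raises(ValueError, match="shape mismatch"):
            lstm_cell_step(np.zeros(5), np.zeros(4), np.zeros(4), p)

    def test_stack_step_matches_cell_function(self, rng):
        """The trainable stack and the standalone cell follow one recurrence."""
        from longconn.model import LSTMStack
        stack = LSTMStack(3, StackConfig(num_lstm_layers=1, hidden_size=4,
                                         dropout=0.0), rng)
        p = stack.cell_params(0)
        x = rng.standard_normal((2, 3))
        top = stack.forward([Tensor(x)])
        h_ref = np.stack([reference_lstm_cell(x[i], np.zeros(4), np.zeros(4), p)[0]
                          for i in range(2)])
        np.testing.assert_allclose(top.data, h_ref, atol=1e-10)


class TestCNNEncoder:
    def test_output_shape(self, rng):
        enc = CNNEncoder(15, TINY_CNN, rng)
        out = enc.forward(Tensor(rng.standard_normal((3, 1, 15))))
        assert out.data.shape == (3, TINY_CNN.feature_dim)

    def test_inference_deterministic(self, rng):
        model = build_classifier(8, cnn_config=TINY_CNN, stack_config=TINY_STACK)
        x = rng.standard_normal((2, 3, 28))
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_exactly_two_shortcuts_enforced(self):
        with pytest.raises(ValueError, match="two short-connection"):
            CNNConfig(shortcut_pairs=((1, 3),))
        with pytest.raises(ValueError, match="follow source"):
            CNNConfig(shortcut_pairs=((2, 1), (1, 3)))

    def test_shortcut_path_carries_signal(self, rng):
        """With dead conv paths the projection alone determines block input."""
        enc = CNNEncoder(15, TINY_CNN, rng)
        src, dst, pw, pb, pool_ks = enc.shortcuts[0]
        act = Tensor(rng.standard_normal((2, TINY_CNN.blocks[src][0], 15)))
        projected = enc._project(act, pw, pb, pool_ks)
        manual = np.einsum("oc,ncl->nol", pw.data[:, :, 0], act.data) \
            + pb.data[None, :, None]
        np.testing.assert_allclose(projected.data, manual, atol=1e-12)
        # zeroing the projection changes the encoder output: the link is live
        x = Tensor(rng.standard_normal((2, 1, 15)))
        before = enc.forward(x).data.copy()
        pw.data = np.zeros_like(pw.data)
        after = enc.forward(x).data
        assert np.abs(before - after).max() > 0

    def test_cnn_forward_on_fc(self, tiny_cohort, rng):
        fc = pearson_fc(tiny_cohort.series[("NC_000", "BL")])
        enc = CNNEncoder(fc.roi_count * (fc.roi_count - 1) // 2, TINY_CNN, rng)
        feat = cnn_forward(fc, enc)
        assert feat.shape == (TINY_CNN.feature_dim,)


class TestClassifier:
    def make_sample(self, rng, r=8, label=1):
        from longconn.connectome import ROITimeSeries, TIMEPOINTS
        fcs = tuple(pearson_fc(ROITimeSeries(rng.standard_normal((20, r)),
                                             timepoint=tp)) for tp in TIMEPOINTS)
        return LongitudinalSample(fc_sequence=fcs, label=label, subject_id="s")

    def test_probability_in_unit_interval(self, rng):
        model = build_classifier(8, cnn_config=TINY_CNN, stack_config=TINY_STACK)
        s = self.make_sample(rng)
        assert 0.0 <= classify(s, model) <= 1.0

    def test_zero_head_gives_half(self, rng):
        model = build_classifier(8, cnn_config=TINY_CNN, stack_config=TINY_STACK)
        model.head_w.data = np.zeros_like(model.head_w.data)
        model.head_b.data = np.zeros_like(model.head_b.data)
        assert classify(self.make_sample(rng), model) == pytest.approx(0.5)

    def test_weight_sharing_across_timepoints(self):
        """One CNN parameter object serves every timepoint."""
        model = build_classifier(8, cnn_config=TINY_CNN, stack_config=TINY_STACK)
        assert model.cnn is model.cnn  # single encoder instance
        cnn_param_ids = {id(p) for p in model.cnn.params}
        assert cnn_param_ids <= {id(p) for p in model.params}

    def test_order_sensitivity(self, rng):
        """A generic model distinguishes timepoint orderings."""
        sensitive = 0
        for seed in range(20):
            model = build_classifier(8, cnn_config=TINY_CNN,
                                     stack_config=TINY_STACK, seed=seed)
            x = rng.standard_normal((1, 3, 28))
            p1 = model.predict_proba(x)[0]
            p2 = model.predict_proba(x[:, ::-1, :].copy())[0]
            if abs(p1 - p2) > 1e-9:
                sensitive += 1
        assert sensitive >= 1

    def test_missing_timepoint_rejected(self, rng):
        s = self.make_sample(rng)
        with pytest.raises(ValueError, match="3 timepoints"):
            LongitudinalSample(fc_sequence=s.fc_sequence[:2], label=0)


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        """Composed CNN+LSTM gradient vs central differences, tiny config.

        Parameters are perturbed away from initialization so no pre-activation
        sits exactly on the ReLU kink.
        """
        model = build_classifier(6, cnn_config=TINY_CNN, stack_config=TINY_STACK,
                                 seed=3)
        for p in model.params:
            p.data = p.data + rng.normal(0, 0.05, p.data.shape)
        x = rng.standard_normal((2, 3, 15))
        y = np.array([0.0, 1.0])

        def loss_value():
            return float(eng.bce_with_logits(model.forward_logits(x), y).data)

        for p in model.params:
            p.grad = None
        eng.bce_with_logits(model.forward_logits(x), y).backward()
        worst = 0.0
        for pi, p in enumerate(model.params):
            flat = list(np.ndindex(*p.data.shape))
            sel = np.random.default_rng(pi).choice(len(flat), size=min(3, len(flat)),
                                                   replace=False)
            for k in sel:
                idx = flat[k]
                eps, orig = 1e-5, p.data[idx]
                p.data[idx] = orig + eps
                lp = loss_value()
                p.data[idx] = orig - eps
                lm = loss_value()
                p.data[idx] = orig
                fd = (lp - lm) / (2 * eps)
                g = 0.0 if p.grad is None else p.grad[idx]
                worst = max(worst, abs(fd - g) / max(abs(fd), abs(g), 1e-7))
        assert worst < 1e-4


class TestTraining:
    def test_loss_curves_and_determinism(self, tiny_cohort):
        samples = cohort_samples(tiny_cohort, "nc-ad")
        cfg = TrainConfig(epochs=5, seed=9)
        r1 = train_model(samples[:14], samples[14:], cfg,
                         cnn_config=TINY_CNN, stack_config=TINY_STACK)
        r2 = train_model(samples[:14], samples[14:], cfg,
                         cnn_config=TINY_CNN, stack_config=TINY_STACK)
        assert len(r1.train_loss) == 5 and len(r1.val_loss) == 5
        for a, b in zip(r1.model.state_arrays(), r2.model.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, tiny_cohort):
        samples = [s for s in cohort_samples(tiny_cohort, "nc-ad") if s.label == 0]
        with pytest.raises(ValueError, match="both classes"):
            train_model(samples, [], TrainConfig(epochs=1))

    def test_separable_cohort_reaches_perfect_training_accuracy(self, tiny_cohort):
        """Huge-effect cohort is fit perfectly within 50 epochs."""
        samples = cohort_samples(tiny_cohort, "nc-ad")
        res = train_model(samples, [], TrainConfig(epochs=50, seed=0))
        x = np.stack([s.feature_sequence() for s in samples])
        y = np.array([s.label for s in samples])
        acc = ((res.model.predict_proba(x) > 0.5).astype(int) == y).mean()
        assert acc == 1.0


def test_model_serialization_roundtrip(tmp_path, rng):
    model = build_classifier(8, cnn_config=TINY_CNN, stack_config=TINY_STACK, seed=2)
    x = rng.standard_normal((3, 3, 28))
    save_model(model, tmp_path / "m.npz")
    back = load_model(tmp_path / "m.npz")
    np.testing.assert_array_equal(model.predict_proba(x), back.predict_proba(x))
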