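"""Loss oracles, encoder/decoder contracts, objective assembly, training."""

import numpy as np
import pytest

from condvae.autodiff import Tensor
from condvae.conditions import make_scheme
from condvae.model import (ConditionCVAE, DecoderConfig, EncoderConfig,
                           LossConfig, TrainConfig, additive_loss,
                           default_loss_config, emd_loss, focal_loss_softmax,
                           total_loss)

LN2 = np.log(2.0)


# ----------------------------------------------------------------------
# loss oracles: direct evaluations of the printed formulas
# ----------------------------------------------------------------------
class TestFocalLoss:
    def test_perfect_prediction_is_zero(self):
        v = focal_loss_softmax(np.array([1.0, 0.0, 0.0]),
                               np.array([1, 0, 0])).item()
        assert v < 1e-10

    def test_reduces_to_cross_entropy(self):
        p = np.array([0.3, 0.7])
        v = focal_loss_softmax(p, np.array([1, 0]), gamma=0.0, alpha=1.0).item()
        assert abs(v - (-np.log(0.3))) < 1e-10

    def test_half_probability_direct_value(self):
        v = focal_loss_softmax(np.array([0.5, 0.5]), np.array([1, 0]),
                               gamma=2.0, alpha=0.25).item()
        assert abs(v - 0.25 * 0.25 * LN2) < 1e-10

    def test_non_one_hot_target_rejected(self):
        with pytest.raises(ValueError):
            focal_loss_softmax(np.array([0.5, 0.5]), np.array([1, 1]))


class TestAdditiveLoss:
    def test_perfect_prediction_zero_for_both_kinds(self):
        p = np.array([0.9999999, 1e-7])
        y = np.array([1, 0])
        assert additive_loss(p, y, "bce").item() < 1e-5
        assert additive_loss(p, y, "binary_focal").item() < 1e-12

    def test_binary_focal_reduces_to_half_bce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, size=6)
        y = rng.integers(0, 2, size=6)
        bf = additive_loss(p, y, "binary_focal", gamma=0.0, alpha=0.5).item()
        bce = additive_loss(p, y, "bce").item()
        assert abs(bf - 0.5 * bce) < 1e-10

    def test_single_bit_direct_value(self):
        v = additive_loss(np.array([0.5]), np.array([1]), "binary_focal",
                          gamma=2.0, alpha=0.25).item()
        assert abs(v - 0.25 * 0.25 * LN2) < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            additive_loss(np.array([0.5, 0.5]), np.array([1]))


class TestEMDLoss:
    def test_exact_match_is_zero(self):
        y = np.array([0, 1, 0])
        assert emd_loss(y.astype(float), y).item() < 1e-6

    def test_distant_class_direct_value(self):
        v = emd_loss(np.array([0, 0, 1.0]), np.array([1, 0, 0]), r=2).item()
        assert abs(v - np.sqrt(2 / 3)) < 1e-9

    def test_adjacent_error_cheaper_than_distant(self):
        near = emd_loss(np.array([0, 1.0, 0]), np.array([1, 0, 0]), r=2).item()
        far = emd_loss(np.array([0, 0, 1.0]), np.array([1, 0, 0]), r=2).item()
        assert abs(near - np.sqrt(1 / 3)) < 1e-9
        assert near < far

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            emd_loss(np.array([1.0]), np.array([1]))


# ----------------------------------------------------------------------
# loss gradients vs finite differences
# ----------------------------------------------------------------------
@pytest.mark.parametrize("loss_name", ["focal", "bce", "binary_focal", "emd"])
def test_loss_gradients_match_finite_differences(loss_name):
    rng = np.random.default_rng(42)
    logits = Tensor(rng.normal(size=(2, 4)), requires_grad=True)
    y_onehot = np.eye(4)[[1, 3]]
    y_multi = rng.integers(0, 2, size=(2, 4))

    def build():
        if loss_name == "focal":
            return focal_loss_softmax(logits.softmax(), y_onehot).sum()
        if loss_name == "emd":
            return emd_loss(logits.softmax(), y_onehot).sum()
        p = logits.sigmoid()
        return additive_loss(p, y_multi, loss_name).sum()

    build().backward()
    analytic = logits.grad.copy()
    eps = 1e-6
    num = np.zeros_like(analytic)
    for i in range(2):
        for j in range(4):
            logits.data[i, j] += eps
            up = build().item()
            logits.data[i, j] -= 2 * eps
            dn = build().item()
            logits.data[i, j] += eps
            num[i, j] = (up - dn) / (2 * eps)
    assert np.abs(analytic - num).max() < 1e-4


# ----------------------------------------------------------------------
# composite objective
# ----------------------------------------------------------------------
def tiny_scheme():
    return make_scheme("custom", catalyst_vocab=["a", "b"],
                       additive_vocab=["acid", "base"],
                       temp_bins=["lo", "hi"], temp_edges=[25.0],
                       pressure_bins=["lo", "hi"], pressure_edges=[2.0],
                       allow_unknown_tp=True)


def perfect_outputs(scheme, bits):
    from condvae.model import HeadOutputs

    b = np.asarray(bits, dtype=float)[None, :]
    return HeadOutputs(
        catalyst_probs=Tensor(b[:, scheme.catalyst_slice]),
        additive_probs=Tensor(np.clip(b[:, scheme.additive_slice], 1e-9, 1 - 1e-9)),
        temp_probs=Tensor(b[:, scheme.temp_slice]),
        pressure_probs=Tensor(b[:, scheme.pressure_slice]),
    )


class TestTotalLoss:
    def test_perfect_outputs_standard_posterior_is_zero(self):
        scheme = tiny_scheme()
        bits = np.array([1, 0, 1, 0, 0, 1, 1, 0], dtype=float)
        outputs = perfect_outputs(scheme, bits)
        kl = Tensor(np.zeros(1))     # μ=0, σ=1 posterior
        loss, bd = total_loss(outputs, bits[None, :], kl,
                              LossConfig(prior_recon_weight=0.0), 0.001,
                              np.array([[True, True]]), scheme)
        assert loss.item() < 1e-5
        assert bd["kl"] == 0.0

    def test_masked_ordinal_terms_vanish(self):
        scheme = tiny_scheme()
        bits = np.array([0, 1, 0, 0, 0, 0, 0, 0], dtype=float)  # unknown T/P
        rng = np.random.default_rng(0)
        from condvae.model import HeadOutputs

        raw = rng.uniform(0.2, 0.8, size=(1, 8))
        outputs = HeadOutputs(
            catalyst_probs=Tensor(raw[:, scheme.catalyst_slice]
                                  / raw[:, scheme.catalyst_slice].sum()),
            additive_probs=Tensor(raw[:, scheme.additive_slice]),
            temp_probs=Tensor(raw[:, scheme.temp_slice]
                              / raw[:, scheme.temp_slice].sum()),
            pressure_probs=Tensor(raw[:, scheme.pressure_slice]
                                  / raw[:, scheme.pressure_slice].sum()),
        )
        kl = Tensor(np.array([2.0]))
        loss, bd = total_loss(outputs, bits[None, :], kl,
                              LossConfig(prior_recon_weight=0.0), 0.001,
                              np.array([[False, False]]), scheme)
        assert bd["emd_temperature"] == 0.0
        assert bd["emd_pressure"] == 0.0
        expected = bd["focal_catalyst"] + bd["additive"] + 0.001 * 2.0
        assert abs(loss.item() - expected) < 1e-12

    def test_beta_enters_linearly(self):
        scheme = tiny_scheme()
        bits = np.array([1, 0, 0, 1, 1, 0, 0, 1], dtype=float)
        outputs = perfect_outputs(scheme, bits)
        kl = Tensor(np.array([3.0]))
        cfg = LossConfig(prior_recon_weight=0.0)
        l0, _ = total_loss(outputs, bits[None, :], kl, cfg, 0.0,
                           np.array([[True, True]]), scheme)
        l1, _ = total_loss(outputs, bits[None, :], kl, cfg, 0.001,
                           np.array([[True, True]]), scheme)
        assert abs((l1.item() - l0.item()) - 0.001 * 3.0) < 1e-12

    def test_breakdown_sums_to_total(self):
        scheme = tiny_scheme()
        rng = np.random.default_rng(5)
        bits = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=float)
        from condvae.model import HeadOutputs

        raw = rng.uniform(0.1, 0.9, size=(1, 8))
        outputs = HeadOutputs(
            catalyst_probs=Tensor(raw[:, scheme.catalyst_slice]
                                  / raw[:, scheme.catalyst_slice].sum()),
            additive_probs=Tensor(raw[:, scheme.additive_slice]),
            temp_probs=Tensor(raw[:, scheme.temp_slice]
                              / raw[:, scheme.temp_slice].sum()),
            pressure_probs=Tensor(raw[:, scheme.pressure_slice]
                                  / raw[:, scheme.pressure_slice].sum()),
        )
        kl = Tensor(np.array([1.3]))
        loss, bd = total_loss(outputs, bits[None, :], kl,
                              LossConfig(prior_recon_weight=0.0), 0.001,
                              np.array([[True, True]]), scheme)
        parts = (bd["focal_catalyst"] + bd["additive"] + bd["emd_temperature"]
                 + bd["emd_pressure"] + bd["beta"] * bd["kl"])
        assert abs(loss.item() - parts) < 1e-10


# ----------------------------------------------------------------------
# encoder / decoder contracts
# ----------------------------------------------------------------------
class TestEncoderDecoder:
    @pytest.fixture
    def tiny_model(self):
        return ConditionCVAE(tiny_scheme(), descriptor_dim=5,
                             encoder=EncoderConfig(latent_dim=4, c_hidden=8,
                                                   s_hidden=8),
                             decoder=DecoderConfig(s_hidden=8, f_hidden=8,
                                                   trunk_hidden=8),
                             train=TrainConfig(seed=0))

    def test_gaussian_posterior_dims(self, tiny_model):
        post = tiny_model.encode(np.zeros((3, 8)), np.zeros((3, 5)))
        assert post.mu.shape == (3, 4)
        assert post.sigma.shape == (3, 4)
        assert np.all(post.sigma.data > 0)

    def test_vmf_posterior_dims_and_norm(self):
        m = ConditionCVAE(tiny_scheme(), descriptor_dim=5,
                          encoder=EncoderConfig(latent_dim=4, c_hidden=8,
                                                s_hidden=8, family="vmf"),
                          decoder=DecoderConfig(s_hidden=8, f_hidden=8,
                                                trunk_hidden=8),
                          train=TrainConfig(seed=0))
        post = m.encode(np.random.default_rng(0).normal(size=(3, 8)),
                        np.random.default_rng(1).normal(size=(3, 5)))
        assert post.mu.shape == (3, 4) and post.k.shape == (3,)
        assert np.allclose(np.linalg.norm(post.mu.data, axis=1), 1, atol=1e-9)
        assert np.all(post.k.data >= 0)

    def test_heads_are_simplices(self, tiny_model):
        rng = np.random.default_rng(2)
        out = tiny_model.decode(rng.normal(size=(6, 4)), rng.normal(size=(6, 5)))
        for probs in (out.catalyst_probs, out.temp_probs, out.pressure_probs):
            assert np.allclose(probs.data.sum(axis=1), 1, atol=1e-6)
            assert np.all((probs.data >= 0) & (probs.data <= 1))
        assert np.all((out.additive_probs.data >= 0)
                      & (out.additive_probs.data <= 1))

    def test_latent_is_live(self, tiny_model):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 5))
        o1 = tiny_model.decode(rng.normal(size=(1, 4)), x)
        o2 = tiny_model.decode(rng.normal(size=(1, 4)), x)
        assert not np.allclose(o1.catalyst_probs.data, o2.catalyst_probs.data)

    def test_decoder_without_f_net_still_valid(self):
        m = ConditionCVAE(tiny_scheme(), descriptor_dim=5,
                          encoder=EncoderConfig(latent_dim=4, c_hidden=8,
                                                s_hidden=8),
                          decoder=DecoderConfig(s_hidden=8, f_hidden=8,
                                                trunk_hidden=8, use_f_net=False),
                          train=TrainConfig(seed=0))
        out = m.decode(np.zeros((2, 4)), np.zeros((2, 5)))
        assert np.allclose(out.catalyst_probs.data.sum(axis=1), 1, atol=1e-6)

    def test_encoder_gradients_reach_all_weights(self, tiny_model):
        y = np.random.default_rng(4).normal(size=(2, 8))
        x = np.random.default_rng(5).normal(size=(2, 5))
        post = tiny_model.encode(y, x)
        (post.mu.sum() + post.sigma.sum()).backward()
        for layer in (tiny_model.c_net, tiny_model.s_net_enc, tiny_model.h_net):
            assert layer.W.grad is not None
            assert np.any(layer.W.grad != 0)


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------
def tiny_training_data(n=64, seed=0):
    scheme = tiny_scheme()
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 5))
    Y = np.zeros((n, 8))
    for i in range(n):
        Y[i, rng.integers(0, 2)] = 1                    # catalyst
        Y[i, 2 + rng.integers(0, 2)] = rng.integers(0, 2)  # one additive maybe
        Y[i, 4 + rng.integers(0, 2)] = 1                # temp
        Y[i, 6 + rng.integers(0, 2)] = 1                # pressure
    return scheme, X, Y


class TestTraining:
    def make(self, family="gaussian", seed=0, epochs=3):
        scheme, X, Y = tiny_training_data()
        model = ConditionCVAE(
            scheme, 5,
            encoder=EncoderConfig(latent_dim=4, c_hidden=8, s_hidden=8,
                                  family=family),
            decoder=DecoderConfig(s_hidden=8, f_hidden=8, trunk_hidden=8,
                                  f_pretrain_epochs=2),
            train=TrainConfig(epochs=epochs, batch_size=16, seed=seed))
        return model, X, Y

    def test_one_epoch_reduces_loss(self):
        model, X, Y = self.make(epochs=8)
        trace = model.fit(X, Y)
        assert trace[-1]["total"] < trace[0]["total"]

    def test_same_seed_identical_weights(self):
        m1, X, Y = self.make(seed=7)
        m2, _, _ = self.make(seed=7)
        m1.fit(X, Y)
        m2.fit(X, Y)
        for p1, p2 in zip(m1.parameters, m2.parameters):
            assert np.array_equal(p1.data, p2.data)

    def test_empty_dataset_rejected(self):
        model, _, _ = self.make()
        with pytest.raises(ValueError):
            model.fit(np.zeros((0, 5)), np.zeros((0, 8)))

    def test_rnf_beta_schedule_endpoints(self):
        model, _, _ = self.make(family="rnf")
        model.train_cfg.epochs = 11
        model.loss_cfg = default_loss_config("rnf")
        assert model._beta_at(0) == 0.0
        assert abs(model._beta_at(10) - 0.8) < 1e-12
        mid = model._beta_at(5)
        assert abs(mid - 0.4) < 1e-12      # linear interpolation

    def test_lr_linear_decay(self):
        model, _, _ = self.make()
        model.train_cfg.epochs = 200
        assert model._lr_at(0) == pytest.approx(1e-3)
        assert model._lr_at(199) == pytest.approx(2.5e-4)

    def test_rnf_identity_flows_reproduce_gaussian_losses(self):
        """With identity flows, zero MMD/penalty and the same loss settings,
        the flow model's first-epoch loss equals the Gaussian model's bitwise."""
        scheme, X, Y = tiny_training_data()
        shared_loss = dict(beta=0.001, beta_schedule="constant",
                           additive_kind="bce")
        common = dict(
            encoder=dict(latent_dim=4, c_hidden=8, s_hidden=8),
            decoder=DecoderConfig(s_hidden=8, f_hidden=8, trunk_hidden=8,
                                  f_pretrain_epochs=2),
            train=TrainConfig(epochs=1, batch_size=64, seed=5))
        g = ConditionCVAE(scheme, 5,
                          encoder=EncoderConfig(**common["encoder"],
                                                family="gaussian"),
                          decoder=common["decoder"],
                          loss=LossConfig(**shared_loss),
                          train=common["train"])
        r = ConditionCVAE(scheme, 5,
                          encoder=EncoderConfig(**common["encoder"],
                                                family="rnf"),
                          decoder=common["decoder"],
                          loss=LossConfig(**shared_loss, mmd_weight=0.0,
                                          flow_penalty_weight=0.0),
                          train=common["train"])
        tg = g.fit(X, Y)
        tr = r.fit(X, Y)
        assert tg[0]["total"] == tr[0]["total"]

    def test_sampled_condition_entropy_positive_on_ambiguous_task(self):
        """A transformation type mapped to ≥2 conditions in training yields
        >0 sampling entropy (no posterior collapse at β = 0.001)."""
        from condvae.inference import sample_conditions

        scheme = tiny_scheme()
        rng = np.random.default_rng(0)
        n = 128
        X = np.repeat(rng.normal(size=(2, 5)), n // 2, axis=0)
        Y = np.zeros((n, 8))
        for i in range(n):
            cond = rng.integers(0, 2)      # two conditions per transformation
            Y[i, cond] = 1
            Y[i, 4 + cond] = 1
            Y[i, 6] = 1
        model = ConditionCVAE(
            scheme, 5,
            encoder=EncoderConfig(latent_dim=4, c_hidden=8, s_hidden=8),
            decoder=DecoderConfig(s_hidden=8, f_hidden=8, trunk_hidden=8,
                                  f_pretrain_epochs=5),
            train=TrainConfig(epochs=30, batch_size=32, seed=1))
        model.fit(X, Y)
        samples = sample_conditions(model, X[0], n_draws=400, seed=9)
        assert len(set(samples)) >= 2

    def test_model_save_load_roundtrip(self, tmp_path):
        model, X, Y = self.make(epochs=2)
        model.fit(X, Y)
        model.save(tmp_path / "ckpt")
        loaded = ConditionCVAE.load(tmp_path / "ckpt")
        rng = np.random.default_rng(0)
        z, x = rng.normal(size=(3, 4)), rng.normal(size=(3, 5))
        a = model.decode(z, x).catalyst_probs.data
        b = loaded.decode(z, x).catalyst_probs.data
        assert np.allclose(a, b)
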