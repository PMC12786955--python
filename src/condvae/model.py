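"""Conditional VAE over reaction conditions, with per-component output heads.

The encoder consumes both the condition vector y and the transformation
descriptor x: y passes through C_net (one hidden layer of 64 units,
Flatten-T Swish), x through S_net (one hidden layer of 512 units, same
activation); the concatenation feeds H_net, a linear map onto the posterior
parameters — (μ, σ) for the Gaussian and flow families, (μ, k) with μ
normalized to the unit sphere for the von Mises–Fisher family.

The decoder never sees y: it receives the latent draw z together with two
structural embeddings of x — a decoder-side S_net and the frozen, pre-trained
F_net (one hidden layer of 2000 ReLU units with sigmoid outputs over the
condition bits, trained beforehand as a multi-label condition predictor).
Four heads emit the condition blocks: softmax simplices for catalyst,
temperature and pressure, independent sigmoids for the additives.

The training objective is

    L = FL(catalyst) + AL(additives) + EMD(temperature) + EMD(pressure) + β·KL

with focal loss on the catalyst head, BCE or binary focal loss on the
additives (class-flag vs per-compound schemes), squared-CDF Earth-Mover's
distance on the two ordinal heads, and a β-weighted divergence to the prior.
Records with unknown temperature/pressure contribute exactly zero to the
corresponding ordinal term and propagate no gradient through that head. The
flow family adds an MMD alignment term and a flow-regularity penalty, and
anneals β from 0 to 0.8 across training; the other families keep β = 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .conditions import ConditionScheme
from .latent import (FlowStack, GaussianParams, VmfParams,
                     flow_transform, gaussian_kl, gaussian_sample, mmd,
                     vmf_kl_to_uniform, vmf_sample)
from .nn import Adam, FTSwish, Linear, MLP

__all__ = [
    "EncoderConfig", "DecoderConfig", "LossConfig", "TrainConfig",
    "HeadOutputs", "ConditionCVAE", "FNet",
    "focal_loss_softmax", "additive_loss", "emd_loss", "total_loss",
    "default_loss_config",
]

_P_CLAMP = 1e-7


# ======================================================================
# configs
# ======================================================================
@dataclass
class EncoderConfig:
    c_hidden: int = 64
    s_hidden: int = 512
    fts_threshold: float = -0.20
    latent_dim: int = 32
    family: str = "gaussian"            # gaussian | rnf | vmf

    def __post_init__(self):
        if self.family not in ("gaussian", "rnf", "vmf"):
            raise ValueError(f"unknown latent family {self.family!r}")
        if self.family == "vmf" and self.latent_dim < 2:
            raise ValueError("vMF needs latent dim ≥ 2")


@dataclass
class DecoderConfig:
    s_hidden: int = 512
    f_hidden: int = 2000
    trunk_hidden: int = 512     # shared dense layer feeding the four heads
    f_pretrain_epochs: int = 50
    use_f_net: bool = True


@dataclass
class LossConfig:
    gamma: float = 2.0
    alpha: float = 0.25
    emd_r: float = 2.0
    beta: float = 0.001
    beta_schedule: str = "constant"     # constant | linear (0 → beta_end)
    beta_end: float = 0.8
    additive_kind: str = "bce"          # bce | binary_focal
    mmd_weight: float = 0.0             # rnf only
    flow_penalty_weight: float = 0.0    # rnf only
    # hybrid objective: also reconstruct y from prior-drawn z (decoder
    # anchoring on the prior support, after the hybrid CVAE objective of the
    # conditional-generation literature); 0 disables
    prior_recon_weight: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.emd_r < 1.0:
            raise ValueError("emd_r must be ≥ 1")
        if self.beta < 0:
            raise ValueError("beta must be ≥ 0")


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 128
    lr_start: float = 1e-3
    lr_end: float = 2.5e-4              # linear decay across epochs
    n_flows: int = 3
    seed: int = 0


def default_loss_config(family: str, scheme_kind: str = "S") -> LossConfig:
    """Stock loss settings: BCE additives for class-flag (S-style) schemes,
    binary focal for per-compound (B-style) schemes; β = 0.001 constant for
    the gaussian and vMF families, 0 → 0.8 linear annealing plus MMD and a
    flow penalty for the flow family."""
    kind = "bce" if scheme_kind == "S" else "binary_focal"
    if family == "rnf":
        return LossConfig(beta=0.0, beta_schedule="linear", beta_end=0.8,
                          additive_kind=kind, mmd_weight=1.0,
                          flow_penalty_weight=0.1)
    return LossConfig(beta=0.001, additive_kind=kind)


@dataclass
class HeadOutputs:
    """Per-head probabilities; simplex blocks sum to 1 within 1e−6."""

    catalyst_probs: Tensor
    additive_probs: Tensor
    temp_probs: Tensor
    pressure_probs: Tensor

    def as_arrays(self):
        return (self.catalyst_probs.data, self.additive_probs.data,
                self.temp_probs.data, self.pressure_probs.data)


# ======================================================================
# losses
# ======================================================================
def _as_tensor(p) -> Tensor:
    return p if isinstance(p, Tensor) else Tensor(p)


def _check_one_hot(y: np.ndarray) -> None:
    if not np.all(np.isin(y, (0, 1))) or not np.allclose(y.sum(axis=-1), 1.0):
        raise ValueError("target must be one-hot")


def focal_loss_softmax(p, y, gamma: float = 2.0, alpha: float = 0.25) -> Tensor:
    """Softmax focal loss Σᵢ −α(1−pᵢ)^γ yᵢ log pᵢ, per row.

    Reduces to plain cross-entropy at γ = 0, α = 1. Probabilities are clamped
    to [1e−7, 1−1e−7] before the log.
    """
    p = _as_tensor(p)
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    p2 = p if p.ndim == 2 else p.reshape(1, -1)
    _check_one_hot(y)
    pc = p2.clip(_P_CLAMP, 1.0 - _P_CLAMP)
    term = (1.0 - pc) ** gamma * pc.log() * Tensor(y) * (-alpha)
    out = term.sum(axis=-1)
    return out if p.ndim == 2 else out.reshape(())


def additive_loss(p, y, kind: str = "bce", gamma: float = 2.0,
                  alpha: float = 0.25) -> Tensor:
    """Multi-hot additive loss per row: summed BCE, or binary focal loss
    with αᵢ = α for positive bits and 1−α for negative ones.

    Binary focal with γ = 0, α = 0.5 equals ½ × BCE.
    """
    p = _as_tensor(p)
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    p2 = p if p.ndim == 2 else p.reshape(1, -1)
    if p2.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p2.shape} vs targets {y.shape}")
    pc = p2.clip(_P_CLAMP, 1.0 - _P_CLAMP)
    yt = Tensor(y)
    # p_t: probability assigned to the true bit value
    pt = pc * yt + (1.0 - pc) * (1.0 - yt)
    pt = pt.clip(_P_CLAMP, 1.0 - _P_CLAMP)
    if kind == "bce":
        term = -pt.log()
    elif kind == "binary_focal":
        alpha_t = Tensor(np.where(y == 1, alpha, 1.0 - alpha))
        term = (1.0 - pt) ** gamma * pt.log() * alpha_t * (-1.0)
    else:
        raise ValueError(f"unknown additive loss kind {kind!r}")
    out = term.sum(axis=-1)
    return out if p.ndim == 2 else out.reshape(())


def emd_loss(p, y, r: float = 2.0) -> Tensor:
    """Earth-Mover's distance between CDFs of ordered class distributions.

    EMD = ((1/K) Σₖ |CDF_y(k) − CDF_p(k)|^r)^{1/r}, per row; zero when p = y,
    and larger for predictions further from the true bin — the ordinal
    penalty for the temperature and pressure heads.
    """
    p = _as_tensor(p)
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    p2 = p if p.ndim == 2 else p.reshape(1, -1)
    K = p2.shape[-1]
    if K < 2:
        raise ValueError("EMD needs at least 2 ordered classes")
    diff = p2.cumsum(axis=-1) - Tensor(np.cumsum(y, axis=-1))
    inner = ((diff.abs() + 1e-12) ** r).sum(axis=-1) * (1.0 / K)
    out = inner ** (1.0 / r)
    return out if p.ndim == 2 else out.reshape(())


def total_loss(outputs: HeadOutputs, target_bits: np.ndarray,
               kl: Tensor, cfg: LossConfig, beta: float,
               tp_mask: np.ndarray, scheme: ConditionScheme,
               extra: dict | None = None) -> tuple[Tensor, dict]:
    """Composite objective with per-term breakdown (batch means).

    `tp_mask` is (batch, 2) booleans (temperature known, pressure known);
    masked ordinal rows contribute exactly 0 and pass no gradient. `extra`
    may carry pre-weighted rnf terms ('mmd', 'flow_penalty') as Tensors.
    """
    y = np.atleast_2d(np.asarray(target_bits, dtype=np.float64))
    n = y.shape[0]
    mask = np.atleast_2d(np.asarray(tp_mask, dtype=bool))
    y_cat = y[:, scheme.catalyst_slice]
    y_add = y[:, scheme.additive_slice]
    y_t = y[:, scheme.temp_slice]
    y_p = y[:, scheme.pressure_slice]
    # one-hot check skipped for masked (all-zero) ordinal rows
    fl_cat = focal_loss_softmax(outputs.catalyst_probs, y_cat,
                                cfg.gamma, cfg.alpha).mean()
    al_add = additive_loss(outputs.additive_probs, y_add, cfg.additive_kind,
                           cfg.gamma, cfg.alpha).mean()

    def masked_emd(probs: Tensor, yy: np.ndarray, known: np.ndarray) -> Tensor:
        if not known.any():
            return Tensor(0.0)
        safe_y = np.where(known[:, None], yy, np.eye(yy.shape[1])[0])
        per_row = emd_loss(probs, safe_y, cfg.emd_r)
        return (per_row * Tensor(known.astype(np.float64))).sum() * (1.0 / n)

    emd_t = masked_emd(outputs.temp_probs, y_t, mask[:, 0])
    emd_p = masked_emd(outputs.pressure_probs, y_p, mask[:, 1])
    kl_mean = kl.mean() if kl.ndim else kl
    loss = fl_cat + al_add + emd_t + emd_p + kl_mean * beta
    breakdown = {"focal_catalyst": fl_cat.item(), "additive": al_add.item(),
                 "emd_temperature": emd_t.item(), "emd_pressure": emd_p.item(),
                 "kl": kl_mean.item(), "beta": beta}
    for name, term in (extra or {}).items():
        loss = loss + term
        breakdown[name] = term.item()
    breakdown["total"] = loss.item()
    return loss, breakdown


# ======================================================================
# F_net: pre-trained structural condition predictor (LRM architecture)
# ======================================================================
class FNet:
    """One hidden layer of `hidden` ReLU units, sigmoid outputs over all
    condition bits; trained as a multi-label predictor with summed BCE and
    then frozen. Its output enriches the decoder with a structure-conditioned
    prior guess of the condition bits."""

    def __init__(self, n_in: int, n_bits: int, hidden: int,
                 rng: np.random.Generator):
        self.net = MLP(n_in, hidden, n_bits, lambda t: t.relu(), rng)

    def pretrain(self, X: np.ndarray, Y: np.ndarray, epochs: int,
                 batch_size: int, rng: np.random.Generator,
                 lr: float = 1e-3) -> list[float]:
        opt = Adam(self.net.parameters, lr=lr)
        n = X.shape[0]
        trace = []
        for _ in range(epochs):
            order = rng.permutation(n)
            ep = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                p = self.net(Tensor(X[idx])).sigmoid().clip(_P_CLAMP, 1 - _P_CLAMP)
                yt = Tensor(Y[idx])
                pt = p * yt + (1.0 - p) * (1.0 - yt)
                loss = -(pt.clip(_P_CLAMP, 1 - _P_CLAMP).log()).sum() * (1.0 / len(idx))
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep += loss.item() * len(idx)
            trace.append(ep / n)
        return trace

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Frozen numpy forward (no autodiff graph)."""
        W1, b1 = self.net.fc1.W.data, self.net.fc1.b.data
        W2, b2 = self.net.fc2.W.data, self.net.fc2.b.data
        h = np.maximum(X @ W1 + b1, 0.0)
        logits = h @ W2 + b2
        return 1.0 / (1.0 + np.exp(-np.clip(logits, -500, 500)))


# ======================================================================
# the CVAE
# ======================================================================
class ConditionCVAE:
    """Conditional VAE generating condition vectors for a mapped reaction.

    Parameters
    ----------
    scheme : ConditionScheme
        Bit layout of the condition vectors (defines head sizes).
    descriptor_dim : int
        Length of the compressed transformation descriptor x.
    encoder, decoder, loss, train : config dataclasses
        See :class:`EncoderConfig` etc. When ``loss`` is None the stock
        configuration for the latent family is used.
    """

    def __init__(self, scheme: ConditionScheme, descriptor_dim: int,
                 encoder: EncoderConfig | None = None,
                 decoder: DecoderConfig | None = None,
                 loss: LossConfig | None = None,
                 train: TrainConfig | None = None):
        self.scheme = scheme
        self.descriptor_dim = descriptor_dim
        self.enc_cfg = encoder or EncoderConfig()
        self.dec_cfg = decoder or DecoderConfig()
        scheme_kind = "S" if self.scheme.name == "S" else "B"
        self.loss_cfg = loss or default_loss_config(self.enc_cfg.family, scheme_kind)
        self.train_cfg = train or TrainConfig()
        self.fitted = False
        self._build(np.random.default_rng(self.train_cfg.seed))

    # ------------------------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        m = self.enc_cfg.latent_dim
        n_bits = self.scheme.n_bits
        act = FTSwish(self.enc_cfg.fts_threshold)
        self.c_net = Linear(n_bits, self.enc_cfg.c_hidden, rng)
        self.s_net_enc = Linear(self.descriptor_dim, self.enc_cfg.s_hidden, rng)
        h_in = self.enc_cfg.c_hidden + self.enc_cfg.s_hidden
        n_out = m + 1 if self.enc_cfg.family == "vmf" else 2 * m
        self.h_net = Linear(h_in, n_out, rng)
        # posterior initialized at the prior: softplus(b) = 1 → σ ≈ 1 at start,
        # so early posteriors overlap and the decoder must lean on x, not on a
        # memorized latent partition
        if self.enc_cfg.family != "vmf":
            self.h_net.b.data[m:] = float(np.log(np.e - 1.0))
        self._act = act

        self.s_net_dec = Linear(self.descriptor_dim, self.dec_cfg.s_hidden, rng)
        self.f_net = FNet(self.descriptor_dim, n_bits, self.dec_cfg.f_hidden, rng)
        dec_in = m + self.dec_cfg.s_hidden + (n_bits if self.dec_cfg.use_f_net else 0)
        self.trunk = Linear(dec_in, self.dec_cfg.trunk_hidden, rng)
        s = self.scheme
        t_dim = self.dec_cfg.trunk_hidden
        self.head_catalyst = Linear(t_dim, len(s.catalyst_vocab), rng)
        self.head_additive = Linear(t_dim, len(s.additive_vocab), rng)
        self.head_temp = Linear(t_dim, len(s.temp_bins), rng)
        self.head_pressure = Linear(t_dim, len(s.pressure_bins), rng)
        self.flows = (FlowStack(m, self.train_cfg.n_flows, rng, identity_init=True)
                      if self.enc_cfg.family == "rnf" else None)

    @property
    def parameters(self) -> list[Tensor]:
        params = (self.c_net.parameters + self.s_net_enc.parameters
                  + self.h_net.parameters + self.s_net_dec.parameters
                  + self.trunk.parameters
                  + self.head_catalyst.parameters + self.head_additive.parameters
                  + self.head_temp.parameters + self.head_pressure.parameters)
        if self.flows is not None:
            params += self.flows.parameters
        return params

    # ------------------------------------------------------------------
    def encode(self, cond_bits: np.ndarray, x: np.ndarray):
        """Posterior parameters for (condition, descriptor) batches.

        Returns :class:`GaussianParams` for the gaussian/rnf families or
        :class:`VmfParams` for vmf (μ unit-normalized, k ≥ 0 via softplus).
        """
        y = Tensor(np.atleast_2d(cond_bits))
        xt = Tensor(np.atleast_2d(x))
        h = concat([self._act(self.c_net(y)), self._act(self.s_net_enc(xt))], axis=1)
        out = self.h_net(h)
        m = self.enc_cfg.latent_dim
        if self.enc_cfg.family == "vmf":
            mu_raw = out[:, :m]
            norm = ((mu_raw * mu_raw).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
            mu = mu_raw / norm
            k = out[:, m:].softplus().reshape(-1) + 1e-6
            return VmfParams(mu=mu, k=k)
        mu = out[:, :m]
        sigma = out[:, m:].softplus() + 1e-6
        return GaussianParams(mu=mu, sigma=sigma)

    def decode(self, z, x, f_out: np.ndarray | None = None) -> HeadOutputs:
        """Head probabilities for latent draws and descriptors.

        `z` may be a Tensor (training path) or array (inference); `f_out`
        optionally carries precomputed frozen F_net outputs for the batch.
        The frozen F_net output enters each head on the logit scale as a skip
        connection, so the decoder starts from the structure-conditional bit
        probabilities p(bits|x) and the latent and trunk refine them — this
        anchors the generated conditions to the query transformation instead
        of letting the latent shortcut dominate.
        """
        zt = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
        if zt.ndim == 1:
            zt = zt.reshape(1, -1)
        xt = Tensor(np.atleast_2d(x))
        pieces = [zt, self._act(self.s_net_dec(xt))]
        f_logit = None
        if self.dec_cfg.use_f_net:
            if f_out is None:
                f_out = self.f_net.predict(np.atleast_2d(x))
            f_out = np.clip(np.atleast_2d(f_out), _P_CLAMP, 1.0 - _P_CLAMP)
            f_logit = np.log(f_out / (1.0 - f_out))
            pieces.append(Tensor(np.atleast_2d(f_out)))
        h = self._act(self.trunk(concat(pieces, axis=1)))
        s = self.scheme

        def head(layer, block) -> Tensor:
            logits = layer(h)
            if f_logit is not None:
                logits = logits + Tensor(f_logit[:, block])
            return logits

        return HeadOutputs(
            catalyst_probs=head(self.head_catalyst, s.catalyst_slice).softmax(axis=-1),
            additive_probs=head(self.head_additive, s.additive_slice).sigmoid(),
            temp_probs=head(self.head_temp, s.temp_slice).softmax(axis=-1),
            pressure_probs=head(self.head_pressure, s.pressure_slice).softmax(axis=-1),
        )

    # ------------------------------------------------------------------
    def _beta_at(self, epoch: int) -> float:
        cfg, n = self.loss_cfg, self.train_cfg.epochs
        if cfg.beta_schedule == "linear":
            frac = epoch / max(n - 1, 1)
            return cfg.beta + (cfg.beta_end - cfg.beta) * frac
        return cfg.beta

    def _lr_at(self, epoch: int) -> float:
        cfg = self.train_cfg
        frac = epoch / max(cfg.epochs - 1, 1)
        return cfg.lr_start + (cfg.lr_end - cfg.lr_start) * frac

    def _latent_and_kl(self, posterior, rng: np.random.Generator):
        m = self.enc_cfg.latent_dim
        extra: dict = {}
        if self.enc_cfg.family == "vmf":
            sample = vmf_sample(posterior, rng)
            kl = vmf_kl_to_uniform(posterior)
            return sample, kl, extra
        eps = rng.standard_normal(posterior.mu.shape)
        sample = gaussian_sample(posterior, eps)
        kl = gaussian_kl(posterior)
        if self.enc_cfg.family == "rnf":
            sample = flow_transform(sample, self.flows)
            # density correction: log q(z_n) = log q0(z_0) − log|det|
            kl = kl - sample.log_det
            cfg = self.loss_cfg
            if cfg.mmd_weight > 0:
                prior0 = Tensor(rng.standard_normal(posterior.mu.shape))
                prior_z, _ = self.flows(prior0)
                extra["mmd"] = mmd(sample.z, prior_z) * cfg.mmd_weight
            if cfg.flow_penalty_weight > 0:
                extra["flow_penalty"] = ((sample.log_det ** 2.0).mean()
                                         * cfg.flow_penalty_weight)
        return sample, kl, extra

    def fit(self, X: np.ndarray, Y: np.ndarray, tp_mask: np.ndarray | None = None,
            log_stream=None, trace_path=None) -> list[dict]:
        """Train on descriptor/condition pairs; returns the per-epoch trace.

        X: (n, D) descriptors; Y: (n, n_bits) condition bits; tp_mask: (n, 2)
        booleans (temperature known, pressure known), all-known when omitted.
        Deterministic given ``train.seed``. Raises on NaN loss with the
        offending epoch/batch.
        """
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if len(X) == 0:
            raise ValueError("empty training set")
        if tp_mask is None:
            tp_mask = np.ones((len(X), 2), dtype=bool)
        tp_mask = np.asarray(tp_mask, dtype=bool)
        cfg = self.train_cfg
        rng = np.random.default_rng(cfg.seed + 1)
        if self.dec_cfg.use_f_net:
            self.f_net.pretrain(X, Y, self.dec_cfg.f_pretrain_epochs,
                                cfg.batch_size, rng)
            f_all = self.f_net.predict(X)
        else:
            f_all = None
        opt = Adam(self.parameters, lr=cfg.lr_start)
        n = len(X)
        trace: list[dict] = []
        for epoch in range(cfg.epochs):
            beta = self._beta_at(epoch)
            lr = self._lr_at(epoch)
            order = rng.permutation(n)
            sums: dict[str, float] = {}
            for bnum, start in enumerate(range(0, n, cfg.batch_size)):
                idx = order[start:start + cfg.batch_size]
                posterior = self.encode(Y[idx], X[idx])
                sample, kl, extra = self._latent_and_kl(posterior, rng)
                outputs = self.decode(sample.z, X[idx],
                                      None if f_all is None else f_all[idx])
                if self.loss_cfg.prior_recon_weight > 0:
                    z_prior = self.sample_prior(len(idx), rng)
                    out_prior = self.decode(z_prior, X[idx],
                                            None if f_all is None else f_all[idx])
                    prior_loss, _ = total_loss(
                        out_prior, Y[idx], Tensor(np.zeros(len(idx))),
                        self.loss_cfg, 0.0, tp_mask[idx], self.scheme)
                    extra["prior_recon"] = prior_loss * self.loss_cfg.prior_recon_weight
                loss, breakdown = total_loss(outputs, Y[idx], kl, self.loss_cfg,
                                             beta, tp_mask[idx], self.scheme,
                                             extra)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch}, batch {bnum}: {breakdown}")
                opt.zero_grad()
                loss.backward()
                opt.step(lr=lr)
                w = len(idx) / n
                for key, val in breakdown.items():
                    sums[key] = sums.get(key, 0.0) + val * w
            sums["epoch"] = epoch
            sums["lr"] = lr
            trace.append(sums)
            if log_stream is not None:
                terms = " ".join(f"{k}={v:.4f}" for k, v in sums.items()
                                 if k not in ("epoch", "lr", "beta"))
                print(f"epoch {epoch:3d} {terms}", file=log_stream)
        if trace_path is not None:
            _write_trace(trace_path, trace)
        self.fitted = True
        self.loss_trace = trace
        return trace

    # ------------------------------------------------------------------
    def sample_prior(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Prior latent draws: N(0,I) for gaussian; N(0,I) pushed through the
        flows for rnf; uniform on the sphere for vmf."""
        m = self.enc_cfg.latent_dim
        if self.enc_cfg.family == "vmf":
            v = rng.standard_normal((n_draws, m))
            return v / np.linalg.norm(v, axis=1, keepdims=True)
        z = rng.standard_normal((n_draws, m))
        if self.enc_cfg.family == "rnf":
            zt, _ = self.flows(Tensor(z))
            return zt.data
        return z


    # ------------------------------------------------------------------
    def _named_params(self) -> dict[str, Tensor]:
        named = {
            "c_net.W": self.c_net.W, "c_net.b": self.c_net.b,
            "s_enc.W": self.s_net_enc.W, "s_enc.b": self.s_net_enc.b,
            "h_net.W": self.h_net.W, "h_net.b": self.h_net.b,
            "s_dec.W": self.s_net_dec.W, "s_dec.b": self.s_net_dec.b,
            "trunk.W": self.trunk.W, "trunk.b": self.trunk.b,
            "f1.W": self.f_net.net.fc1.W, "f1.b": self.f_net.net.fc1.b,
            "f2.W": self.f_net.net.fc2.W, "f2.b": self.f_net.net.fc2.b,
        }
        for name, head in (("cat", self.head_catalyst), ("add", self.head_additive),
                           ("temp", self.head_temp), ("pres", self.head_pressure)):
            named[f"head_{name}.W"] = head.W
            named[f"head_{name}.b"] = head.b
        if self.flows is not None:
            for i, fl in enumerate(self.flows.flows):
                named[f"flow{i}.u"], named[f"flow{i}.w"], named[f"flow{i}.b"] = \
                    fl.u, fl.w, fl.b
        return named

    def save(self, path) -> None:
        """Write weights (.npz) plus a JSON sidecar with configs and scheme."""
        import dataclasses
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{k: v.data for k, v in self._named_params().items()})
        meta = {
            "descriptor_dim": self.descriptor_dim,
            "fitted": self.fitted,
            "encoder": dataclasses.asdict(self.enc_cfg),
            "decoder": dataclasses.asdict(self.dec_cfg),
            "loss": dataclasses.asdict(self.loss_cfg),
            "train": dataclasses.asdict(self.train_cfg),
            "scheme": {
                "catalyst_vocab": list(self.scheme.catalyst_vocab),
                "additive_vocab": list(self.scheme.additive_vocab),
                "temp_bins": list(self.scheme.temp_bins),
                "temp_edges": list(self.scheme.temp_edges),
                "pressure_bins": list(self.scheme.pressure_bins),
                "pressure_edges": list(self.scheme.pressure_edges),
                "forbid_acid_base_together": self.scheme.forbid_acid_base_together,
                "allow_unknown_tp": self.scheme.allow_unknown_tp,
                "name": self.scheme.name,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "ConditionCVAE":
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        scheme = ConditionScheme(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["scheme"].items()})
        model = cls(scheme, meta["descriptor_dim"],
                    encoder=EncoderConfig(**meta["encoder"]),
                    decoder=DecoderConfig(**meta["decoder"]),
                    loss=LossConfig(**meta["loss"]),
                    train=TrainConfig(**meta["train"]))
        with np.load(path.with_suffix(".npz")) as data:
            for name, tensor in model._named_params().items():
                tensor.data = data[name].copy()
        model.fitted = meta["fitted"]
        return model


def _write_trace(path, trace: list[dict]) -> None:
    keys = sorted({k for row in trace for k in row})
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for row in trace:
            fh.write("\t".join(f"{row.get(k, ''):.6g}" if isinstance(row.get(k), float)
                               else str(row.get(k, "")) for k in keys) + "\n")
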