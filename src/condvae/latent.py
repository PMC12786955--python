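"""Latent-space families for the condition-generating VAE.

Three posterior/prior pairs are supported:

* **gaussian** — diagonal Gaussian posterior ``N(μ, σ²)`` against a standard
  normal prior; reparameterized as ``z = μ + σ⊙ε``.
* **rnf** — the same Gaussian base followed by a stack of learnable planar
  normalizing flows ``z_n = f_n∘…∘f_1(z_0)``; the flow log-Jacobian enters
  the density, and an MMD term plus a flow penalty regularize training.
* **vmf** — von Mises–Fisher posterior on the unit hypersphere ``S^{m−1}``
  with mean direction μ (‖μ‖=1) and concentration k ≥ 0, against the uniform
  sphere distribution (the k = 0 limit). Sampling uses Wood's
  acceptance–rejection scheme for the cosine ω = μᵀz followed by a
  Householder rotation from the canonical axis to μ; gradients flow through
  the concentration via b(k) and through μ via the rotation, with the
  accepted Beta draw treated as a constant.

All samplers take an explicit ``numpy.random.Generator`` and are
deterministic given it. Functions operate on autodiff
:class:`~condvae.autodiff.Tensor` values so they can sit inside the training
graph; pass plain arrays wrapped in ``Tensor`` for numeric use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ive

from .autodiff import Tensor, concat

__all__ = [
    "GaussianParams", "VmfParams", "PlanarFlow", "FlowStack", "LatentSample",
    "gaussian_sample", "gaussian_kl", "flow_transform",
    "vmf_sample", "vmf_kl_to_uniform", "mmd",
    "log_sphere_area", "vmf_log_normalizer", "bessel_ratio",
]


@dataclass
class GaussianParams:
    mu: Tensor
    sigma: Tensor

    def __post_init__(self):
        if np.any(self.sigma.data <= 0):
            raise ValueError("sigma must be positive elementwise")


@dataclass
class VmfParams:
    mu: Tensor          # unit vectors, shape (batch, m)
    k: Tensor           # concentrations ≥ 0, shape (batch,)

    def __post_init__(self):
        norms = np.linalg.norm(self.mu.data, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("vMF mean directions must be unit vectors")
        if np.any(self.k.data < 0):
            raise ValueError("vMF concentration must be ≥ 0")


@dataclass
class LatentSample:
    z: Tensor
    eps: np.ndarray | None = None
    z0: Tensor | None = None
    log_det: Tensor | None = None


# ----------------------------------------------------------------------
# Gaussian
# ----------------------------------------------------------------------
def gaussian_sample(params: GaussianParams, eps: np.ndarray) -> LatentSample:
    """Reparameterized draw ``z = μ + σ⊙ε`` for externally supplied ε."""
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != params.mu.shape:
        raise ValueError(f"eps shape {eps.shape} != mu shape {params.mu.shape}")
    z = params.mu + params.sigma * Tensor(eps)
    return LatentSample(z=z, eps=eps)


def gaussian_kl(params: GaussianParams) -> Tensor:
    """Closed-form KL(N(μ,σ²) ‖ N(0,I)) summed over latent dims.

    Returns one value per batch row: ½ Σᵢ (μᵢ² + σᵢ² − 1 − ln σᵢ²).
    """
    mu, sigma = params.mu, params.sigma
    term = mu * mu + sigma * sigma - 1.0 - (sigma * sigma).log()
    return term.sum(axis=-1) * 0.5


# ----------------------------------------------------------------------
# Planar normalizing flows
# ----------------------------------------------------------------------
class PlanarFlow:
    """f(z) = z + u·tanh(wᵀz + b), log|det ∂f/∂z| = log|1 + (1−tanh²)(wᵀu)|.

    ``identity_init`` starts with u = 0 and b = 0, so the flow is exactly the
    identity with zero log-determinant — the limit in which the flow model
    reduces to the plain Gaussian one.
    """

    def __init__(self, m: int, rng: np.random.Generator, identity_init: bool = True):
        scale = 0.01
        self.u = Tensor(np.zeros(m) if identity_init else rng.normal(0, scale, m),
                        requires_grad=True)
        self.w = Tensor(rng.normal(0, scale, m), requires_grad=True)
        self.b = Tensor(0.0 if identity_init else rng.normal(0, scale),
                        requires_grad=True)

    def __call__(self, z: Tensor) -> tuple[Tensor, Tensor]:
        lin = (z * self.w).sum(axis=-1) + self.b          # (batch,)
        h = lin.tanh()
        z_out = z + h.reshape(-1, 1) * self.u
        psi_u = (1.0 - h * h) * (self.w * self.u).sum()   # (batch,)
        det = 1.0 + psi_u
        log_det = det.abs().clip(1e-12, np.inf).log()
        return z_out, log_det

    @property
    def parameters(self) -> list[Tensor]:
        return [self.u, self.w, self.b]


class FlowStack:
    """Composition of planar flows; total log-det is the sum over steps."""

    def __init__(self, m: int, n_flows: int, rng: np.random.Generator,
                 identity_init: bool = True):
        self.flows = [PlanarFlow(m, rng, identity_init) for _ in range(n_flows)]

    def __call__(self, z: Tensor) -> tuple[Tensor, Tensor]:
        total = Tensor(np.zeros(z.shape[0] if z.ndim == 2 else ()))
        for i, flow in enumerate(self.flows):
            z, ld = flow(z)
            if not np.all(np.isfinite(ld.data)):
                raise FloatingPointError(f"non-finite log-det at flow step {i}")
            total = total + ld
        return z, total

    def __len__(self):
        return len(self.flows)

    @property
    def parameters(self) -> list[Tensor]:
        return [p for f in self.flows for p in f.parameters]


def flow_transform(sample: LatentSample, flows: FlowStack) -> LatentSample:
    """Push a base sample through the flow stack, accumulating the log-det."""
    z0 = sample.z
    zn, log_det = flows(z0 if z0.ndim == 2 else z0.reshape(1, -1))
    if z0.ndim == 1:
        zn = zn.reshape(-1)
    return LatentSample(z=zn, eps=sample.eps, z0=z0, log_det=log_det)


# ----------------------------------------------------------------------
# von Mises–Fisher
# ----------------------------------------------------------------------
def log_sphere_area(m: int) -> float:
    """log surface area of the unit sphere S^{m−1} in R^m."""
    return np.log(2.0) + 0.5 * m * np.log(np.pi) - gammaln(0.5 * m)


def vmf_log_normalizer(k: np.ndarray, m: int) -> np.ndarray:
    """log C_m(k) with exponentially scaled Bessel functions for stability."""
    k = np.asarray(k, dtype=np.float64)
    v = 0.5 * m - 1.0
    out = np.empty_like(k)
    small = k < 1e-12
    out[small] = -log_sphere_area(m)
    ks = np.where(small, 1.0, k)
    log_iv = np.log(ive(v, ks)) + ks   # log I_v(k)
    out[~small] = (v * np.log(ks) - 0.5 * m * np.log(2.0 * np.pi) - log_iv)[~small]
    return out


def bessel_ratio(k: np.ndarray, m: int) -> np.ndarray:
    """I_{m/2}(k) / I_{m/2−1}(k) = E[μᵀz] under vMF(μ, k)."""
    k = np.asarray(k, dtype=np.float64)
    v = 0.5 * m - 1.0
    small = k < 1e-12
    ks = np.where(small, 1.0, k)
    r = ive(v + 1.0, ks) / ive(v, ks)
    return np.where(small, 0.0, r)


def vmf_kl_to_uniform(params: VmfParams) -> Tensor:
    """KL(vMF(μ,k) ‖ Uniform(S^{m−1})), per batch row, differentiable in k.

    KL = k·ρ(k) + log C_m(k) + log A(S^{m−1}) with ρ the Bessel ratio
    I_{m/2}/I_{m/2−1}. Zero at k = 0; gradient is k·ρ′(k) with
    ρ′ = 1 − ρ² − (m−1)ρ/k. Does not depend on μ.
    """
    m = params.mu.shape[-1]
    k = params.k
    k_data = np.asarray(k.data, dtype=np.float64)
    rho = bessel_ratio(k_data, m)
    value = k_data * rho + vmf_log_normalizer(k_data, m) + log_sphere_area(m)
    value = np.maximum(value, 0.0)
    if not np.all(np.isfinite(value)):
        raise FloatingPointError(
            "vMF KL overflow; use the exponentially scaled Bessel path (k too large?)")

    def bw(g):
        safe_k = np.where(k_data < 1e-12, 1.0, k_data)
        rho_prime = 1.0 - rho**2 - (m - 1.0) * rho / safe_k
        grad = np.where(k_data < 1e-12, 0.0, k_data * rho_prime)
        return (g * grad,)

    return k._make(value, (k,), bw)


_WOOD_MAX_ITER = 1000


def _wood_rejection(k: np.ndarray, m: int, rng: np.random.Generator,
                    max_iter: int = _WOOD_MAX_ITER) -> np.ndarray:
    """Accepted Beta((m−1)/2,(m−1)/2) draws ε for each concentration in `k`."""
    k = np.asarray(k, dtype=np.float64)
    n = k.shape[0]
    b = (-2.0 * k + np.sqrt(4.0 * k**2 + (m - 1.0) ** 2)) / (m - 1.0)
    x0 = (1.0 - b) / (1.0 + b)
    c = k * x0 + (m - 1.0) * np.log(1.0 - x0**2 + 1e-300)
    eps = np.empty(n)
    pending = np.ones(n, dtype=bool)
    a = 0.5 * (m - 1.0)
    for _ in range(max_iter):
        idx = np.flatnonzero(pending)
        if idx.size == 0:
            return eps
        z = rng.beta(a, a, size=idx.size)
        w = (1.0 - (1.0 + b[idx]) * z) / (1.0 - (1.0 - b[idx]) * z)
        u = rng.uniform(size=idx.size)
        accept = (k[idx] * w + (m - 1.0) * np.log(1.0 - x0[idx] * w + 1e-300)
                  - c[idx]) >= np.log(u + 1e-300)
        eps[idx[accept]] = z[accept]
        pending[idx[accept]] = False
    raise RuntimeError(f"vMF rejection sampler failed to accept within {max_iter} iterations")


def vmf_sample(params: VmfParams, rng: np.random.Generator) -> LatentSample:
    """One reparameterized vMF draw per batch row; unit norm within 1e−6.

    At k = 0 this reduces to the uniform distribution on the sphere.
    """
    mu, k = params.mu, params.k
    batch, m = mu.shape if mu.ndim == 2 else (1, mu.shape[0])
    if m < 2:
        raise ValueError("vMF requires latent dimension ≥ 2")
    mu2 = mu if mu.ndim == 2 else mu.reshape(1, -1)
    k2 = k if k.ndim == 1 else k.reshape(-1)
    k_data = np.broadcast_to(np.asarray(k2.data, dtype=np.float64), (batch,))

    eps = _wood_rejection(k_data, m, rng)                   # constants
    v = rng.normal(size=(batch, m - 1))
    v_hat = v / np.linalg.norm(v, axis=1, keepdims=True)

    # ω = (1 − (1+b)ε) / (1 − (1−b)ε), differentiable through b(k)
    b = ((-2.0) * k2 + (4.0 * k2 * k2 + (m - 1.0) ** 2) ** 0.5) * (1.0 / (m - 1.0))
    e = Tensor(eps)
    omega = (1.0 - (1.0 + b) * e) / (1.0 - (1.0 - b) * e)   # (batch,)
    radial = (1.0 - omega * omega).clip(0.0, 1.0) ** 0.5
    z_canon = concat([omega.reshape(-1, 1),
                      radial.reshape(-1, 1) * Tensor(v_hat)], axis=1)

    # Householder reflection mapping e1 to μ
    e1 = np.zeros(m)
    e1[0] = 1.0
    u = Tensor(e1) - mu2                                    # (batch, m)
    uu = (u * u).sum(axis=-1, keepdims=True) + 1e-30
    uz = (u * z_canon).sum(axis=-1, keepdims=True)
    z = z_canon - 2.0 * u * (uz / uu)
    if mu.ndim == 1:
        z = z.reshape(-1)
    return LatentSample(z=z, eps=eps)


# ----------------------------------------------------------------------
# Maximum Mean Discrepancy
# ----------------------------------------------------------------------
def mmd(x: Tensor, y: Tensor, bandwidths=(0.25, 0.5, 1.0, 2.0, 4.0)) -> Tensor:
    """Unbiased MMD² estimate with a mixture of RBF kernels.

    Bandwidth grid is scaled by the latent dimension (so the default grid
    behaves comparably across m). Zero in expectation when the two sample
    sets come from the same distribution; may be slightly negative on finite
    samples (unbiasedness).
    """
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != y.shape[1]:
        raise ValueError("mmd expects 2-D sample sets with equal dimensionality")
    nx, ny = x.shape[0], y.shape[0]
    if nx < 2 or ny < 2:
        raise ValueError("mmd needs at least 2 draws per set")
    m_dim = x.shape[1]

    def sq_dists(a: Tensor, bten: Tensor) -> Tensor:
        a2 = (a * a).sum(axis=1, keepdims=True)             # (na,1)
        b2 = (bten * bten).sum(axis=1, keepdims=True)       # (nb,1)
        ab = a @ _transpose(bten)
        return a2 + _transpose(b2) - 2.0 * ab

    dxx = sq_dists(x, x)
    dyy = sq_dists(y, y)
    dxy = sq_dists(x, y)

    total = Tensor(0.0)
    for bw in bandwidths:
        gamma = 1.0 / (2.0 * bw * m_dim)
        kxx = (dxx * (-gamma)).exp()
        kyy = (dyy * (-gamma)).exp()
        kxy = (dxy * (-gamma)).exp()
        sum_xx = kxx.sum() - Tensor(float(nx))      # remove unit diagonal
        sum_yy = kyy.sum() - Tensor(float(ny))
        total = total + (sum_xx * (1.0 / (nx * (nx - 1)))
                         + sum_yy * (1.0 / (ny * (ny - 1)))
                         - kxy.mean() * 2.0)
    return total * (1.0 / len(bandwidths))


def _transpose(t: Tensor) -> Tensor:
    def bw(g):
        return (np.transpose(g),)

    return t._make(np.transpose(t.data), (t,), bw)
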