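"""Latent-space denoising diffusion (DDPM) with classifier-free guidance.

The forward process adds Gaussian noise to latent codes over ``T`` steps
under a variance schedule beta_1..beta_T; the reverse process is ancestral
sampling driven by a learned noise predictor eps(z_t, t, c).  Conditional
and unconditional denoising share one network: during training the
condition label is dropped to a reserved null identifier with probability
``p_uncond``, and at sampling time the two estimates are combined as

    eps_guided = (1 + omega) * eps_cond - omega * eps_uncond

where ``omega`` sets the guidance strength (omega = 0 is purely conditional
sampling; large omega pushes samples outside the training distribution).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .nn import (Conv1d, Embedding, Linear, Module, Tensor, avg_pool2, cat,
                 sinusoidal_embedding, upsample2)

DEFAULT_T = 500
DEFAULT_BETA_LO = 1e-4
DEFAULT_BETA_HI = 0.02


@dataclass(frozen=True)
class DiffusionSchedule:
    """Variance schedule and all coefficients derived from it.

    Arrays are indexed ``t-1`` for timestep ``t`` in ``1..T``; the
    convention ``alpha_bar_0 := 1`` makes ``sigma_1 = 0`` so the final
    denoising step is deterministic.
    """

    beta: np.ndarray
    kind: str = "linear"

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim != 1 or beta.size < 1:
            raise ValueError("beta must be a 1-D array")
        if np.any(beta <= 0) or np.any(beta >= 1):
            raise ValueError("need 0 < beta_t < 1")
        object.__setattr__(self, "beta", beta)

    @property
    def T(self) -> int:
        return self.beta.size

    @property
    def alpha(self) -> np.ndarray:
        return 1.0 - self.beta

    @property
    def alpha_bar(self) -> np.ndarray:
        return np.cumprod(self.alpha)

    @property
    def alpha_bar_prev(self) -> np.ndarray:
        """alpha_bar_{t-1} with alpha_bar_0 := 1."""
        return np.concatenate([[1.0], self.alpha_bar[:-1]])

    @property
    def sigma(self) -> np.ndarray:
        var = (1.0 - self.alpha_bar_prev) / (1.0 - self.alpha_bar) * self.beta
        return np.sqrt(var)

    def _check_t(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=int)
        if np.any(t < 1) or np.any(t > self.T):
            raise ValueError(f"timestep out of range 1..{self.T}")
        return t


def make_schedule(T: int = DEFAULT_T, kind: str = "linear",
                  beta_lo: float = DEFAULT_BETA_LO,
                  beta_hi: float = DEFAULT_BETA_HI) -> DiffusionSchedule:
    """Build a variance schedule.

    ``linear`` ramps beta from ``beta_lo`` to ``beta_hi``; ``constant``
    holds beta at ``beta_lo`` for every step.  In either case the schedule
    is fixed, not learned.
    """
    if not (0 < beta_lo <= beta_hi < 1):
        raise ValueError("need 0 < beta_lo <= beta_hi < 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind == "linear":
        beta = np.linspace(beta_lo, beta_hi, T)
    elif kind == "constant":
        beta = np.full(T, beta_lo)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return DiffusionSchedule(beta=beta, kind=kind)


@dataclass(frozen=True)
class DiffusionConfig:
    """Schedule + noise-predictor hyperparameters (JSON section "diffusion")."""

    T: int = DEFAULT_T
    kind: str = "linear"
    beta_lo: float = DEFAULT_BETA_LO
    beta_hi: float = DEFAULT_BETA_HI
    p_uncond: float = 0.1
    base_channels: int = 32
    n_levels: int = 4
    cond_dim: int = 64

    def schedule(self) -> "DiffusionSchedule":
        return make_schedule(self.T, self.kind, self.beta_lo, self.beta_hi)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GuidanceSpec:
    """Classifier-free guidance settings; ``null_label`` encodes ∅."""

    omega: float = 0.0
    p_uncond: float = 0.1
    null_label: int = 8

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be nonnegative")
        if not 0 <= self.p_uncond <= 1:
            raise ValueError("p_uncond must lie in [0, 1]")


def q_sample(z0, t, eps, schedule: DiffusionSchedule):
    """One-shot forward marginal: z_t = sqrt(ab_t) z0 + sqrt(1-ab_t) eps.

    Equal in distribution to iterating the per-step noising kernel ``t``
    times.  Accepts numpy arrays or autodiff Tensors for ``z0`` (gradients
    flow through when the latent feeds the joint loss).
    """
    t = schedule._check_t(t)
    ab = schedule.alpha_bar[t - 1]
    a = np.sqrt(ab)
    b = np.sqrt(1.0 - ab)
    if np.ndim(a) == 1:
        a = a[:, None]
        b = b[:, None]
    eps = eps.data if isinstance(eps, Tensor) else np.asarray(eps)
    if isinstance(z0, Tensor):
        return z0 * Tensor(np.asarray(a)) + Tensor(b * eps)
    return a * np.asarray(z0) + b * eps


def ddpm_step(z_t: np.ndarray, t: int, eps_hat: np.ndarray,
              schedule: DiffusionSchedule, gamma: np.ndarray) -> np.ndarray:
    """One reverse ancestral step from z_t to z_{t-1}.

    z_{t-1} = (z_t - beta_t/sqrt(1-ab_t) * eps_hat)/sqrt(alpha_t) + sigma_t*gamma;
    sigma_1 = 0, so the last step adds no noise.
    """
    t = int(schedule._check_t(t))
    i = t - 1
    z_t = np.asarray(z_t, dtype=float)
    coef = schedule.beta[i] / np.sqrt(1.0 - schedule.alpha_bar[i])
    mean = (z_t - coef * np.asarray(eps_hat)) / np.sqrt(schedule.alpha[i])
    return mean + schedule.sigma[i] * np.asarray(gamma)


def guided_eps(eps_c, eps_u, omega: float):
    """Classifier-free combination (1 + omega)*eps_c - omega*eps_u."""
    eps_c = np.asarray(eps_c, dtype=float)
    eps_u = np.asarray(eps_u, dtype=float)
    if eps_c.shape != eps_u.shape:
        raise ValueError("conditional/unconditional estimates must share a shape")
    return (1.0 + omega) * eps_c - omega * eps_u


def condition_dropout(labels: np.ndarray, p_uncond: float,
                      rng: np.random.Generator, null_label: int) -> np.ndarray:
    """Independently replace each label by the null identifier w.p. p_uncond."""
    if not 0 <= p_uncond <= 1:
        raise ValueError("p_uncond must lie in [0, 1]")
    labels = np.asarray(labels, dtype=int).copy()
    drop = rng.random(labels.shape) < p_uncond
    labels[drop] = null_label
    return labels


def ldm_loss(predictor, z0, labels: np.ndarray, schedule: DiffusionSchedule,
             rng: np.random.Generator):
    """Denoising score-matching loss: E ||eps - eps_theta(z_t, t, c)||^2.

    ``t`` is drawn uniformly on 1..T per batch element and ``eps`` is
    standard normal; the squared norm is summed over latent dimensions and
    averaged over the batch.  ``labels`` must already have passed through
    :func:`condition_dropout`.
    """
    z0_arr = z0.data if isinstance(z0, Tensor) else np.asarray(z0)
    B = z0_arr.shape[0]
    t = rng.integers(1, schedule.T + 1, size=B)
    eps = rng.standard_normal(z0_arr.shape)
    z_t = q_sample(z0, t, eps, schedule)
    pred = predictor(z_t, t, labels)
    if not isinstance(pred, Tensor):
        pred = Tensor(pred)
    if not isinstance(z_t, Tensor):
        diff = pred - Tensor(eps)
    else:
        diff = pred - Tensor(eps)
    return (diff ** 2.0).sum(axis=-1).mean()


def ancestral_sample(predictor, schedule: DiffusionSchedule, n: int, dim: int,
                     label: int | None = None, null_label: int | None = None,
                     omega: float = 0.0, rng: np.random.Generator | None = None
                     ) -> np.ndarray:
    """Reverse the diffusion chain from z_T ~ N(0, I) down to z_0.

    With a label, the noise estimate is the classifier-free combination of
    the conditional and null-label predictions; without one, the null-label
    (unconditional) path is used alone.
    """
    rng = rng or np.random.default_rng()
    z = rng.standard_normal((n, dim))
    cond = np.full(n, null_label if label is None else label)
    null = np.full(n, null_label)
    for t in range(schedule.T, 0, -1):
        tb = np.full(n, t)
        eps_c = predictor(z, tb, cond)
        eps_c = eps_c.data if isinstance(eps_c, Tensor) else np.asarray(eps_c)
        if label is not None and omega != 0:
            eps_u = predictor(z, tb, null)
            eps_u = eps_u.data if isinstance(eps_u, Tensor) else np.asarray(eps_u)
            eps = guided_eps(eps_c, eps_u, omega)
        else:
            eps = eps_c
        z = ddpm_step(z, t, eps, schedule, rng.standard_normal((n, dim)))
    return z


def fit_noise_predictor(z0: np.ndarray, labels: np.ndarray, n_labels: int,
                        schedule: DiffusionSchedule, p_uncond: float = 0.1,
                        epochs: int = 60, batch_size: int = 128,
                        lr: float = 2e-3, seed: int = 0,
                        base_channels: int = 32, n_levels: int = 1,
                        cond_dim: int = 32) -> "UNet1D":
    """Train a UNet noise predictor directly on a labeled point cloud.

    Used for diffusion-only studies (e.g. recovering a known Gaussian
    mixture) where no autoencoder is involved; ``z0`` must be roughly
    unit-scale.
    """
    from ._rng import substream
    from .nn import AdamW, CosineAnnealingLR

    z0 = np.asarray(z0, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, dim = z0.shape
    unet = UNet1D(dim, n_labels, substream(seed, "init"), base_channels,
                  n_levels, cond_dim)
    opt = AdamW(unet.parameters(), lr=lr)
    lr_sched = CosineAnnealingLR(opt, t_max=epochs)
    shuffle = substream(seed, "shuffle")
    drop = substream(seed, "label-dropout")
    trng = substream(seed, "diffusion-t")
    bs = min(batch_size, n)
    for _ in range(epochs):
        order = shuffle.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            unet.zero_grad()
            dropped = condition_dropout(labels[idx], p_uncond, drop, n_labels)
            loss = ldm_loss(unet, z0[idx], dropped, schedule, trng)
            loss.backward()
            opt.step()
        lr_sched.step()
    unet.eval()
    return unet


class UNet1D(Module):
    """Small 1-D convolutional UNet noise predictor eps(z_t, t, c).

    The latent vector is treated as a one-channel signal; channels double at
    each of ``n_levels`` resolutions (halved by mean-pooling), with nearest-
    neighbour upsampling and skip connections on the way back.  Sinusoidal
    timestep features and a learned label embedding (the null identifier has
    its own row) are projected and added at every block.
    """

    def __init__(self, latent_dim: int, n_labels: int,
                 rng: np.random.Generator, base_channels: int = 32,
                 n_levels: int = 4, cond_dim: int = 64):
        super().__init__()
        # each level halves the length; keep at least 2 samples at the bottom
        max_levels = max(int(np.log2(max(latent_dim, 2))), 1)
        levels = min(n_levels, max_levels)
        while levels > 1 and latent_dim % (2 ** (levels - 1)):
            levels -= 1  # pooling halves the length, so it must divide evenly
        self.n_levels = levels
        self.latent_dim = latent_dim
        self.n_labels = n_labels
        self.null_label = n_labels
        self.cond_dim = cond_dim

        self.time_proj = Linear(cond_dim, cond_dim, rng)
        self.label_emb = Embedding(n_labels + 1, cond_dim, rng)

        chans = [base_channels * (2 ** i) for i in range(self.n_levels)]
        self.in_conv = Conv1d(1, chans[0], 3, rng)
        downs, down_cond = [], []
        for i in range(self.n_levels - 1):
            downs.append(Conv1d(chans[i], chans[i + 1], 3, rng))
            down_cond.append(Linear(cond_dim, chans[i + 1], rng))
        self.downs = downs
        self.down_cond = down_cond
        self.mid = Conv1d(chans[-1], chans[-1], 3, rng)
        self.mid_cond = Linear(cond_dim, chans[-1], rng)
        ups, up_cond = [], []
        for i in reversed(range(self.n_levels - 1)):
            ups.append(Conv1d(chans[i + 1] + chans[i], chans[i], 3, rng))
            up_cond.append(Linear(cond_dim, chans[i], rng))
        self.ups = ups
        self.up_cond = up_cond
        self.out_conv = Conv1d(chans[0], 1, 3, rng)

    def _cond(self, t: np.ndarray, labels: np.ndarray) -> Tensor:
        te = Tensor(sinusoidal_embedding(t, self.cond_dim))
        return self.time_proj(te).relu() + self.label_emb(labels)

    def forward(self, z_t, t, labels) -> Tensor:
        if not isinstance(z_t, Tensor):
            z_t = Tensor(np.asarray(z_t, dtype=float))
        B, D = z_t.shape
        t = np.broadcast_to(np.asarray(t, dtype=int), (B,))
        labels = np.broadcast_to(np.asarray(labels, dtype=int), (B,))
        if labels.max() > self.n_labels or labels.min() < 0:
            raise ValueError("label out of range (incl. null identifier)")
        cond = self._cond(t, labels)                       # (B, cond_dim)

        h = self.in_conv(z_t.reshape(B, 1, D)).relu()
        skips = []
        for conv, proj in zip(self.downs, self.down_cond):
            skips.append(h)
            h = avg_pool2(h)
            h = (conv(h) + proj(cond).reshape(B, -1, 1)).relu()
        h = (self.mid(h) + self.mid_cond(cond).reshape(B, -1, 1)).relu()
        for conv, proj, skip in zip(self.ups, self.up_cond, reversed(skips)):
            h = upsample2(h)
            h = cat([h, skip], axis=1)
            h = (conv(h) + proj(cond).reshape(B, -1, 1)).relu()
        return self.out_conv(h).reshape(B, D)
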