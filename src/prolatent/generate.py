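"""Joint training and conditional/unconditional sequence generation.

The training loop minimizes the sum of the autoencoder reconstruction
cross-entropy, the regressor squared error and the latent-diffusion
denoising loss.  The diffusion operates on latent codes standardized by an
exponential moving average of their batch statistics (refreshed exactly
over the training set at the end of training), so the noising process sees
roughly unit-scale inputs regardless of where the encoder puts its codes.

Sampling is ancestral: start from standard normal latents, denoise for
t = T..1 with the classifier-free-guided noise estimate, then decode the
final code and predict its fitness with the regressor.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._rng import substream
from .diffusion import (DiffusionConfig, DiffusionSchedule, UNet1D,
                        condition_dropout, ddpm_step, guided_eps, ldm_loss)
from .jtae import JTAEConfig, JTAEModel
from .nn import AdamW, CosineAnnealingLR, Tensor
from .nn.tensor import default_dtype
from .seqdata import (Alphabet, LabelBinning, SequenceDataset, SequenceRecord,
                      train_val_split)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 500
    batch_size: int = 512
    lr: float = 2e-5
    weight_decay: float = 0.0
    seed: int = 0
    detach_latents: bool = False
    val_fraction: float = 0.1
    grad_clip: float = 1.0
    ldm_weight: float = 1.0
    diffusion_refine_epochs: int = 0
    dtype: str = "float32"
    log_path: str | None = None

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.lr <= 0:
            raise ValueError("epochs, batch_size and lr must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenerationResult:
    sequences: list[SequenceRecord]
    predicted_fitness: np.ndarray
    omega: float
    label: int | None
    trajectory: np.ndarray | None = None          # (n, n_checkpoints)
    trajectory_steps: np.ndarray | None = None
    latents: np.ndarray | None = None


_CKPT_MAGIC = b"PROLATENT-CKPT-1\n"


class Checkpoint:
    """Live models plus everything needed to regenerate them bit-exactly."""

    def __init__(self, model: JTAEModel, unet: UNet1D, schedule: DiffusionSchedule,
                 jtae_config: JTAEConfig, diff_config: DiffusionConfig,
                 max_length: int, n_bins: int, latent_mean: np.ndarray,
                 latent_sd: np.ndarray, binning: LabelBinning | None = None,
                 loss_log: list[dict] | None = None):
        self.model = model
        self.unet = unet
        self.schedule = schedule
        self.jtae_config = jtae_config
        self.diff_config = diff_config
        self.max_length = max_length
        self.n_bins = n_bins
        self.latent_mean = np.asarray(latent_mean, dtype=float)
        self.latent_sd = np.asarray(latent_sd, dtype=float)
        self.binning = binning
        self.loss_log = loss_log or []

    @property
    def null_label(self) -> int:
        return self.n_bins

    @property
    def dtype(self) -> str:
        """Float dtype the parameters were trained in."""
        return str(self.model.parameters()[0].data.dtype)

    def save(self, path: str | Path) -> None:
        meta = {
            "jtae": self.jtae_config.to_dict(),
            "diffusion": self.diff_config.to_dict(),
            "max_length": self.max_length,
            "n_bins": self.n_bins,
            "binning": self.binning.to_dict() if self.binning else None,
            "alphabet": {"residues": self.model.alphabet.residues,
                         "pad": self.model.alphabet.pad_symbol,
                         "gap": self.model.alphabet.gap_symbol,
                         "unknown": self.model.alphabet.unknown_symbol},
            "loss_log": self.loss_log,
        }
        arrays = {"latent_mean": self.latent_mean, "latent_sd": self.latent_sd}
        arrays.update({"jtae:" + k: v for k, v in self.model.state_dict().items()})
        arrays.update({"unet:" + k: v for k, v in self.unet.state_dict().items()})
        meta["arrays"] = sorted(arrays)
        # plain length-prefixed container: byte-identical for identical state
        # (zip-based formats embed timestamps)
        with open(path, "wb") as fh:
            fh.write(_CKPT_MAGIC)
            blob = json.dumps(meta, sort_keys=True).encode()
            fh.write(len(blob).to_bytes(8, "little"))
            fh.write(blob)
            for name in meta["arrays"]:
                np.lib.format.write_array(fh, np.ascontiguousarray(arrays[name]),
                                          allow_pickle=False)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with open(path, "rb") as fh:
            if fh.read(len(_CKPT_MAGIC)) != _CKPT_MAGIC:
                raise ValueError(f"{path}: not a checkpoint file")
            n = int.from_bytes(fh.read(8), "little")
            meta = json.loads(fh.read(n).decode())
            arrays = {name: np.lib.format.read_array(fh, allow_pickle=False)
                      for name in meta["arrays"]}
        jtae_cfg = JTAEConfig(**meta["jtae"])
        diff_cfg = DiffusionConfig(**meta["diffusion"])
        alph = meta["alphabet"]
        alphabet = Alphabet(alph["residues"], alph["pad"], alph["gap"],
                            alph["unknown"])
        rng = np.random.default_rng(0)   # placeholder init, overwritten below
        model = JTAEModel(jtae_cfg, meta["max_length"], rng, alphabet)
        unet = UNet1D(jtae_cfg.latent_dim, meta["n_bins"], rng,
                      diff_cfg.base_channels, diff_cfg.n_levels, diff_cfg.cond_dim)
        model.load_state_dict({k[5:]: v for k, v in arrays.items()
                               if k.startswith("jtae:")})
        unet.load_state_dict({k[5:]: v for k, v in arrays.items()
                              if k.startswith("unet:")})
        model.eval()
        unet.eval()
        binning = (LabelBinning.from_dict(meta["binning"])
                   if meta["binning"] else None)
        return cls(model, unet, diff_cfg.schedule(), jtae_cfg, diff_cfg,
                   meta["max_length"], meta["n_bins"], arrays["latent_mean"],
                   arrays["latent_sd"], binning, meta["loss_log"])

    # -- latent standardization -------------------------------------------
    def normalize(self, z: np.ndarray) -> np.ndarray:
        return (z - self.latent_mean) / self.latent_sd

    def denormalize(self, zn: np.ndarray) -> np.ndarray:
        return zn * self.latent_sd + self.latent_mean


def _clip_gradients(params, max_norm: float) -> None:
    total = math.sqrt(sum(float((p.grad ** 2).sum())
                          for p in params if p.grad is not None))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def train(dataset: SequenceDataset, jtae_cfg: JTAEConfig,
          diff_cfg: DiffusionConfig, train_cfg: TrainConfig) -> Checkpoint:
    """Train the full model on a (labeled or unlabeled) dataset.

    Unlabeled datasets are handled in unsupervised mode: fitness and labels
    are taken as 0 everywhere, which reduces the regression term to a
    bounded constant target.  Raises on an empty dataset and aborts with a
    diagnostic if any loss term goes non-finite.
    """
    with default_dtype(train_cfg.dtype):
        return _train_impl(dataset, jtae_cfg, diff_cfg, train_cfg)


def _train_impl(dataset: SequenceDataset, jtae_cfg: JTAEConfig,
                diff_cfg: DiffusionConfig, train_cfg: TrainConfig) -> Checkpoint:
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    seed = train_cfg.seed
    max_length = dataset.max_length

    y = dataset.fitness_array()
    if np.isnan(y).all():
        y = np.zeros(len(dataset))
    elif np.isnan(y).any():
        raise ValueError("mixed labeled/unlabeled records are not supported")
    labels = dataset.label_array()
    n_bins = dataset.n_bins

    if len(dataset) >= 10 and train_cfg.val_fraction > 0:
        ds_train, ds_val = train_val_split(dataset, train_cfg.val_fraction,
                                           seed=seed)
    else:
        ds_train, ds_val = dataset, None

    tok_train = ds_train.tokens(max_length)
    y_train = np.nan_to_num(ds_train.fitness_array())
    lab_train = ds_train.label_array()

    init_rng = substream(seed, "init")
    model = JTAEModel(jtae_cfg, max_length, init_rng, dataset.alphabet)
    unet = UNet1D(jtae_cfg.latent_dim, n_bins, init_rng,
                  diff_cfg.base_channels, diff_cfg.n_levels, diff_cfg.cond_dim)
    schedule = diff_cfg.schedule()

    params = model.parameters() + unet.parameters()
    opt = AdamW(params, lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    sched = CosineAnnealingLR(opt, t_max=train_cfg.epochs)

    shuffle_rng = substream(seed, "shuffle")
    drop_rng = substream(seed, "label-dropout")
    t_rng = substream(seed, "diffusion-t")

    mu = np.zeros(jtae_cfg.latent_dim)
    sd = np.ones(jtae_cfg.latent_dim)
    ema = 0.1

    n = tok_train.shape[0]
    bs = min(train_cfg.batch_size, n)
    loss_log: list[dict] = []
    log_file = (open(train_cfg.log_path, "a")
                if train_cfg.log_path else None)
    try:
        for epoch in range(train_cfg.epochs):
            order = shuffle_rng.permutation(n)
            sums = np.zeros(3)
            n_batches = 0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                model.zero_grad()
                unet.zero_grad()
                recon, reg, z = model.losses(tok_train[idx], y_train[idx],
                                             detach_latents=False)
                # standardize latents for the diffusion branch
                zb = z.data
                mu = (1 - ema) * mu + ema * zb.mean(axis=0)
                sd = (1 - ema) * sd + ema * (zb.std(axis=0) + 1e-6)
                z_in = z.detach() if train_cfg.detach_latents else z
                zn = (z_in - Tensor(mu)) * Tensor(1.0 / sd)
                dropped = condition_dropout(lab_train[idx], diff_cfg.p_uncond,
                                            drop_rng, null_label=n_bins)
                ldm = ldm_loss(unet, zn, dropped, schedule, t_rng)
                total = recon + reg + train_cfg.ldm_weight * ldm
                terms = {"recon": float(recon.data), "regression": float(reg.data),
                         "ldm": float(ldm.data)}
                for name, v in terms.items():
                    if not np.isfinite(v):
                        raise RuntimeError(
                            f"non-finite {name} loss at epoch {epoch}")
                total.backward()
                _clip_gradients(params, train_cfg.grad_clip)
                opt.step()
                sums += [terms["recon"], terms["regression"], terms["ldm"]]
                n_batches += 1
            sched.step()
            entry = {"epoch": epoch, "recon": sums[0] / n_batches,
                     "regression": sums[1] / n_batches,
                     "ldm": sums[2] / n_batches, "lr": opt.lr}
            loss_log.append(entry)
            if log_file:
                log_file.write(json.dumps(entry) + "\n")
                log_file.flush()
    finally:
        if log_file:
            log_file.close()

    # exact latent statistics over the full training set, eval mode
    model.eval()
    unet.eval()
    z_all = model.encode(tok_train).data
    mu = z_all.mean(axis=0)
    sd = z_all.std(axis=0) + 1e-6

    # optional second stage: refine the noise predictor on the frozen,
    # fully standardized latents (cheap epochs, autoencoder untouched)
    if train_cfg.diffusion_refine_epochs > 0:
        unet.train()
        zn_all = (z_all - mu) / sd
        ropt = AdamW(unet.parameters(), lr=train_cfg.lr,
                     weight_decay=train_cfg.weight_decay)
        rsched = CosineAnnealingLR(ropt, t_max=train_cfg.diffusion_refine_epochs)
        for epoch in range(train_cfg.diffusion_refine_epochs):
            order = shuffle_rng.permutation(n)
            sums = 0.0
            n_batches = 0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                unet.zero_grad()
                dropped = condition_dropout(lab_train[idx], diff_cfg.p_uncond,
                                            drop_rng, null_label=n_bins)
                ldm = ldm_loss(unet, zn_all[idx], dropped, schedule, t_rng)
                if not np.isfinite(ldm.data):
                    raise RuntimeError(f"non-finite ldm loss in refine epoch {epoch}")
                ldm.backward()
                _clip_gradients(unet.parameters(), train_cfg.grad_clip)
                ropt.step()
                sums += float(ldm.data)
                n_batches += 1
            rsched.step()
            loss_log.append({"epoch": train_cfg.epochs + epoch,
                             "stage": "diffusion-refine",
                             "ldm": sums / n_batches, "lr": ropt.lr})
        unet.eval()
    return Checkpoint(model, unet, schedule, jtae_cfg, diff_cfg, max_length,
                      n_bins, mu, sd, dataset.binning, loss_log)


def sample_latents(ckpt: Checkpoint, label: int | None, omega: float, n: int,
                   seed: int, snapshot_every: int = 0
                   ) -> tuple[np.ndarray, list[tuple[int, np.ndarray]]]:
    """Ancestral sampling of ``n`` latent codes conditioned on ``label``.

    ``label=None`` samples unconditionally (the null identifier); otherwise
    the guided estimate combines the conditional and unconditional
    predictions with strength ``omega`` (omega = 0 is purely conditional).
    Returns de-standardized codes plus optional (t, z_t) snapshots.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if label is not None and not 0 <= label < ckpt.n_bins:
        raise ValueError(f"unknown label {label!r} (0..{ckpt.n_bins - 1})")
    with default_dtype(ckpt.dtype):
        return _sample_latents_impl(ckpt, label, omega, n, seed, snapshot_every)


def _sample_latents_impl(ckpt, label, omega, n, seed, snapshot_every):
    ckpt.model.eval()
    ckpt.unet.eval()
    rng = substream(seed, "sampling")
    D = ckpt.jtae_config.latent_dim
    sched = ckpt.schedule
    z = rng.standard_normal((n, D))
    snaps: list[tuple[int, np.ndarray]] = []
    cond = np.full(n, ckpt.null_label if label is None else label)
    null = np.full(n, ckpt.null_label)
    for t in range(sched.T, 0, -1):
        tb = np.full(n, t)
        eps_c = ckpt.unet(z, tb, cond).data
        if label is not None and omega != 0:
            eps_u = ckpt.unet(z, tb, null).data
            eps = guided_eps(eps_c, eps_u, omega)
        else:
            eps = eps_c
        gamma = rng.standard_normal((n, D))
        if snapshot_every and (t % snapshot_every == 0 or t == sched.T):
            # predicted-z0 convention: invert the forward marginal with the
            # current noise estimate before handing the code to the regressor
            ab = sched.alpha_bar[t - 1]
            z0_hat = (z - np.sqrt(1.0 - ab) * eps) / np.sqrt(ab)
            snaps.append((t, ckpt.denormalize(z0_hat)))
        z = ddpm_step(z, t, eps, sched, gamma)
    z0 = ckpt.denormalize(z)
    if snapshot_every:
        snaps.append((0, z0))
    return z0, snaps


def generate_sequences(ckpt: Checkpoint, label: int | None, omega: float,
                       n: int, seed: int, trajectory_every: int = 0
                       ) -> GenerationResult:
    """Sample latents, decode them and predict their fitness.

    With ``trajectory_every`` set, the regressor is also applied to the
    intermediate latents every that many timesteps, tracing how predicted
    fitness converges over the denoising process; its final column equals
    the prediction on the fully denoised code.
    """
    z0, snaps = sample_latents(ckpt, label, omega, n, seed,
                               snapshot_every=trajectory_every)
    _, seqs = ckpt.model.decode(z0)
    fitness = ckpt.model.predict_fitness(z0).data
    records = [SequenceRecord(f"gen{k:05d}", s, fitness=float(fitness[k]),
                              label=label)
               for k, s in enumerate(seqs)]
    trajectory = steps = None
    if trajectory_every:
        steps = np.array([t for t, _ in snaps])
        trajectory = np.stack(
            [ckpt.model.predict_fitness(zt).data for _, zt in snaps], axis=1)
    return GenerationResult(records, fitness, omega, label,
                            trajectory=trajectory, trajectory_steps=steps,
                            latents=z0)


def predict_sequence_fitness(ckpt: Checkpoint, sequences: list[str]) -> np.ndarray:
    """Regressor prediction for explicit sequences (encode, then regress).

    ``GenerationResult.predicted_fitness`` applies the regressor to the raw
    sampled latent; for sequences sampled far outside the training
    distribution (large guidance strength) that code can leave the domain
    the regressor was fitted on.  Re-encoding the decoded sequence keeps the
    regressor on the encoder's output manifold, which is the calibrated way
    to score a designed sequence.
    """
    from .seqdata import tokenize
    toks = np.stack([tokenize(s, ckpt.model.alphabet, ckpt.max_length)
                     for s in sequences])
    ckpt.model.eval()
    with default_dtype(ckpt.dtype):
        return ckpt.model.predict_fitness(ckpt.model.encode(toks)).data.copy()


def project_latents(codes: np.ndarray, n_components: int = 2
                    ) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores of latent codes via SVD, with a fixed sign convention.

    In each component the loading of largest magnitude is made positive, so
    projections are deterministic.  Returns (scores, explained variance
    ratio).
    """
    codes = np.asarray(codes, dtype=float)
    if codes.ndim != 2 or codes.shape[0] < 2:
        raise ValueError("need at least 2 codes")
    if n_components > min(codes.shape):
        raise ValueError("more components than data support")
    centered = codes - codes.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    for i in range(n_components):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    scores = U[:, :n_components] * S[:n_components]
    var = S ** 2
    ratio = (var / var.sum())[:n_components] if var.sum() > 0 else var[:n_components]
    return scores, ratio
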