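"""Jointly trained autoencoder: transformer encoder, conv decoder, regressor.

The encoder embeds tokenized sequences (learned positional embeddings),
runs them through a pre-norm transformer with pad positions masked out of
attention, mean-pools the non-pad positions and projects through a single
fully connected bottleneck to the latent code ``z``.  A 1-D convolutional
decoder reconstructs per-position residue scores from ``z`` and an MLP
regressor predicts scalar fitness from the same code, so the latent space
is shaped simultaneously by sequence content and fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import (BatchNorm1d, Conv1d, Dropout, Embedding, LayerNorm, Linear,
                 Module, Tensor, TransformerEncoderLayer, log_softmax)
from .seqdata import Alphabet, detokenize


@dataclass(frozen=True)
class JTAEConfig:
    """Architecture hyperparameters (defaults follow the published setup)."""

    embed_dim: int = 100
    model_dim: int = 200
    n_heads: int = 4
    n_layers: int = 6
    latent_dim: int = 64
    decoder_layers: int = 4
    decoder_channels: int = 64
    decoder_hidden: int = 256
    regressor_hidden: int = 64
    regressor_dropout: float = 0.2
    ffn_mult: int = 2

    def __post_init__(self) -> None:
        if self.model_dim % self.n_heads:
            raise ValueError("model_dim must be divisible by n_heads")
        if min(self.embed_dim, self.model_dim, self.n_heads, self.n_layers,
               self.latent_dim, self.decoder_layers) < 1:
            raise ValueError("all dimensions must be positive")
        if not 0 <= self.regressor_dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


class JTAEModel(Module):
    def __init__(self, config: JTAEConfig, max_length: int,
                 rng: np.random.Generator, alphabet: Alphabet | None = None):
        super().__init__()
        self.config = config
        self.max_length = max_length
        self.alphabet = alphabet or Alphabet()
        V = self.alphabet.size
        c = config

        self.token_emb = Embedding(V, c.embed_dim, rng)
        self.pos_emb = Embedding(max_length, c.embed_dim, rng)
        self.in_proj = Linear(c.embed_dim, c.model_dim, rng)
        self.blocks = [TransformerEncoderLayer(c.model_dim, c.n_heads,
                                               c.ffn_mult * c.model_dim, rng)
                       for _ in range(c.n_layers)]
        self.enc_norm = LayerNorm(c.model_dim)
        self.bottleneck = Linear(c.model_dim, c.latent_dim, rng)

        # decoder: z -> hidden -> (channels x L) feature map -> conv stack
        self.dec_hidden = Linear(c.latent_dim, c.decoder_hidden, rng)
        self.dec_fc = Linear(c.decoder_hidden, c.decoder_channels * max_length, rng)
        convs, norms = [], []
        for i in range(c.decoder_layers - 1):
            convs.append(Conv1d(c.decoder_channels, c.decoder_channels, 3, rng))
            norms.append(BatchNorm1d(c.decoder_channels))
        convs.append(Conv1d(c.decoder_channels, V, 3, rng))
        self.dec_convs = convs
        self.dec_norms = norms

        self.reg_fc1 = Linear(c.latent_dim, c.regressor_hidden, rng)
        self.reg_drop = Dropout(c.regressor_dropout, rng)
        self.reg_fc2 = Linear(c.regressor_hidden, 1, rng)

    # -- encoder -----------------------------------------------------------
    def encode(self, tokens: np.ndarray) -> Tensor:
        """Map tokenized sequences (B, max_length) to latent codes (B, latent_dim).

        Pad positions are masked out of attention and excluded from the mean
        pooling feeding the bottleneck, so appending extra padding never
        changes a sequence's code.
        """
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.ndim != 2:
            raise ValueError("tokens must be a (batch, length) matrix")
        if tokens.max(initial=0) >= self.alphabet.size or tokens.min(initial=0) < 0:
            raise ValueError("token id out of vocabulary")
        B, L = tokens.shape
        if L != self.max_length:
            raise ValueError(f"expected length {self.max_length}, got {L}")
        mask = tokens != self.alphabet.pad_code           # (B, L) valid positions
        h = self.token_emb(tokens) + self.pos_emb(np.arange(L))
        h = self.in_proj(h)
        for block in self.blocks:
            h = block(h, mask)
        h = self.enc_norm(h)
        m = mask[:, :, None].astype(float)
        denom = np.maximum(mask.sum(axis=1, keepdims=True), 1).astype(float)
        pooled = (h * Tensor(m)).sum(axis=1) * Tensor(1.0 / denom)
        return self.bottleneck(pooled)

    # -- decoder -----------------------------------------------------------
    def decode_scores(self, z: Tensor | np.ndarray) -> Tensor:
        """Per-position scores over the full vocabulary, shape (B, L, V)."""
        if not isinstance(z, Tensor):
            z = Tensor(np.asarray(z, dtype=float))
        if z.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"latent width {z.shape[-1]} != {self.config.latent_dim}")
        B = z.shape[0]
        h = self.dec_fc(self.dec_hidden(z).relu())
        h = h.reshape(B, self.config.decoder_channels, self.max_length)
        for conv, norm in zip(self.dec_convs[:-1], self.dec_norms):
            h = norm(conv(h).relu())
        h = self.dec_convs[-1](h)                          # (B, V, L)
        return h.transpose(0, 2, 1)

    def decode(self, z: Tensor | np.ndarray) -> tuple[Tensor, list[str]]:
        """Scores plus argmax sequences (ties -> lowest token index,
        trailing pads stripped)."""
        scores = self.decode_scores(z)
        codes = np.argmax(scores.data, axis=-1)            # first max wins ties
        seqs = [detokenize(row, self.alphabet) for row in codes]
        return scores, seqs

    # -- regressor ---------------------------------------------------------
    def predict_fitness(self, z: Tensor | np.ndarray) -> Tensor:
        if not isinstance(z, Tensor):
            z = Tensor(np.asarray(z, dtype=float))
        if z.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"latent width {z.shape[-1]} != {self.config.latent_dim}")
        h = self.reg_drop(self.reg_fc1(z).relu())
        return self.reg_fc2(h).reshape(z.shape[0])

    # -- losses --------------------------------------------------------------
    def losses(self, tokens: np.ndarray, fitness: np.ndarray,
               detach_latents: bool = False
               ) -> tuple[Tensor, Tensor, Tensor]:
        """Reconstruction and regression terms, plus the latent batch.

        Reconstruction is mean token-level cross-entropy between decoder
        scores and the input tokens (the discrete realization of the
        sequence reconstruction error); regression is mean squared error of
        the predicted fitness.
        """
        tokens = np.asarray(tokens, dtype=np.int64)
        fitness = np.asarray(fitness, dtype=float)
        if fitness.shape[0] != tokens.shape[0]:
            raise ValueError("fitness / tokens batch mismatch")
        z = self.encode(tokens)
        scores = self.decode_scores(z)
        B, L, V = scores.shape
        ls = log_softmax(scores, axis=-1)
        idx = (np.arange(B)[:, None], np.arange(L)[None, :], tokens)
        recon = -(ls[idx].mean())
        yhat = self.predict_fitness(z.detach() if detach_latents else z)
        reg = ((yhat - Tensor(fitness)) ** 2.0).mean()
        return recon, reg, z


def jtae_loss(model: JTAEModel, tokens: np.ndarray, fitness: np.ndarray
              ) -> tuple[Tensor, Tensor]:
    """The two non-diffusion terms of the joint training objective."""
    recon, reg, _ = model.losses(tokens, fitness)
    return recon, reg
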