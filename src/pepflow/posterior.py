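"""Amortized approximate posterior q(z | y, x).

The target peptide is embedded with a trainable residue embedding, a random
third of the token embeddings is replaced by a learned mask vector during
training (masked-LM-style dropout that prevents the latent from collapsing to
a per-token copy), and a transformer with cross-attention to the spectrum
embedding emits per-position diagonal-Gaussian parameters over the latent
sequence.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import DecoderLayer, Embedding, Linear, Module, Parameter, Tensor

__all__ = ["PosteriorNetwork", "gaussian_log_density", "sample_diagonal_gaussian"]

SIGMA_FLOOR = 1e-4
LOG_2PI = math.log(2.0 * math.pi)


def gaussian_log_density(z: Tensor, mu: Tensor, sigma: Tensor) -> Tensor:
    """Elementwise diagonal-Gaussian log density log N(z; mu, sigma^2)."""
    return (
        (-0.5 * LOG_2PI) - sigma.log() - 0.5 * ((z - mu) / sigma) ** 2
    )


def sample_diagonal_gaussian(
    mu: Tensor, sigma: Tensor, rng: np.random.Generator
) -> Tensor:
    """Reparameterized sample z = mu + sigma * eps."""
    eps = rng.standard_normal(mu.shape)
    return mu + sigma * eps


class PosteriorNetwork(Module):
    def __init__(
        self,
        vocab_size: int,
        d_model: int,
        d_z: int,
        n_layers: int,
        n_heads: int,
        ffn_mult: int,
        max_len: int,
        rng: np.random.Generator,
        dropout_rate: float = 0.33,
    ):
        if not 0 <= dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.dropout_rate = dropout_rate
        self.token_emb = Embedding(vocab_size, d_model, rng)
        self.mask_vector = Parameter(rng.normal(0.0, 0.02, size=(d_model,)))
        self.pos_emb = Embedding(max_len, d_model, rng)
        self.layers = [
            DecoderLayer(d_model, n_heads, ffn_mult * d_model, rng)
            for _ in range(n_layers)
        ]
        self.mu_head = Linear(d_model, d_z, rng)
        self.sigma_head = Linear(d_model, d_z, rng)

    def __call__(
        self,
        token_ids: np.ndarray,
        token_mask: np.ndarray,
        x: Tensor,
        x_mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Per-position (mu, sigma), each (B, T, d_z); sigma strictly positive.

        ``token_mask`` marks model positions (true peptide residues plus the
        sentinel padding up to the minimum supported length).
        """
        B, T = token_ids.shape
        if T == 0:
            raise ValueError("empty target sequence")
        h = self.token_emb(token_ids)
        if training and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("token dropout requires an rng during training")
            drop = (rng.random((B, T)) < self.dropout_rate) & token_mask
            dropf = drop[..., None].astype(float)
            h = h * (1.0 - dropf) + self.mask_vector * dropf
        h = h + self.pos_emb(np.arange(T))
        for layer in self.layers:
            h = layer(h, x, self_mask=token_mask, memory_mask=x_mask)
        mu = self.mu_head(h)
        sigma = self.sigma_head(h).softplus() + SIGMA_FLOOR
        return mu, sigma

    @staticmethod
    def log_q(
        z: Tensor, mu: Tensor, sigma: Tensor, token_mask: np.ndarray
    ) -> Tensor:
        """Per-sample log q(z | y, x), summed over valid positions and latent
        dimensions."""
        dens = gaussian_log_density(z, mu, sigma)
        return (dens * token_mask[..., None].astype(float)).sum(axis=(-1, -2))
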