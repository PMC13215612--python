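"""Conditional normalizing flow over the latent sequence: p(z | x).

A stack of reversible steps, each composed of actnorm, an invertible
multi-head linear map and an affine coupling layer conditioned on the spectrum
embedding. The forward direction maps latents z to base-space variables u and
accumulates the exact log|det| of the Jacobian, giving

    log p(z | x) = log p_base(f(z)) + log|det df/dz|;

the inverse direction turns base samples into latents (generation).

Conventions:
  * coupling scales are parameterized as exp(tanh(raw) * clamp), strictly
    positive with bounded log-determinant, so invertibility can never break;
  * the three coupling partition patterns (time-alternating, contiguous
    features, alternating features) cycle across steps, the transformed /
    untransformed roles swap every step, and the multi-head linear alternates
    contiguous vs strided head splits;
  * actnorm is data-dependently initialized on the first training batch so the
    transformed activations have zero mean and unit variance per feature.

Padded positions of a batch never contribute to log-determinants or base
densities, and the coupling conditioning networks mask them out of attention.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import (
    DecoderLayer,
    Embedding,
    Linear,
    Module,
    Parameter,
    Tensor,
    concatenate,
    no_grad,
    slogdet_abs,
)

__all__ = [
    "ActNorm",
    "MultiHeadInvertibleLinear",
    "AffineCoupling",
    "FlowStep",
    "PriorFlow",
    "COUPLING_PATTERNS",
]

LOG_2PI = math.log(2.0 * math.pi)
COUPLING_PATTERNS = ("time", "feature_cont", "feature_alt")


def _valid_lengths(token_mask: np.ndarray) -> np.ndarray:
    return token_mask.sum(axis=1).astype(float)


class ActNorm(Module):
    """Per-feature affine normalization with data-dependent initialization."""

    def __init__(self, d_z: int):
        self.scale = Parameter(np.ones(d_z))
        self.shift = Parameter(np.zeros(d_z))
        self.initialized = False  # serialized with the checkpoint

    def _maybe_init(self, z: Tensor, token_mask: np.ndarray) -> None:
        m = token_mask[..., None].astype(float)
        n = max(float(m.sum()), 1.0)
        mean = (z.data * m).sum(axis=(0, 1)) / n
        var = (((z.data - mean) ** 2) * m).sum(axis=(0, 1)) / n
        std = np.sqrt(var + 1e-6)
        self.scale.data = 1.0 / std
        self.shift.data = -mean / std
        self.initialized = True

    def forward(
        self, z: Tensor, token_mask: np.ndarray, training: bool = False
    ) -> tuple[Tensor, Tensor]:
        if training and not self.initialized:
            self._maybe_init(z, token_mask)
        if np.any(self.scale.data == 0.0):
            raise ValueError("actnorm scale contains zeros; map not invertible")
        out = z * self.scale + self.shift
        log_abs_s = (0.5 * (self.scale**2).log()).sum()
        logdet = log_abs_s * _valid_lengths(token_mask)
        return out, logdet

    def inverse(self, z: Tensor, token_mask: np.ndarray) -> Tensor:
        return (z - self.shift) / self.scale


class MultiHeadInvertibleLinear(Module):
    """Blockwise invertible linear map: features are split into ``h`` heads
    (contiguously or strided, alternating across steps) and each head is
    multiplied by its own d_h x d_h matrix. log|det| is the sum of the head
    log-determinants times the sequence length."""

    def __init__(self, d_z: int, n_heads: int, rng: np.random.Generator,
                 scheme: str = "contiguous"):
        if d_z % n_heads:
            raise ValueError("n_heads must divide d_z")
        if scheme not in ("contiguous", "strided"):
            raise ValueError(f"unknown head split scheme {scheme!r}")
        self.d_z, self.h = d_z, n_heads
        self.d_head = d_z // n_heads
        self.scheme = scheme
        # random rotations: orthogonal init keeps the map well-conditioned
        mats = []
        for _ in range(n_heads):
            q, _ = np.linalg.qr(rng.standard_normal((self.d_head, self.d_head)))
            mats.append(q)
        self.weight = Parameter(np.stack(mats))
        if scheme == "contiguous":
            self.perm = np.arange(d_z)
        else:
            self.perm = np.arange(d_z).reshape(self.d_head, n_heads).T.reshape(-1)
        self.inv_perm = np.argsort(self.perm)

    def _head_logdets(self) -> Tensor:
        total = None
        for i in range(self.h):
            ld = slogdet_abs(self.weight[i])
            total = ld if total is None else total + ld
        return total

    def forward(
        self, z: Tensor, token_mask: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        B, T, _ = z.shape
        dets = np.linalg.det(self.weight.data)
        if np.any(np.abs(dets) < 1e-12):
            raise ValueError("numerically singular head matrix")
        zp = z[..., self.perm].reshape(B, T, self.h, self.d_head)
        zp = zp.transpose((0, 2, 1, 3))  # (B, h, T, d_head)
        out = zp @ self.weight  # broadcast over (B, h)
        out = out.transpose((0, 2, 1, 3)).reshape(B, T, self.d_z)
        out = out[..., self.inv_perm]
        logdet = self._head_logdets() * _valid_lengths(token_mask)
        return out, logdet

    def inverse(self, z: Tensor, token_mask: np.ndarray) -> Tensor:
        B, T, _ = z.shape
        inv = np.linalg.inv(self.weight.data)
        zp = z.data[..., self.perm].reshape(B, T, self.h, self.d_head)
        zp = zp.transpose((0, 2, 1, 3)) @ inv
        out = zp.transpose((0, 2, 1, 3)).reshape(B, T, self.d_z)
        return Tensor(out[..., self.inv_perm])


class _CouplingNet(Module):
    """A single (configurable-depth) transformer decoder block computing the
    coupling scale/shift from the untouched partition, with cross-attention to
    the spectrum embedding. The output projection starts at zero so a fresh
    coupling layer is the identity."""

    def __init__(self, d_in: int, d_out: int, d_model: int, n_heads: int,
                 ffn_mult: int, n_layers: int, max_len: int,
                 rng: np.random.Generator):
        self.in_proj = Linear(d_in, d_model, rng)
        self.pos_emb = Embedding(max_len, d_model, rng)
        self.layers = [
            DecoderLayer(d_model, n_heads, ffn_mult * d_model, rng)
            for _ in range(n_layers)
        ]
        self.out_proj = Linear(d_model, d_out, rng)
        self.out_proj.weight.data[:] = 0.0
        self.out_proj.bias.data[:] = 0.0

    def __call__(self, za: Tensor, positions: np.ndarray, a_mask: np.ndarray,
                 x: Tensor, x_mask: np.ndarray) -> Tensor:
        h = self.in_proj(za) + self.pos_emb(positions)
        for layer in self.layers:
            h = layer(h, x, self_mask=a_mask, memory_mask=x_mask)
        return self.out_proj(h)


class AffineCoupling(Module):
    """Affine coupling layer: one partition passes through unchanged, the
    other is scaled and shifted by functions of the first (and the spectrum).

    ``pattern`` selects the split: "time" (even vs odd sequence positions),
    "feature_cont" (first vs second half of the features) or "feature_alt"
    (even vs odd features). ``swap_roles`` exchanges which partition is
    transformed.
    """

    def __init__(self, d_z: int, pattern: str, swap_roles: bool, d_model: int,
                 n_heads: int, ffn_mult: int, n_layers: int, max_len: int,
                 rng: np.random.Generator, clamp: float = 2.0):
        if pattern not in COUPLING_PATTERNS:
            raise ValueError(f"unknown coupling pattern {pattern!r}")
        if pattern != "time" and d_z < 2:
            raise ValueError("feature couplings need d_z >= 2")
        self.pattern = pattern
        self.swap_roles = swap_roles
        self.d_z = d_z
        self.clamp = clamp
        if pattern == "time":
            d_in, d_out = d_z, 2 * d_z
        else:
            if pattern == "feature_cont":
                ia = np.arange(0, (d_z + 1) // 2)
                ib = np.arange((d_z + 1) // 2, d_z)
            else:
                ia = np.arange(0, d_z, 2)
                ib = np.arange(1, d_z, 2)
            if swap_roles:
                ia, ib = ib, ia
            self.feat_a, self.feat_b = ia, ib
            perm = np.concatenate([ia, ib])
            self.feat_inv_perm = np.argsort(perm)
            d_in, d_out = len(ia), 2 * len(ib)
        self.net = _CouplingNet(
            d_in, d_out, d_model, n_heads, ffn_mult, n_layers, max_len, rng
        )

    # -- splits ------------------------------------------------------------
    def _time_split_idx(self, T: int) -> tuple[np.ndarray, np.ndarray]:
        a_idx, b_idx = np.arange(0, T, 2), np.arange(1, T, 2)
        if self.swap_roles:
            a_idx, b_idx = b_idx, a_idx
        return a_idx, b_idx

    def _scale_shift(self, za: Tensor, positions: np.ndarray,
                     a_mask: np.ndarray, x: Tensor, x_mask: np.ndarray,
                     n_b_rows: int) -> tuple[Tensor, Tensor, Tensor]:
        raw = self.net(za, positions, a_mask, x, x_mask)
        if self.pattern == "time":
            n_a_rows = raw.shape[1]
            if n_b_rows <= n_a_rows:
                raw = raw[:, :n_b_rows, :]
            else:
                # odd T with swapped roles: the extra z_b row reuses the last
                # conditioning row
                idx = np.minimum(np.arange(n_b_rows), n_a_rows - 1)
                raw = raw[:, idx, :]
        half = raw.shape[-1] // 2
        pre = raw[..., :half].tanh() * self.clamp
        shift = raw[..., half:]
        return pre.exp(), shift, pre  # (scale, shift, log scale)

    def _apply(self, z: Tensor, token_mask: np.ndarray, x: Tensor,
               x_mask: np.ndarray, inverse: bool) -> tuple[Tensor, Tensor | None]:
        B, T, _ = z.shape
        if self.pattern == "time":
            a_idx, b_idx = self._time_split_idx(T)
            za, zb = z[:, a_idx, :], z[:, b_idx, :]
            a_mask = token_mask[:, a_idx]
            scale, shift, logs = self._scale_shift(
                za, a_idx, a_mask, x, x_mask, len(b_idx)
            )
            zb_new = (zb - shift) / scale if inverse else scale * zb + shift
            order = np.argsort(np.concatenate([a_idx, b_idx]))
            out = concatenate([za, zb_new], axis=1)[:, order, :]
            b_valid = token_mask[:, b_idx][..., None].astype(float)
        else:
            za, zb = z[..., self.feat_a], z[..., self.feat_b]
            positions = np.arange(T)
            scale, shift, logs = self._scale_shift(
                za, positions, token_mask, x, x_mask, T
            )
            zb_new = (zb - shift) / scale if inverse else scale * zb + shift
            out = concatenate([za, zb_new], axis=-1)[..., self.feat_inv_perm]
            b_valid = token_mask[..., None].astype(float)
        if inverse:
            return out, None
        logdet = (logs * b_valid).sum(axis=(-1, -2))
        return out, logdet

    def forward(self, z: Tensor, token_mask: np.ndarray, x: Tensor,
                x_mask: np.ndarray) -> tuple[Tensor, Tensor]:
        return self._apply(z, token_mask, x, x_mask, inverse=False)

    def inverse(self, z: Tensor, token_mask: np.ndarray, x: Tensor,
                x_mask: np.ndarray) -> Tensor:
        out, _ = self._apply(z, token_mask, x, x_mask, inverse=True)
        return out


class FlowStep(Module):
    """actnorm -> invertible multi-head linear -> affine coupling."""

    def __init__(self, d_z: int, n_heads_flow: int, pattern: str,
                 swap_roles: bool, linear_scheme: str, d_model: int,
                 n_heads_attn: int, ffn_mult: int, cond_layers: int,
                 max_len: int, rng: np.random.Generator, clamp: float = 2.0):
        self.actnorm = ActNorm(d_z)
        self.linear = MultiHeadInvertibleLinear(d_z, n_heads_flow, rng, linear_scheme)
        self.coupling = AffineCoupling(
            d_z, pattern, swap_roles, d_model, n_heads_attn, ffn_mult,
            cond_layers, max_len, rng, clamp,
        )

    def forward(self, z, token_mask, x, x_mask, training=False):
        z, ld1 = self.actnorm.forward(z, token_mask, training)
        z, ld2 = self.linear.forward(z, token_mask)
        z, ld3 = self.coupling.forward(z, token_mask, x, x_mask)
        return z, ld1 + ld2 + ld3

    def inverse(self, z, token_mask, x, x_mask):
        z = self.coupling.inverse(z, token_mask, x, x_mask)
        z = self.linear.inverse(z, token_mask)
        z = self.actnorm.inverse(z, token_mask)
        return z


class PriorFlow(Module):
    """The full conditional flow: a stack of steps cycling through the three
    coupling patterns with alternating roles and head-split schemes."""

    def __init__(self, d_z: int, n_steps: int, n_heads_flow: int,
                 d_model: int, n_heads_attn: int, ffn_mult: int,
                 cond_layers: int, max_len: int, rng: np.random.Generator,
                 clamp: float = 2.0):
        self.d_z = d_z
        self.steps = [
            FlowStep(
                d_z,
                n_heads_flow,
                pattern=COUPLING_PATTERNS[i % 3],
                swap_roles=bool(i % 2),
                linear_scheme=("contiguous" if i % 2 == 0 else "strided"),
                d_model=d_model,
                n_heads_attn=n_heads_attn,
                ffn_mult=ffn_mult,
                cond_layers=cond_layers,
                max_len=max_len,
                rng=rng,
                clamp=clamp,
            )
            for i in range(n_steps)
        ]

    # -- density -----------------------------------------------------------
    def forward(self, z: Tensor, token_mask: np.ndarray, x: Tensor,
                x_mask: np.ndarray, training: bool = False) -> tuple[Tensor, Tensor]:
        logdet: Tensor | float = 0.0
        for step in self.steps:
            z, ld = step.forward(z, token_mask, x, x_mask, training)
            logdet = ld + logdet
        if not isinstance(logdet, Tensor):
            logdet = Tensor(np.zeros(z.shape[0]))
        return z, logdet

    def inverse(self, u: Tensor, token_mask: np.ndarray, x: Tensor,
                x_mask: np.ndarray) -> Tensor:
        for step in reversed(self.steps):
            u = step.inverse(u, token_mask, x, x_mask)
        return u

    def log_prob(self, z: Tensor, token_mask: np.ndarray, x: Tensor,
                 x_mask: np.ndarray, training: bool = False) -> Tensor:
        """Per-sample log p(z | x) under a standard-normal base."""
        u, logdet = self.forward(z, token_mask, x, x_mask, training)
        m = token_mask[..., None].astype(float)
        base = ((-0.5 * LOG_2PI - 0.5 * u**2) * m).sum(axis=(-1, -2))
        return base + logdet

    def sample(self, x: Tensor, x_mask: np.ndarray, token_mask: np.ndarray,
               rng: np.random.Generator, noise_scale: float = 1.0,
               family: str = "normal") -> Tensor:
        """Draw base noise, scale it, and pull it back through the flow."""
        if noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        B, T = token_mask.shape
        if family == "normal":
            u = rng.standard_normal((B, T, self.d_z)) * noise_scale
        elif family == "uniform":
            # matched standard deviation: U(-sqrt(3) s, sqrt(3) s)
            lim = math.sqrt(3.0) * noise_scale
            u = rng.uniform(-lim, lim, size=(B, T, self.d_z))
        else:
            raise ValueError(f"unknown base family {family!r}")
        with no_grad():
            z = self.inverse(Tensor(u), token_mask, x, x_mask)
        return z

    # -- actnorm bookkeeping -----------------------------------------------
    def actnorm_flags(self) -> list[bool]:
        return [s.actnorm.initialized for s in self.steps]

    def set_actnorm_flags(self, flags: list[bool]) -> None:
        for s, f in zip(self.steps, flags):
            s.actnorm.initialized = bool(f)
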