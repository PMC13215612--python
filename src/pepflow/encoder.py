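"""Spectrum encoder: sinusoidal m/z encoding plus a transformer over peaks.

Each peak is embedded as (fixed sinusoidal encoding of its m/z) + (a learned
linear map of its intensity), then contextualized by self-attention encoder
layers. Padded peak slots are excluded through the attention mask, so outputs
at real peaks never depend on padding.
"""

from __future__ import annotations

import numpy as np

from .nn import EncoderLayer, Linear, Module, Tensor
from .spectra import Spectrum

__all__ = ["encode_mz", "SpectrumEncoder", "SpectrumBatch"]

LAMBDA_MIN = 0.001
LAMBDA_MAX = 10_000.0


def encode_mz(
    mz: float | np.ndarray,
    d: int,
    lam_min: float = LAMBDA_MIN,
    lam_max: float = LAMBDA_MAX,
) -> np.ndarray:
    """Fixed sinusoidal encoding of m/z values into ``d`` dimensions.

    The first d/2 components are sines, the last d/2 cosines, with wavelengths
    interpolated geometrically between ``lam_min`` and ``lam_max`` (so the
    angular divisor of component ``i`` is ``lam_i / (2*pi)``). Deterministic,
    no trainable parameters.
    """
    if d % 2:
        raise ValueError("embedding width d must be even")
    mz = np.asarray(mz, dtype=np.float64)
    half = d // 2
    exponents = np.arange(half) / max(half - 1, 1)
    wavelengths = lam_min * (lam_max / lam_min) ** exponents  # lam_min .. lam_max
    divisor = wavelengths / (2.0 * np.pi)
    angles = mz[..., None] / divisor
    return np.concatenate([np.sin(angles), np.cos(angles)], axis=-1)


class SpectrumBatch:
    """Padded peak arrays for a batch of spectra."""

    def __init__(self, spectra: list[Spectrum], pad_to: int | None = None):
        if any(sp.n_peaks == 0 for sp in spectra):
            raise ValueError("cannot encode an empty spectrum")
        n_max = max(sp.n_peaks for sp in spectra)
        if pad_to is not None:
            n_max = max(n_max, pad_to)
        B = len(spectra)
        self.mz = np.zeros((B, n_max))
        self.intensity = np.zeros((B, n_max))
        self.mask = np.zeros((B, n_max), dtype=bool)
        for i, sp in enumerate(spectra):
            n = sp.n_peaks
            self.mz[i, :n] = sp.mz
            self.intensity[i, :n] = sp.intensity
            self.mask[i, :n] = True
        self.precursor_mz = np.array([sp.precursor_mz for sp in spectra])
        self.precursor_charge = np.array(
            [sp.precursor_charge for sp in spectra], dtype=np.int64
        )
        self.spectra = spectra

    def __len__(self) -> int:
        return len(self.spectra)


class SpectrumEncoder(Module):
    """Transformer encoder mapping a peak list to per-peak embeddings."""

    def __init__(
        self,
        d_model: int,
        n_layers: int,
        n_heads: int,
        ffn_mult: int,
        rng: np.random.Generator,
    ):
        self.d_model = d_model
        self.intensity_proj = Linear(1, d_model, rng)
        self.layers = [
            EncoderLayer(d_model, n_heads, ffn_mult * d_model, rng)
            for _ in range(n_layers)
        ]

    def __call__(self, batch: SpectrumBatch) -> tuple[Tensor, np.ndarray]:
        """Returns (embeddings (B, N, d), validity mask (B, N))."""
        pos = encode_mz(batch.mz, self.d_model)  # constant w.r.t. parameters
        inten = Tensor(batch.intensity[..., None])
        x = self.intensity_proj(inten) + pos
        # zero out padded rows so they carry no signal besides being masked
        x = x * batch.mask[..., None].astype(float)
        for layer in self.layers:
            x = layer(x, batch.mask)
        return x, batch.mask
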