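"""Non-autoregressive decoding head and the length-offset classifier.

The decoder maps the latent sequence (plus the spectrum embedding) to
independent per-position distributions over the vocabulary, using transformer
decoder layers *without* causal masking, so every position sees the whole
latent sequence. Sequence length is predicted up front as an offset from the
mean supported length (48), one of 49 classes spanning -24..24; peptides
shorter than the minimum supported length are represented by padding the
target with the sentinel token, which the decoder learns to emit and which is
stripped from outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import DecoderLayer, Embedding, Linear, Module, Tensor, log_softmax

__all__ = ["NARDecoder", "LengthClassifier", "LengthPrediction",
           "MEAN_LENGTH", "MAX_OFFSET", "MIN_MODEL_LENGTH", "MAX_MODEL_LENGTH",
           "model_length"]

MEAN_LENGTH = 48
MAX_OFFSET = 24
N_LENGTH_CLASSES = 2 * MAX_OFFSET + 1  # 49
MIN_MODEL_LENGTH = MEAN_LENGTH - MAX_OFFSET  # 24
MAX_MODEL_LENGTH = MEAN_LENGTH + MAX_OFFSET  # 72


def model_length(peptide_length: int) -> int:
    """Model-side sequence length for a peptide: lengths below the supported
    minimum are padded up with the sentinel token."""
    if peptide_length > MAX_MODEL_LENGTH:
        raise ValueError(
            f"peptide length {peptide_length} exceeds the supported maximum "
            f"{MAX_MODEL_LENGTH}"
        )
    return max(peptide_length, MIN_MODEL_LENGTH)


@dataclass
class LengthPrediction:
    offset: int  # argmax offset in [-24, 24]
    log_probs: np.ndarray  # (B, 49) class log-probabilities

    @property
    def predicted_length(self) -> int:
        return MEAN_LENGTH + self.offset

    def top_lengths(self, r: int, row: int = 0) -> list[int]:
        order = np.argsort(self.log_probs[row])[::-1][:r]
        return [MEAN_LENGTH + (int(c) - MAX_OFFSET) for c in order]


class NARDecoder(Module):
    def __init__(self, vocab_size: int, d_z: int, d_model: int, n_layers: int,
                 n_heads: int, ffn_mult: int, max_len: int,
                 rng: np.random.Generator):
        self.in_proj = Linear(d_z, d_model, rng)
        self.pos_emb = Embedding(max_len, d_model, rng)
        self.layers = [
            DecoderLayer(d_model, n_heads, ffn_mult * d_model, rng)
            for _ in range(n_layers)
        ]
        self.vocab_proj = Linear(d_model, vocab_size, rng)

    def __call__(self, z: Tensor, token_mask: np.ndarray, x: Tensor,
                 x_mask: np.ndarray, cond: Tensor | None = None) -> Tensor:
        """Per-position vocabulary log-probabilities, shape (B, T, |V|).

        ``cond`` is an optional (B, 1, d_model) conditioning bias (e.g. a
        precursor embedding) added to every position of the decoder input.
        """
        B, T, _ = z.shape
        h = self.in_proj(z) + self.pos_emb(np.arange(T))
        if cond is not None:
            h = h + cond
        for layer in self.layers:
            h = layer(h, x, self_mask=token_mask, memory_mask=x_mask)
        return log_softmax(self.vocab_proj(h), axis=-1)


class LengthClassifier(Module):
    """Max-pool the spectrum embedding over peaks, then classify the offset of
    the sequence length from the mean supported length."""

    def __init__(self, d_model: int, rng: np.random.Generator):
        self.proj = Linear(d_model, N_LENGTH_CLASSES, rng)

    def __call__(self, x: Tensor, x_mask: np.ndarray) -> Tensor:
        """Class log-probabilities over the 49 offsets, shape (B, 49)."""
        # push padded peaks to -inf before the max so they cannot win
        neg = np.where(x_mask, 0.0, -1e9)[..., None]
        pooled = (x + neg).max(axis=1)
        return log_softmax(self.proj(pooled), axis=-1)

    def predict(self, x: Tensor, x_mask: np.ndarray) -> LengthPrediction:
        lp = self(x, x_mask).data
        offset = int(lp[0].argmax()) - MAX_OFFSET
        return LengthPrediction(offset=offset, log_probs=lp)

    @staticmethod
    def target_classes(model_lengths: np.ndarray) -> np.ndarray:
        """Offset-class index for each model-side sequence length."""
        cls = np.asarray(model_lengths) - MEAN_LENGTH + MAX_OFFSET
        if np.any((cls < 0) | (cls >= N_LENGTH_CLASSES)):
            raise ValueError("model length outside the supported range")
        return cls.astype(np.int64)
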