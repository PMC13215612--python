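"""Model assembly: spectrum encoder + posterior + prior flow + NAR decoder +
length classifier, with configuration presets and checkpoint (de)serialization.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .constants import PROTON_MASS, WATER_MASS
from .decoder import (
    LengthClassifier,
    NARDecoder,
    model_length,
)
from .encoder import SpectrumBatch, SpectrumEncoder, encode_mz
from .flow import PriorFlow
from .masses import AminoAcidVocabulary, Peptide, precursor_neutral_mass
from .nn import Embedding, Linear, Module, Tensor
from .posterior import PosteriorNetwork
from .spectra import MAX_CHARGE

__all__ = ["ModelConfig", "PepFlowModel", "TargetBatch", "make_target_batch"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The defaults are the desk-scale preset (small enough to train on a single
    CPU in minutes); :meth:`full_scale` is a production-width preset.
    """

    d_model: int = 64
    d_z: int = 32
    n_enc_layers: int = 2
    n_post_layers: int = 2
    n_dec_layers: int = 2
    n_heads: int = 4
    ffn_mult: int = 2
    n_flow_steps: int = 3
    n_flow_heads: int = 4
    n_cond_layers: int = 1
    coupling_clamp: float = 2.0
    token_dropout: float = 0.33
    max_len: int = 72

    @classmethod
    def full_scale(cls) -> "ModelConfig":
        return cls(
            d_model=512, d_z=512, n_enc_layers=6, n_post_layers=4,
            n_dec_layers=6, n_heads=8, ffn_mult=4, n_flow_steps=6,
            n_flow_heads=8, n_cond_layers=1,
        )

    @classmethod
    def desk(cls) -> "ModelConfig":
        return cls()


@dataclass
class TargetBatch:
    """Padded target peptides on the model grid (sentinel-padded up to the
    minimum supported length)."""

    token_ids: np.ndarray  # (B, T) int64
    token_mask: np.ndarray  # (B, T) bool: model positions (incl. sentinel pad)
    model_lengths: np.ndarray  # (B,) int
    peptides: list[Peptide]


def make_target_batch(
    peptides: list[Peptide], vocab: AminoAcidVocabulary
) -> TargetBatch:
    lengths = np.array([model_length(len(p)) for p in peptides])
    T = int(lengths.max())
    B = len(peptides)
    ids = np.full((B, T), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((B, T), dtype=bool)
    for i, p in enumerate(peptides):
        enc = vocab.encode(p)
        ids[i, : enc.size] = enc
        mask[i, : lengths[i]] = True
    return TargetBatch(ids, mask, lengths, peptides)


N_FOURIER = 8


def _fourier_features(u: np.ndarray, n_harmonics: int = N_FOURIER) -> np.ndarray:
    """[u, sin(2*pi*k*u), cos(2*pi*k*u)]_k features of a scalar in [0, 1]."""
    k = np.arange(1, n_harmonics + 1)
    ang = 2.0 * np.pi * u[..., None] * k
    return np.concatenate([u[..., None], np.sin(ang), np.cos(ang)], axis=-1)


class PrecursorConditioner(Module):
    """Decoder-side precursor conditioning.

    The spectrum encoder sees only peaks; knowledge of the precursor enters at
    the decoder, in three forms:

    1. a per-spectrum bias built from the sinusoidal encoding of the neutral
       precursor mass plus a charge embedding, added to every decoder input
       position;
    2. per-peak ladder features added to the decoder's cross-attention
       memory. Each peak has two candidate prefix-mass readings — mz - proton
       if it is N-terminal (b-type), M + proton - mz if it is C-terminal
       (y-type). Readings that coincide across complementary peaks mark
       backbone rungs (see :meth:`_rung_list`); every reading then gets its
       normalized rank on the rung list, a flag for sitting on a rung, and
       the sinusoidally encoded gaps to the neighboring rungs (for a true
       reading those gaps are the adjacent residue masses). The complement
       mass itself is also sinusoidally encoded;
    3. per-position Fourier features of the decoder position's expected rung
       coordinate (t+1) / (R-1), with R the detected rung count.

    (2) and (3) reduce "find the t-th ladder rung and the residue mass it
    ends" to soft rank matching plus feature retrieval, which dot-product
    attention represents naturally. Everything here is computed from the
    observed peaks and the precursor record only, identically at training and
    inference time.
    """

    def __init__(
        self,
        d_model: int,
        rng: np.random.Generator,
        residue_masses: np.ndarray | None = None,
    ):
        self.d_model = d_model
        self.mass_proj = Linear(d_model, d_model, rng)
        self.charge_emb = Embedding(MAX_CHARGE + 1, d_model, rng)
        self.comp_proj = Linear(d_model, d_model, rng)
        n_feat = 2 * N_FOURIER + 1
        self.rank_proj = Linear(2 * (n_feat + 1), d_model, rng)
        self.pos_proj = Linear(n_feat, d_model, rng)
        self.gap_proj = Linear(4 * d_model, d_model, rng)
        self.twin_tol = 0.02  # Da; coincidence tolerance for paired readings
        self.gap_tol = 0.03  # Da; tolerance for single-residue gap membership
        if residue_masses is None:
            residue_masses = AminoAcidVocabulary.default().mass_array()
        masses = np.unique(residue_masses[residue_masses > 0])
        self.residue_alphabet = masses
        self.min_residue_mass = float(masses.min())

    def _neutral_masses(self, batch: SpectrumBatch) -> np.ndarray:
        return np.array(
            [
                precursor_neutral_mass(mz, int(ch))
                for mz, ch in zip(batch.precursor_mz, batch.precursor_charge)
            ]
        )

    def sequence_bias(self, batch: SpectrumBatch) -> Tensor:
        """(B, 1, d) bias for the decoder input positions."""
        m = self._neutral_masses(batch)
        enc = Tensor(encode_mz(m, self.d_model))
        bias = self.mass_proj(enc) + self.charge_emb(batch.precursor_charge)
        return bias.reshape(len(m), 1, self.d_model)

    def _spectrum_ladder(self, sp, neutral: float) -> dict:
        """Per-spectrum ladder features (cached on the spectrum: they depend
        only on the observed peaks and the precursor record)."""
        cache = getattr(sp, "_ladder_cache", None)
        if cache is not None:
            return cache
        qb = sp.mz - PROTON_MASS
        qy = neutral + PROTON_MASS - sp.mz
        rungs = self._rung_list(qb, qy, sp.intensity, neutral)
        denom = max(rungs.size - 1, 1)
        n = sp.n_peaks
        rank = np.zeros((n, 2))
        twin = np.zeros((n, 2))
        gaps = np.zeros((n, 4))
        for col, q in ((0, qb), (1, qy)):
            j = np.clip(np.searchsorted(rungs, q), 1, rungs.size - 1)
            below, above = rungs[j - 1], rungs[np.minimum(j, rungs.size - 1)]
            idx = np.where(
                (q - below) < self.twin_tol,
                j - 1,
                np.where((above - q) < self.twin_tol, j, -1),
            )
            twin[:, col] = idx >= 0
            rank[:, col] = np.where(idx >= 0, idx, j - 0.5) / denom
            prev_idx = np.maximum(np.where(idx >= 0, idx - 1, j - 1), 0)
            next_idx = np.minimum(np.where(idx >= 0, idx + 1, j), rungs.size - 1)
            gaps[:, 2 * col] = np.clip(q - rungs[prev_idx], 0.0, 2000.0)
            gaps[:, 2 * col + 1] = np.clip(rungs[next_idx] - q, 0.0, 2000.0)
        cache = {
            "rank": rank,
            "twin": twin,
            "gaps": gaps,
            "rung_count": float(rungs.size),
        }
        sp._ladder_cache = cache
        return cache

    def memory_bias(self, batch: SpectrumBatch) -> Tensor:
        """(B, N, d) complement-mass + rank features for the decoder memory."""
        m = self._neutral_masses(batch)
        comp = (m + 2 * PROTON_MASS)[:, None] - batch.mz
        comp = np.clip(comp, 1e-3, None)
        bias = self.comp_proj(Tensor(encode_mz(comp, self.d_model)))

        B, N = batch.mz.shape
        rank = np.zeros((B, N, 2))
        twin = np.zeros((B, N, 2))
        gaps = np.zeros((B, N, 4))
        for i, sp in enumerate(batch.spectra):
            lad = self._spectrum_ladder(sp, m[i])
            n = sp.n_peaks
            rank[i, :n] = lad["rank"]
            twin[i, :n] = lad["twin"]
            gaps[i, :n] = lad["gaps"]
        feats = np.concatenate(
            [
                _fourier_features(rank[..., 0]),
                twin[..., 0:1],
                _fourier_features(rank[..., 1]),
                twin[..., 1:2],
            ],
            axis=-1,
        )
        gap_enc = encode_mz(gaps, self.d_model)  # (B, N, 4, d)
        gap_enc = gap_enc.reshape(B, N, 4 * self.d_model)
        return (
            bias
            + self.rank_proj(Tensor(feats))
            + self.gap_proj(Tensor(gap_enc))
        )

    def _rung_list(
        self,
        qb: np.ndarray,
        qy: np.ndarray,
        intensity: np.ndarray,
        neutral: float,
    ) -> np.ndarray:
        """Candidate backbone rungs.

        A reading that appears twice — once as some peak's N-terminal
        (b-type) reading, once as another peak's complementary C-terminal
        (y-type) reading — marks a backbone rung. Complementary *false*
        readings coincide too (a shadow ladder offset by the water mass), so
        coincidences are scored by the intensity ordering of their sources:
        for a true rung the y-hypothesis source is the brighter (y) ion.
        Virtual boundary rungs at 0 and at the total residue mass are always
        included.
        """
        vals = np.concatenate([qb, qy])
        hyp_y = np.concatenate(
            [np.zeros(qb.size, bool), np.ones(qy.size, bool)]
        )
        inten = np.concatenate([intensity, intensity])
        order = np.argsort(vals)
        vals, hyp_y, inten = vals[order], hyp_y[order], inten[order]

        total = neutral - WATER_MASS
        accepted: list[tuple[float, float]] = [(0.0, np.inf), (total, np.inf)]
        rejected: list[tuple[float, float]] = []
        k = 0
        while k < vals.size:
            j = k
            while j + 1 < vals.size and vals[j + 1] - vals[j] < self.twin_tol:
                j += 1
            group = slice(k, j + 1)
            gy, gb = hyp_y[group], ~hyp_y[group]
            if gy.any() and gb.any():
                score = float(inten[group][gy].max() - inten[group][gb].max())
                value = float(vals[group].mean())
                if self.twin_tol < value < total - self.twin_tol:
                    (accepted if score > 0 else rejected).append((value, score))
            k = j + 1

        # Local consistency repairs against the residue-mass alphabet:
        # two real rungs cannot lie closer than the lightest residue, and a
        # gap that matches no single residue mass must hide at least one rung
        # (recoverable from the rejected coincidences).
        accepted.sort()

        def _prune() -> None:
            while len(accepted) > 2:
                for i in range(len(accepted) - 1):
                    if (
                        accepted[i + 1][0] - accepted[i][0]
                        < self.min_residue_mass - self.twin_tol
                    ):
                        victim = min(accepted[i : i + 2], key=lambda r: r[1])
                        if np.isfinite(victim[1]):
                            accepted.remove(victim)
                            break
                else:
                    return

        def _single_residue(gap: float) -> bool:
            j = np.searchsorted(self.residue_alphabet, gap)
            best = np.inf
            for idx in (j - 1, j):
                if 0 <= idx < self.residue_alphabet.size:
                    best = min(best, abs(self.residue_alphabet[idx] - gap))
            return best < self.gap_tol

        _prune()
        for _ in range(len(rejected)):
            filled = False
            for a, b in zip(accepted[:-1], accepted[1:]):
                if not _single_residue(b[0] - a[0]):
                    inside = [
                        r
                        for r in rejected
                        if a[0] + self.min_residue_mass - self.twin_tol
                        < r[0]
                        < b[0] - self.min_residue_mass + self.twin_tol
                    ]
                    if inside:
                        best = max(inside, key=lambda r: r[1])
                        rejected.remove(best)
                        accepted.append(best)
                        accepted.sort()
                        filled = True
                        break
            if not filled:
                break
        _prune()

        return np.unique(np.round(np.array([v for v, _ in accepted]), 5))

    def rung_counts(self, batch: SpectrumBatch) -> np.ndarray:
        """Number of detected rungs per spectrum (including boundaries)."""
        m = self._neutral_masses(batch)
        return np.array(
            [
                self._spectrum_ladder(sp, m[i])["rung_count"]
                for i, sp in enumerate(batch.spectra)
            ]
        )

    def position_bias(self, batch: SpectrumBatch, T: int) -> Tensor:
        """(B, T, d) expected ladder coordinate of each decoder position:
        position t ends at rung t+1 of the detected rung list."""
        rungs = self.rung_counts(batch)
        t = np.arange(T, dtype=float)
        s = (t[None, :] + 1.0) / np.maximum(rungs[:, None] - 1.0, 1.0)
        return self.pos_proj(Tensor(_fourier_features(np.clip(s, 0.0, 1.5))))


class PepFlowModel(Module):
    def __init__(
        self,
        config: ModelConfig,
        vocab: AminoAcidVocabulary,
        rng: np.random.Generator,
    ):
        c = config
        self.config = c
        self.vocab = vocab
        self.encoder = SpectrumEncoder(
            c.d_model, c.n_enc_layers, c.n_heads, c.ffn_mult, rng
        )
        self.posterior = PosteriorNetwork(
            len(vocab), c.d_model, c.d_z, c.n_post_layers, c.n_heads,
            c.ffn_mult, c.max_len, rng, dropout_rate=c.token_dropout,
        )
        self.flow = PriorFlow(
            c.d_z, c.n_flow_steps, c.n_flow_heads, c.d_model, c.n_heads,
            c.ffn_mult, c.n_cond_layers, c.max_len, rng, clamp=c.coupling_clamp,
        )
        self.decoder = NARDecoder(
            len(vocab), c.d_z, c.d_model, c.n_dec_layers, c.n_heads,
            c.ffn_mult, c.max_len, rng,
        )
        self.length_head = LengthClassifier(c.d_model, rng)
        self.precursor_cond = PrecursorConditioner(
            c.d_model, rng, vocab.mass_array()
        )

    # -- convenience -------------------------------------------------------
    def encode_spectra(self, batch: SpectrumBatch) -> tuple[Tensor, np.ndarray]:
        return self.encoder(batch)

    def decode_logits(
        self,
        z: Tensor,
        token_mask: np.ndarray,
        x: Tensor,
        x_mask: np.ndarray,
        batch: SpectrumBatch,
        repeat: int = 1,
    ) -> Tensor:
        """Decoder log-probabilities with precursor conditioning applied.

        ``repeat`` tiles the per-spectrum conditioning when ``z`` holds
        multiple latent samples per spectrum.
        """
        T = z.shape[1]
        seq_bias = self.precursor_cond.sequence_bias(batch)
        mem_bias = self.precursor_cond.memory_bias(batch)
        pos_bias = self.precursor_cond.position_bias(batch, T)
        if repeat > 1:
            seq_bias = Tensor(np.repeat(seq_bias.data, repeat, axis=0))
            mem_bias = Tensor(np.repeat(mem_bias.data, repeat, axis=0))
            pos_bias = Tensor(np.repeat(pos_bias.data, repeat, axis=0))
        memory = x + mem_bias
        return self.decoder(
            z, token_mask, memory, x_mask, cond=seq_bias + pos_bias
        )

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "actnorm_initialized": self.flow.actnorm_flags(),
            "vocabulary": self.vocab.to_table(),
        }
        state = self.state_dict()
        buf = io.BytesIO()
        np.savez_compressed(buf, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **state)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "PepFlowModel":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        config = ModelConfig(**meta["config"])
        vocab = AminoAcidVocabulary.from_table(meta["vocabulary"])
        model = cls(config, vocab, np.random.default_rng(0))
        model.load_state_dict(state)
        model.flow.set_actnorm_flags(meta["actnorm_initialized"])
        return model
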