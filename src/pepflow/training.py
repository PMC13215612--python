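"""Variational training: ELBO assembly and the optimization loop.

The objective per annotated spectrum is the negative evidence lower bound

    -E_q[log P(y | z, x)] + kl_weight * (log q(z | y, x) - log p(z | x))

estimated with one reparameterized posterior sample, plus the cross-entropy of
the length-offset classifier (the classifier and the sequence model are
optimized jointly). The KL weight is annealed linearly from 0 to 1 over the
first fraction of steps to avoid posterior collapse, complementing the token
dropout in the posterior.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .decoder import LengthClassifier
from .encoder import SpectrumBatch
from .model import ModelConfig, PepFlowModel, make_target_batch
from .nn import Adam, Tensor
from .nn.tensor import dropout_mode
from .posterior import sample_diagonal_gaussian
from .spectra import Spectrum

__all__ = ["ElboBreakdown", "TrainingConfig", "Trainer", "elbo_step", "train"]


@dataclass
class ElboBreakdown:
    """Batch-mean terms of the objective (per-sample sums, not per-token)."""

    reconstruction: float
    kl: float
    length_loss: float
    total: float


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 30
    batch_size: int = 32
    lr: float = 5e-4
    lr_final_frac: float = 1.0  # cosine-decay floor as a fraction of lr
    warmup_frac: float = 0.05
    kl_anneal_frac: float = 0.1
    kl_weight_max: float = 1.0
    length_weight: float = 1.0
    clip_norm: float = 1.0
    dropout: float = 0.1
    weight_decay: float = 0.01
    seed: int = 0


def _elbo_graph(
    model: PepFlowModel,
    spectra: list[Spectrum],
    rng: np.random.Generator,
    kl_weight: float,
    length_weight: float,
    training: bool = True,
) -> tuple[Tensor, ElboBreakdown]:
    """Build the loss graph for one annotated batch."""
    peptides = [sp.annotation for sp in spectra]
    if any(p is None for p in peptides):
        raise ValueError("ELBO requires annotated spectra")
    sbatch = SpectrumBatch(spectra)
    tbatch = make_target_batch(peptides, model.vocab)
    x, x_mask = model.encode_spectra(sbatch)

    mu, sigma = model.posterior(
        tbatch.token_ids, tbatch.token_mask, x, x_mask,
        training=training, rng=rng,
    )
    z = sample_diagonal_gaussian(mu, sigma, rng)
    logq = model.posterior.log_q(z, mu, sigma, tbatch.token_mask)
    logp_prior = model.flow.log_prob(
        z, tbatch.token_mask, x, x_mask, training=training
    )

    logits = model.decode_logits(z, tbatch.token_mask, x, x_mask, sbatch)
    B, T = tbatch.token_ids.shape
    sel = (np.arange(B)[:, None], np.arange(T)[None, :], tbatch.token_ids)
    token_lp = logits[sel] * tbatch.token_mask.astype(float)
    recon = token_lp.sum(axis=-1)  # (B,)

    length_lp = model.length_head(x, x_mask)
    cls = LengthClassifier.target_classes(tbatch.model_lengths)
    length_ce = -length_lp[(np.arange(B), cls)]

    kl = logq - logp_prior
    loss = (
        (-recon).mean() + kl_weight * kl.mean()
        + length_weight * length_ce.mean()
    )
    breakdown = ElboBreakdown(
        reconstruction=float(recon.data.mean()),
        kl=float(kl.data.mean()),
        length_loss=float(length_ce.data.mean()),
        total=float(loss.data),
    )
    return loss, breakdown


def elbo_step(
    model: PepFlowModel,
    spectra: list[Spectrum],
    rng: np.random.Generator,
    kl_weight: float = 1.0,
    length_weight: float = 1.0,
    training: bool = True,
) -> ElboBreakdown:
    """Evaluate the objective on one batch (no parameter update)."""
    _, breakdown = _elbo_graph(
        model, spectra, rng, kl_weight, length_weight, training
    )
    return breakdown


class Trainer:
    """Owns the optimizer, schedules and RNG; supports exact resume."""

    def __init__(
        self,
        model: PepFlowModel,
        cfg: TrainingConfig,
        total_steps: int,
    ):
        self.model = model
        self.cfg = cfg
        self.total_steps = max(total_steps, 1)
        self.optimizer = Adam(
            model.parameters(), lr=cfg.lr, clip_norm=cfg.clip_norm,
            weight_decay=cfg.weight_decay,
        )
        self.rng = np.random.default_rng(cfg.seed)
        self.step_count = 0

    # -- schedules ---------------------------------------------------------
    def _lr(self) -> float:
        warm = max(int(self.cfg.warmup_frac * self.total_steps), 1)
        if self.step_count < warm:
            return self.cfg.lr * (self.step_count + 1) / warm
        if self.cfg.lr_final_frac >= 1.0:
            return self.cfg.lr
        frac = (self.step_count - warm) / max(self.total_steps - warm, 1)
        floor = self.cfg.lr * self.cfg.lr_final_frac
        return floor + 0.5 * (self.cfg.lr - floor) * (1 + math.cos(math.pi * min(frac, 1.0)))

    def _kl_weight(self) -> float:
        anneal = max(int(self.cfg.kl_anneal_frac * self.total_steps), 1)
        return self.cfg.kl_weight_max * min(1.0, self.step_count / anneal)

    # -- one step ----------------------------------------------------------
    def train_step(self, spectra: list[Spectrum]) -> ElboBreakdown:
        with dropout_mode(self.cfg.dropout, self.rng):
            loss, breakdown = _elbo_graph(
                self.model, spectra, self.rng,
                kl_weight=self._kl_weight(),
                length_weight=self.cfg.length_weight,
                training=True,
            )
        if not math.isfinite(breakdown.total):
            raise FloatingPointError(
                f"non-finite loss at step {self.step_count}: {breakdown}"
            )
        self.optimizer.zero_grad()
        loss.backward()
        self.optimizer.lr = self._lr()
        self.optimizer.step()
        self.step_count += 1
        return breakdown

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        self.model.save(Path(path))
        extra = {
            "step_count": self.step_count,
            "total_steps": self.total_steps,
            "config": asdict(self.cfg),
            "rng_state": self.rng.bit_generator.state,
            "adam_t": self.optimizer.t,
        }
        np.savez_compressed(
            Path(path).with_suffix(".opt.npz"),
            __meta__=np.frombuffer(json.dumps(extra).encode(), dtype=np.uint8),
            **{f"m_{i}": m for i, m in enumerate(self.optimizer.m)},
            **{f"v_{i}": v for i, v in enumerate(self.optimizer.v)},
        )

    @classmethod
    def resume(cls, path: str | Path) -> "Trainer":
        model = PepFlowModel.load(Path(path))
        with np.load(Path(path).with_suffix(".opt.npz")) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            n = len(model.parameters())
            m = [data[f"m_{i}"] for i in range(n)]
            v = [data[f"v_{i}"] for i in range(n)]
        trainer = cls(
            model, TrainingConfig(**meta["config"]), meta["total_steps"]
        )
        trainer.step_count = meta["step_count"]
        trainer.optimizer.t = meta["adam_t"]
        trainer.optimizer.m = [np.asarray(a) for a in m]
        trainer.optimizer.v = [np.asarray(a) for a in v]
        trainer.rng.bit_generator.state = meta["rng_state"]
        return trainer


def train(
    model: PepFlowModel,
    spectra: list[Spectrum],
    cfg: TrainingConfig,
    metrics_path: str | Path | None = None,
    checkpoint_path: str | Path | None = None,
    log_every: int = 20,
    progress: bool = False,
) -> list[dict]:
    """Train on annotated (preprocessed) spectra; returns per-log metrics."""
    steps_per_epoch = max(len(spectra) // cfg.batch_size, 1)
    trainer = Trainer(model, cfg, total_steps=cfg.epochs * steps_per_epoch)
    order_rng = np.random.default_rng(cfg.seed + 1)
    metrics: list[dict] = []
    t0 = time.time()
    for epoch in range(cfg.epochs):
        order = order_rng.permutation(len(spectra))
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            batch = [spectra[i] for i in idx]
            breakdown = trainer.train_step(batch)
            if trainer.step_count % log_every == 0 or (
                epoch == cfg.epochs - 1 and b == steps_per_epoch - 1
            ):
                row = {
                    "step": trainer.step_count,
                    "epoch": epoch,
                    "loss": breakdown.total,
                    "reconstruction": breakdown.reconstruction,
                    "kl": breakdown.kl,
                    "length_loss": breakdown.length_loss,
                    "elapsed_s": round(time.time() - t0, 2),
                }
                metrics.append(row)
                if progress:
                    print(
                        f"step {row['step']:6d} loss {row['loss']:10.3f} "
                        f"recon {row['reconstruction']:10.3f} "
                        f"kl {row['kl']:8.3f} len {row['length_loss']:6.3f}",
                        flush=True,
                    )
    if metrics_path is not None:
        import pandas as pd

        pd.DataFrame(metrics).to_csv(metrics_path, sep="\t", index=False)
    if checkpoint_path is not None:
        trainer.save(checkpoint_path)
    return metrics
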