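"""Staged inference: prior sampling, precursor-mass filtering, probability
maximization, and knapsack repair.

For each spectrum, ``k`` latent sequences are drawn from the conditional prior
at the predicted length(s) and decoded in parallel to their argmax peptides.
Any candidate whose neutral mass already falls inside the precursor tolerance
window is emitted immediately (stage ``filtered``). Otherwise the candidate
with the highest total log-probability is repaired by the exact knapsack
solver against the precursor window (stage ``knapsack``), falling back to the
unrepaired candidate when the window is infeasible (stage ``argmax``).

The confidence score ``score01`` is the geometric mean of the per-residue
probabilities of the emitted peptide, a length-invariant value in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import WATER_MASS
from .encoder import SpectrumBatch
from .knapsack import KnapsackInfeasible, knapsack_repair
from .masses import (
    MassWindow,
    Peptide,
    mass_window,
    precursor_neutral_mass,
)
from .model import PepFlowModel
from .nn import Tensor, no_grad
from .spectra import Spectrum

__all__ = [
    "DecodingCandidate",
    "DecodingConfig",
    "decode_spectrum",
    "decode_spectra",
    "score_from_logprobs",
    "write_predictions",
    "read_predictions",
]


@dataclass(frozen=True)
class DecodingConfig:
    k: int = 5
    tol_ppm: float = 20.0
    noise_scale: float = 0.3  # prior sampling temperature; <1 is mode-seeking
    base_family: str = "normal"  # "normal" | "uniform"
    use_knapsack: bool = True
    top_r_lengths: int = 1
    knapsack_bin_width: float = 1e-3
    knapsack_top_q: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")


@dataclass
class DecodingCandidate:
    peptide: Peptide | None
    position_logprobs: np.ndarray  # log P of the emitted residues
    total_logprob: float  # over all model positions (incl. sentinel slots)
    neutral_mass: float
    stage: str  # filtered | knapsack | argmax
    score01: float
    spectrum_id: str = ""
    mass_error_ppm: float = float("nan")
    knapsack_infeasible: bool = False


def score_from_logprobs(position_logprobs: np.ndarray) -> float:
    """Geometric mean of per-residue probabilities; 0 for an empty peptide."""
    if position_logprobs.size == 0:
        return 0.0
    return float(np.exp(position_logprobs.mean()))


def _candidate_from_ids(
    ids: np.ndarray,
    logits: np.ndarray,
    model: PepFlowModel,
    stage: str,
) -> DecodingCandidate:
    vocab = model.vocab
    masses = vocab.mass_array()
    pos = np.arange(ids.size)
    chosen_lp = logits[pos, ids]
    emitted = ids > vocab.unk_id  # residues only, sentinels stripped
    peptide = vocab.decode(ids[emitted]) if emitted.any() else None
    res_lp = chosen_lp[emitted]
    neutral = float(masses[ids].sum() + WATER_MASS)
    return DecodingCandidate(
        peptide=peptide,
        position_logprobs=res_lp,
        total_logprob=float(chosen_lp.sum()),
        neutral_mass=neutral,
        stage=stage,
        score01=score_from_logprobs(res_lp),
    )


def _sample_candidates(
    chunk: list[Spectrum],
    model: PepFlowModel,
    cfg: DecodingConfig,
    rng: np.random.Generator,
) -> list[list[tuple[DecodingCandidate, np.ndarray]]]:
    """Stage 1 for a chunk of spectra: k prior samples per candidate length,
    decoded to argmax peptides. Forward passes are batched across spectra."""
    with no_grad():
        batch = SpectrumBatch(chunk)
        x, x_mask = model.encode_spectra(batch)
        length_lp = model.length_head(x, x_mask).data
        # candidate lengths per spectrum (top-r offset classes)
        from .decoder import MAX_OFFSET, MEAN_LENGTH

        lengths: list[list[int]] = []
        for row in length_lp:
            order = np.argsort(row)[::-1][: cfg.top_r_lengths]
            lengths.append([MEAN_LENGTH + int(c) - MAX_OFFSET for c in order])

        candidates: list[list[tuple[DecodingCandidate, np.ndarray]]] = [
            [] for _ in chunk
        ]
        tasks: dict[int, list[int]] = {}
        for i, ls in enumerate(lengths):
            for T in ls:
                tasks.setdefault(T, []).append(i)
        for T in sorted(tasks):
            idx = tasks[T]
            sub = SpectrumBatch(
                [chunk[i] for i in idx], pad_to=batch.mz.shape[1]
            )
            xs = Tensor(x.data[idx])
            xs_mask = x_mask[idx]
            xk = Tensor(np.repeat(xs.data, cfg.k, axis=0))
            xk_mask = np.repeat(xs_mask, cfg.k, axis=0)
            token_mask = np.ones((len(idx) * cfg.k, T), dtype=bool)
            z = model.flow.sample(
                xk, xk_mask, token_mask, rng,
                noise_scale=cfg.noise_scale, family=cfg.base_family,
            )
            logits = model.decode_logits(
                z, token_mask, xk, xk_mask, sub, repeat=cfg.k
            ).data
            for row, i in enumerate(idx):
                for j in range(cfg.k):
                    lg = logits[row * cfg.k + j]
                    ids = lg.argmax(axis=-1)
                    cand = _candidate_from_ids(ids, lg, model, "argmax")
                    candidates[i].append((cand, lg))
        return candidates


def _stage_and_repair(
    sp: Spectrum,
    candidates: list[tuple[DecodingCandidate, np.ndarray]],
    model: PepFlowModel,
    cfg: DecodingConfig,
) -> DecodingCandidate:
    """Stages 2-4: precursor filter, probability maximization, knapsack."""
    m = precursor_neutral_mass(sp.precursor_mz, sp.precursor_charge)
    window = mass_window(m, cfg.tol_ppm)

    passers = [
        c for c, _ in candidates
        if c.peptide is not None and window.contains(c.neutral_mass)
    ]
    if passers:
        best = max(passers, key=lambda c: c.total_logprob)
        best.stage = "filtered"
        return _finalize(best, sp, m)

    best, best_logits = max(candidates, key=lambda cl: cl[0].total_logprob)

    if cfg.use_knapsack:
        masses = model.vocab.mass_array()
        allowed = np.ones(len(model.vocab), dtype=bool)
        allowed[model.vocab.unk_id] = False
        try:
            ids = knapsack_repair(
                best_logits,
                masses,
                (window.L - WATER_MASS, window.U - WATER_MASS),
                bin_width=cfg.knapsack_bin_width,
                allowed=allowed,
                top_q=cfg.knapsack_top_q,
            )
            repaired = _candidate_from_ids(ids, best_logits, model, "knapsack")
            return _finalize(repaired, sp, m)
        except KnapsackInfeasible:
            best.knapsack_infeasible = True
    return _finalize(best, sp, m)


def _finalize(c: DecodingCandidate, sp: Spectrum, m: float) -> DecodingCandidate:
    c.spectrum_id = sp.spectrum_id
    c.mass_error_ppm = (c.neutral_mass - m) / m * 1e6
    return c


def decode_spectrum(
    sp: Spectrum,
    model: PepFlowModel,
    cfg: DecodingConfig,
    rng: np.random.Generator,
) -> DecodingCandidate:
    """Run the staged decoding pipeline on one preprocessed spectrum."""
    if sp.n_peaks == 0:
        raise ValueError("cannot decode an empty spectrum")
    (candidates,) = _sample_candidates([sp], model, cfg, rng)
    return _stage_and_repair(sp, candidates, model, cfg)


def decode_spectra(
    spectra: list[Spectrum],
    model: PepFlowModel,
    cfg: DecodingConfig,
    seed: int = 0,
    chunk_size: int = 16,
) -> list[DecodingCandidate]:
    """Decode a spectrum list, batching forward passes over ``chunk_size``
    spectra at a time."""
    rng = np.random.default_rng(seed)
    out: list[DecodingCandidate] = []
    for lo in range(0, len(spectra), chunk_size):
        chunk = spectra[lo : lo + chunk_size]
        if any(sp.n_peaks == 0 for sp in chunk):
            raise ValueError("cannot decode an empty spectrum")
        all_cands = _sample_candidates(chunk, model, cfg, rng)
        for sp, cands in zip(chunk, all_cands):
            out.append(_stage_and_repair(sp, cands, model, cfg))
    return out


# -- prediction tables -----------------------------------------------------

def predictions_frame(candidates: list[DecodingCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "spectrum_id": c.spectrum_id,
                "peptide": str(c.peptide) if c.peptide is not None else "",
                "score01": c.score01,
                "residue_scores": ",".join(
                    f"{p:.4f}" for p in np.exp(c.position_logprobs)
                ),
                "stage": c.stage,
                "mass_error_ppm": c.mass_error_ppm,
            }
        )
    return pd.DataFrame(rows)


def write_predictions(
    candidates: list[DecodingCandidate], path: str | Path, header: str = ""
) -> None:
    """TSV export; ``header`` lines (e.g. the serialized run config) are
    prepended as comments."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        predictions_frame(candidates).to_csv(fh, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
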