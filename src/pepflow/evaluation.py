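"""Evaluation metrics: mass-based residue matching, peptide precision,
alignment identity, threshold/precision-coverage summaries, and the
target-decoy score-distribution report.

Residue matching follows the mass-alignment convention of the de novo
sequencing literature: a predicted residue matches a reference residue when
their residue masses differ by less than 0.1 Da and the mass of the preceding
prefixes differs by at most 0.5 Da. This makes isobaric substitutions (I/L,
and K/Q within 0.04 Da) count as matches, mirroring what a mass spectrometer
can actually distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masses import AminoAcidVocabulary, Peptide

__all__ = [
    "MatchResult",
    "EvaluationRecord",
    "match_residues",
    "identity_fraction",
    "summarize",
    "target_decoy_report",
    "score_histogram",
]

RESIDUE_TOL_DA = 0.1
PREFIX_TOL_DA = 0.5
DEFAULT_IDENTITY_THRESHOLDS = (0.9, 0.8, 0.7, 0.6, 0.5)


@dataclass(frozen=True)
class MatchResult:
    n_matched: int
    n_predicted: int
    n_true: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_matched <= min(self.n_predicted, self.n_true):
            raise ValueError("inconsistent match counts")

    @property
    def peptide_correct(self) -> bool:
        return (
            self.n_matched == self.n_true == self.n_predicted
        )


def match_residues(
    pred: Peptide,
    truth: Peptide,
    vocab: AminoAcidVocabulary,
    mode: str = "mass",
    residue_tol: float = RESIDUE_TOL_DA,
    prefix_tol: float = PREFIX_TOL_DA,
) -> MatchResult:
    """Count matching residues between prediction and ground truth.

    ``mode="mass"`` aligns positions by prefix residue mass (the standard
    criterion); ``mode="position"`` compares same-index residues only.
    """
    pm = np.array([vocab.mass_of(t) for t in pred.tokens])
    tm = np.array([vocab.mass_of(t) for t in truth.tokens])
    if mode == "position":
        n = min(pm.size, tm.size)
        matched = int(np.sum(np.abs(pm[:n] - tm[:n]) < residue_tol))
        return MatchResult(matched, pm.size, tm.size)
    if mode != "mass":
        raise ValueError(f"unknown matching mode {mode!r}")
    pre_p = np.concatenate([[0.0], np.cumsum(pm)])  # prefix mass before i
    pre_t = np.concatenate([[0.0], np.cumsum(tm)])
    i = j = matched = 0
    while i < pm.size and j < tm.size:
        if (
            abs(pm[i] - tm[j]) < residue_tol
            and abs(pre_p[i] - pre_t[j]) <= prefix_tol
        ):
            matched += 1
            i += 1
            j += 1
        elif pre_p[i + 1] < pre_t[j + 1]:
            i += 1
        else:
            j += 1
    return MatchResult(matched, pm.size, tm.size)


def identity_fraction(pred: Peptide, truth: Peptide) -> float:
    """Global-alignment identity: matches / |truth|.

    Needleman-Wunsch with match 1, mismatch 0 and zero gap penalty — the
    maximum number of identically aligned residues — divided by the true
    sequence length.
    """
    a, b = pred.tokens, truth.tokens
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        row = dp[i]
        prev = dp[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            row[j] = max(diag, prev[j], row[j - 1])
    return float(dp[n, m]) / m


@dataclass(frozen=True)
class EvaluationRecord:
    match: MatchResult
    identity: float
    score: float = float("nan")


def summarize(
    records: list[EvaluationRecord],
    thresholds: tuple[float, ...] = DEFAULT_IDENTITY_THRESHOLDS,
) -> dict:
    """Aggregate metrics over a result stream.

    Returns amino-acid precision/recall (pooled over residues), peptide
    precision, the per-threshold identity proportions, and a score-ranked
    precision-coverage curve at the amino-acid and peptide level.
    """
    if not records:
        raise ValueError("cannot summarize an empty result stream")
    n_matched = sum(r.match.n_matched for r in records)
    n_pred = sum(r.match.n_predicted for r in records)
    n_true = sum(r.match.n_true for r in records)
    identities = np.array([r.identity for r in records])
    report = {
        "n_spectra": len(records),
        "aa_precision": n_matched / n_pred if n_pred else 0.0,
        "aa_recall": n_matched / n_true if n_true else 0.0,
        "peptide_precision": float(
            np.mean([r.match.peptide_correct for r in records])
        ),
        "identity_proportions": {
            thr: float(np.mean(identities > thr)) for thr in thresholds
        },
    }
    scores = np.array([r.score for r in records])
    if np.all(np.isfinite(scores)):
        order = np.argsort(scores)[::-1]
        pep_ok = np.array(
            [records[i].match.peptide_correct for i in order], dtype=float
        )
        matched = np.array([records[i].match.n_matched for i in order])
        predicted = np.array([records[i].match.n_predicted for i in order])
        cum_n = np.arange(1, len(records) + 1)
        report["precision_coverage"] = pd.DataFrame(
            {
                "coverage": cum_n / len(records),
                "peptide_precision": np.cumsum(pep_ok) / cum_n,
                "aa_precision": np.cumsum(matched)
                / np.maximum(np.cumsum(predicted), 1),
                "score_threshold": scores[order],
            }
        )
    return report


def target_decoy_report(
    target_scores: np.ndarray,
    decoy_scores: np.ndarray,
    thresholds: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1),
) -> pd.DataFrame:
    """Per-threshold counts of retained target/decoy matches and the decoy
    fraction decoys / (targets + decoys)."""
    t = np.asarray(target_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    for arr in (t, d):
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
    rows = []
    for thr in thresholds:
        nt = int((t >= thr).sum())
        nd = int((d >= thr).sum())
        rows.append(
            {
                "threshold": thr,
                "n_target": nt,
                "n_decoy": nd,
                "decoy_fraction": nd / (nt + nd) if nt + nd else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def score_histogram(
    scores: np.ndarray, n_bins: int = 20
) -> pd.DataFrame:
    """Histogram of confidence scores on [0, 1] for plotting/export."""
    counts, edges = np.histogram(
        np.asarray(scores, dtype=float), bins=n_bins, range=(0.0, 1.0)
    )
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
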