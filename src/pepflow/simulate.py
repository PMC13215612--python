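"""Synthetic HCD-style fragmentation spectra and decoy perturbation.

The generator samples tryptic-like peptides, emits their theoretical b/y
fragment ions with a configurable noise model (fragment dropout, m/z jitter,
spurious peaks, log-normal intensities with y ions brighter than b ions), and
builds decoy spectra by replacing a fraction of peaks with draws from the
pooled empirical peak distribution, as in target-decoy spectrum benchmarks.

All randomness flows from the config seed, so identical configs reproduce
byte-identical MGF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import PROTON_MASS, WATER_MASS
from .masses import AminoAcidVocabulary, Peptide, mass_to_mz, peptide_mass
from .spectra import Spectrum

__all__ = [
    "SimulationConfig",
    "DecoyConfig",
    "sample_peptide",
    "fragment_mzs",
    "fragment_spectrum",
    "simulate_dataset",
    "make_decoy",
    "make_decoys",
]

# Canonical 20-residue alphabet used for sampling (C is carbamidomethylated in
# the mass table; oxidized M is not sampled by default).
CANONICAL_RESIDUES = tuple("GASPVTCLINDQKEMHFRYW")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic spectrum generator.

    Defaults describe a clean (noiseless) tryptic b/y benchmark: singly charged
    b/y ions of doubly charged tryptic precursors, no fragment dropout, no m/z
    jitter, no spurious peaks. Noise terms are opt-in.
    """

    n_peptides: int = 1000
    min_length: int = 7
    max_length: int = 20
    residues: tuple[str, ...] = CANONICAL_RESIDUES
    residue_weights: tuple[float, ...] | None = None  # uniform when None
    tryptic: bool = True  # force C-terminal K/R
    precursor_charges: tuple[int, ...] = (2,)
    fragment_charges: tuple[int, ...] = (1,)
    noise_peak_rate: float = 0.0  # Poisson mean of spurious peaks
    mz_jitter_sd: float = 0.0  # Da
    peak_dropout_prob: float = 0.0
    # log-normal intensity model: log-mean/log-sd for b ions; y ions get twice
    # the b-ion median, matching qualitative HCD behaviour
    intensity_log_mu: float = 0.0
    intensity_log_sd: float = 0.3
    y_boost: float = 2.0
    noise_mz_range: tuple[float, float] = (100.0, 1500.0)
    noise_intensity_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("invalid length range")
        if not 0 <= self.peak_dropout_prob <= 1:
            raise ValueError("peak_dropout_prob must be in [0, 1]")
        if self.noise_peak_rate < 0 or self.mz_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.residue_weights is not None and len(self.residue_weights) != len(
            self.residues
        ):
            raise ValueError("residue_weights must match residues")


@dataclass(frozen=True)
class DecoyConfig:
    """Decoy perturbation: fraction of peaks replaced from the pooled empirical
    peak distribution (0.5 / 0.6 / 0.7 are the benchmark noise levels)."""

    replacement_fraction: float = 0.5
    joint_resampling: bool = True  # draw (m/z, intensity) pairs jointly
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.replacement_fraction < 1:
            raise ValueError("replacement_fraction must be in (0, 1)")


def sample_peptide(cfg: SimulationConfig, rng: np.random.Generator) -> Peptide:
    """Draw a peptide: uniform length in [min_length, max_length], residues
    i.i.d. from the configured frequencies, optional tryptic C-terminus."""
    length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
    p = None
    if cfg.residue_weights is not None:
        w = np.asarray(cfg.residue_weights, dtype=float)
        p = w / w.sum()
    toks = list(rng.choice(cfg.residues, size=length, p=p))
    if cfg.tryptic:
        toks[-1] = str(rng.choice(["K", "R"]))
    return Peptide(tuple(toks))


def fragment_mzs(
    p: Peptide, vocab: AminoAcidVocabulary, charges: tuple[int, ...] = (1,)
) -> tuple[np.ndarray, np.ndarray]:
    """Theoretical b/y fragment m/z values for cleavage at each backbone bond.

    Returns (b_mz, y_mz), each of shape (len(p) - 1, len(charges)): b_k carries
    the first k residues plus a proton, y_k the last k residues plus water and
    a proton, divided by the charge for multiply charged fragments.
    """
    masses = np.array([vocab.mass_of(t) for t in p.tokens])
    b_neutral = np.cumsum(masses)[:-1]  # residue-sum of prefixes, k = 1..T-1
    y_neutral = np.cumsum(masses[::-1])[:-1] + WATER_MASS
    ch = np.asarray(charges, dtype=float)
    b_mz = (b_neutral[:, None] + ch * PROTON_MASS) / ch
    y_mz = (y_neutral[:, None] + ch * PROTON_MASS) / ch
    return b_mz, y_mz


def fragment_spectrum(
    p: Peptide,
    cfg: SimulationConfig,
    vocab: AminoAcidVocabulary,
    rng: np.random.Generator,
    spectrum_id: str = "",
) -> Spectrum:
    """Simulate one annotated HCD-style spectrum of peptide ``p``."""
    b_mz, y_mz = fragment_mzs(p, vocab, cfg.fragment_charges)
    n_frag, n_ch = b_mz.shape
    mzs: list[float] = []
    intens: list[float] = []
    for series, mz_grid in (("b", b_mz), ("y", y_mz)):
        boost = cfg.y_boost if series == "y" else 1.0
        for k in range(n_frag):
            for c in range(n_ch):
                if cfg.peak_dropout_prob > 0 and rng.random() < cfg.peak_dropout_prob:
                    continue
                mz = mz_grid[k, c]
                if cfg.mz_jitter_sd > 0:
                    mz += rng.normal(0.0, cfg.mz_jitter_sd)
                inten = boost * float(
                    rng.lognormal(cfg.intensity_log_mu, cfg.intensity_log_sd)
                )
                mzs.append(float(mz))
                intens.append(inten)
    n_noise = int(rng.poisson(cfg.noise_peak_rate)) if cfg.noise_peak_rate > 0 else 0
    for _ in range(n_noise):
        mzs.append(float(rng.uniform(*cfg.noise_mz_range)))
        intens.append(
            cfg.noise_intensity_scale
            * float(rng.lognormal(cfg.intensity_log_mu, cfg.intensity_log_sd))
        )
    charge = int(rng.choice(cfg.precursor_charges))
    prec_mz = mass_to_mz(peptide_mass(p, vocab), charge)
    return Spectrum(
        mz=np.array(mzs),
        intensity=np.array(intens),
        precursor_mz=prec_mz,
        precursor_charge=charge,
        spectrum_id=spectrum_id,
        annotation=p,
    )


def simulate_dataset(
    cfg: SimulationConfig, vocab: AminoAcidVocabulary | None = None
) -> list[Spectrum]:
    """Generate ``cfg.n_peptides`` annotated spectra, deterministically from
    ``cfg.seed``."""
    vocab = vocab or AminoAcidVocabulary.default()
    rng = np.random.default_rng(cfg.seed)
    out = []
    for i in range(cfg.n_peptides):
        p = sample_peptide(cfg, rng)
        out.append(fragment_spectrum(p, cfg, vocab, rng, spectrum_id=f"synth_{i}"))
    return out


def _pooled_peaks(pool: list[Spectrum]) -> tuple[np.ndarray, np.ndarray]:
    mz = np.concatenate([sp.mz for sp in pool])
    inten = np.concatenate([sp.intensity for sp in pool])
    return mz, inten


def make_decoy(
    sp: Spectrum,
    pool: list[Spectrum],
    cfg: DecoyConfig,
    rng: np.random.Generator,
) -> Spectrum:
    """Perturb a spectrum into a decoy: remove ``floor(f*N)`` random peaks and
    insert as many drawn from the pooled empirical peak distribution.

    Precursor fields are preserved, the annotation is cleared, and the result
    is flagged as a decoy; peak count is preserved by construction.
    """
    if not pool:
        raise ValueError("decoy pool must be non-empty")
    n = sp.n_peaks
    if n < 2:
        raise ValueError("cannot build a decoy from a spectrum with < 2 peaks")
    n_replace = int(np.floor(cfg.replacement_fraction * n))
    keep_mask = np.ones(n, dtype=bool)
    if n_replace > 0:
        removed = rng.choice(n, size=n_replace, replace=False)
        keep_mask[removed] = False
    pool_mz, pool_inten = _pooled_peaks(pool)
    if cfg.joint_resampling:
        idx = rng.integers(0, pool_mz.size, size=n_replace)
        new_mz, new_inten = pool_mz[idx], pool_inten[idx]
    else:
        new_mz = pool_mz[rng.integers(0, pool_mz.size, size=n_replace)]
        new_inten = pool_inten[rng.integers(0, pool_inten.size, size=n_replace)]
    return sp.copy(
        mz=np.concatenate([sp.mz[keep_mask], new_mz]),
        intensity=np.concatenate([sp.intensity[keep_mask], new_inten]),
        annotation=None,
        is_decoy=True,
        spectrum_id=(sp.spectrum_id + "|decoy") if sp.spectrum_id else "decoy",
    )


def make_decoys(
    spectra: list[Spectrum], cfg: DecoyConfig, pool: list[Spectrum] | None = None
) -> list[Spectrum]:
    """Decoy-perturb every spectrum, pooling peaks over ``pool`` (default: the
    input set itself)."""
    rng = np.random.default_rng(cfg.seed)
    pool = pool if pool is not None else spectra
    return [make_decoy(sp, pool, cfg, rng) for sp in spectra]
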