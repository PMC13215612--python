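"""Amino-acid vocabulary, peptide tokenization and monoisotopic mass arithmetic.

The vocabulary maps residue tokens (20 canonical amino acids, cysteine carrying a
fixed carbamidomethyl group, plus oxidized methionine as a distinct token) to
monoisotopic residue masses, and provides the token<->integer-id bijection used
by the neural model. Sentinel tokens (padding / unknown) have mass zero and never
contribute to a peptide mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Sequence

import numpy as np

from .constants import PAD_TOKEN, PROTON_MASS, UNK_TOKEN, WATER_MASS

__all__ = [
    "AminoAcidVocabulary",
    "Peptide",
    "MassWindow",
    "peptide_mass",
    "precursor_neutral_mass",
    "mass_to_mz",
    "mass_window",
    "tokenize_sequence",
]


class UnknownTokenError(KeyError):
    """Raised when a peptide contains a symbol absent from the vocabulary."""


def tokenize_sequence(sequence: str) -> tuple[str, ...]:
    """Split a peptide string into residue tokens.

    Modified residues are written with a parenthesized suffix, e.g. ``"M(ox)"``;
    ``"PEM(ox)TIDE"`` -> ``("P", "E", "M(ox)", "T", "I", "D", "E")``.
    """
    tokens: list[str] = []
    i = 0
    while i < len(sequence):
        ch = sequence[i]
        if i + 1 < len(sequence) and sequence[i + 1] == "(":
            close = sequence.find(")", i + 1)
            if close < 0:
                raise ValueError(f"unbalanced modification bracket in {sequence!r}")
            tokens.append(sequence[i : close + 1])
            i = close + 1
        else:
            tokens.append(ch)
            i += 1
    return tuple(tokens)


@dataclass(frozen=True)
class Peptide:
    """A peptide as a sequence of vocabulary tokens (no sentinels)."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise ValueError("a peptide must contain at least one residue")
        if PAD_TOKEN in self.tokens or UNK_TOKEN in self.tokens:
            raise ValueError("peptides may not contain sentinel tokens")

    @classmethod
    def from_string(cls, sequence: str) -> "Peptide":
        return cls(tokenize_sequence(sequence))

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def __str__(self) -> str:
        return "".join(self.tokens)


@dataclass(frozen=True)
class MassWindow:
    """A closed neutral-mass interval [L, U] in Da."""

    L: float
    U: float

    def __post_init__(self) -> None:
        if not (0 < self.L < self.U):
            raise ValueError(f"invalid mass window [{self.L}, {self.U}]")

    def contains(self, mass: float) -> bool:
        return self.L <= mass <= self.U

    @property
    def width(self) -> float:
        return self.U - self.L


@dataclass
class AminoAcidVocabulary:
    """Ordered residue vocabulary with monoisotopic residue masses.

    ``tokens[0]`` is the padding sentinel and ``tokens[1]`` the unknown sentinel;
    both carry mass 0 and are excluded from peptide masses.
    """

    tokens: list[str]
    residue_mass: dict[str, float]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tokens[0] != PAD_TOKEN or self.tokens[1] != UNK_TOKEN:
            raise ValueError("vocabulary must start with the pad and unk sentinels")
        self._index = {tok: i for i, tok in enumerate(self.tokens)}
        if len(self._index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for tok in self.tokens:
            m = self.residue_mass[tok]
            if tok in (PAD_TOKEN, UNK_TOKEN):
                if m != 0.0:
                    raise ValueError("sentinel tokens must have zero mass")
            elif not (np.isfinite(m) and m > 0):
                raise ValueError(f"token {tok!r} must have a positive finite mass")

    # -- construction ------------------------------------------------------
    @classmethod
    def default(cls) -> "AminoAcidVocabulary":
        """The packaged vocabulary (20 canonical residues, C carbamidomethylated,
        oxidized M as an extra token)."""
        text = resources.files("pepflow.data").joinpath("vocabulary.tsv").read_text()
        return cls.from_table(text)

    @classmethod
    def from_table(cls, text: str) -> "AminoAcidVocabulary":
        tokens: list[str] = []
        masses: dict[str, float] = {}
        notes: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            tok, mass = parts[0], float(parts[1])
            tokens.append(tok)
            masses[tok] = mass
            if len(parts) > 2:
                notes[tok] = parts[2]
        return cls(tokens, masses, notes)

    def to_table(self) -> str:
        lines = ["# token\tmonoisotopic_mass\tmodification"]
        for tok in self.tokens:
            row = f"{tok}\t{self.residue_mass[tok]:.8f}"
            if tok in self.annotations:
                row += f"\t{self.annotations[tok]}"
            lines.append(row)
        return "\n".join(lines) + "\n"

    # -- token/id bijection ------------------------------------------------
    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    @property
    def residue_tokens(self) -> list[str]:
        return self.tokens[2:]

    def id_of(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError as exc:
            raise UnknownTokenError(f"unknown residue token: {token!r}") from exc

    def token_of(self, idx: int) -> str:
        return self.tokens[idx]

    def encode(self, peptide: Peptide | Sequence[str]) -> np.ndarray:
        toks = peptide.tokens if isinstance(peptide, Peptide) else tuple(peptide)
        return np.array([self.id_of(t) for t in toks], dtype=np.int64)

    def decode(self, ids: Iterable[int], strip_sentinels: bool = True) -> Peptide:
        toks = [self.tokens[int(i)] for i in ids]
        if strip_sentinels:
            toks = [t for t in toks if t not in (PAD_TOKEN, UNK_TOKEN)]
        return Peptide(tuple(toks))

    def mass_array(self) -> np.ndarray:
        """Residue masses ordered by token id (sentinels -> 0)."""
        return np.array([self.residue_mass[t] for t in self.tokens], dtype=np.float64)

    def mass_of(self, token: str) -> float:
        if token not in self._index:
            raise UnknownTokenError(f"unknown residue token: {token!r}")
        return self.residue_mass[token]


# -- mass arithmetic -------------------------------------------------------

def peptide_mass(p: Peptide, vocab: AminoAcidVocabulary) -> float:
    """Neutral monoisotopic peptide mass: sum of residue masses plus water."""
    return float(sum(vocab.mass_of(t) for t in p.tokens) + WATER_MASS)


def precursor_neutral_mass(precursor_mz: float, charge: int) -> float:
    """Neutral mass from an observed precursor m/z at the given positive charge."""
    if charge < 1:
        raise ValueError(f"precursor charge must be >= 1, got {charge}")
    if precursor_mz <= 0:
        raise ValueError(f"precursor m/z must be positive, got {precursor_mz}")
    return charge * precursor_mz - charge * PROTON_MASS


def mass_to_mz(neutral_mass: float, charge: int) -> float:
    """Theoretical m/z of a neutral mass carrying `charge` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def mass_window(m: float, tol_ppm: float) -> MassWindow:
    """Symmetric relative mass-tolerance window around a measured mass."""
    if m <= 0:
        raise ValueError("mass must be positive")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    delta = m * tol_ppm * 1e-6
    return MassWindow(m - delta, m + delta)
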