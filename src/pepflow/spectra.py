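"""Spectrum container and MGF input/output.

MGF is the canonical on-disk format. Annotated spectra carry the ground-truth
peptide on a ``SEQ=`` line inside the ion block; decoy spectra are marked with
``DECOY=1``. Reading and writing go through :mod:`pyteomics.mgf`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from pyteomics import mgf as _mgf

from .masses import Peptide

__all__ = ["Spectrum", "read_mgf", "write_mgf", "preprocess"]

logger = logging.getLogger(__name__)

# Default peak-filtering window; must lie inside the m/z positional-encoding
# range (0.001 .. 10,000).
DEFAULT_MIN_MZ = 50.0
DEFAULT_MAX_MZ = 2500.0
DEFAULT_MAX_PEAKS = 150
MAX_CHARGE = 10


@dataclass
class Spectrum:
    """A fragmentation spectrum: precursor record plus a peak list.

    Peaks are kept sorted by m/z; intensities are arbitrary units until
    :func:`preprocess` scales them to unit Euclidean norm.
    """

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    precursor_charge: int
    spectrum_id: str = ""
    annotation: Peptide | None = None
    is_decoy: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have the same shape")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        return out


def _parse_charge(params: dict) -> int | None:
    ch = params.get("charge")
    if ch is None:
        return None
    try:
        value = int(ch[0]) if isinstance(ch, (list, tuple)) else int(ch)
    except (TypeError, ValueError):
        return None
    return value


def read_mgf(
    path: str | Path,
    stats: dict | None = None,
) -> Iterator[Spectrum]:
    """Yield spectra from an MGF file in file order.

    Malformed blocks (missing PEPMASS, empty peak list, unparsable charge out of
    1..10) are skipped with a logged warning. If ``stats`` is given, the counts
    ``read`` and ``skipped`` are accumulated into it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if stats is not None:
        stats.setdefault("read", 0)
        stats.setdefault("skipped", 0)

    def _skip(reason: str, title: str) -> None:
        logger.warning("skipping spectrum %r: %s", title, reason)
        if stats is not None:
            stats["skipped"] += 1

    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for entry in reader:
            params = entry.get("params", {})
            title = str(params.get("title", ""))
            pepmass = params.get("pepmass")
            if pepmass is None:
                _skip("missing PEPMASS", title)
                continue
            prec_mz = pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass
            if prec_mz is None or not np.isfinite(prec_mz) or prec_mz <= 0:
                _skip("invalid PEPMASS", title)
                continue
            mz = np.asarray(entry.get("m/z array", []), dtype=np.float64)
            inten = np.asarray(entry.get("intensity array", []), dtype=np.float64)
            if mz.size == 0:
                _skip("no peaks", title)
                continue
            charge = _parse_charge(params)
            if charge is None:
                logger.warning("spectrum %r has no charge; assuming 2+", title)
                charge = 2
            if not (1 <= charge <= MAX_CHARGE):
                _skip(f"unsupported charge {charge}", title)
                continue
            annotation = None
            seq = params.get("seq")
            if seq:
                try:
                    annotation = Peptide.from_string(str(seq))
                except ValueError:
                    _skip(f"unparsable SEQ {seq!r}", title)
                    continue
            is_decoy = str(params.get("decoy", "0")) in ("1", "true", "True")
            if stats is not None:
                stats["read"] += 1
            yield Spectrum(
                mz=mz,
                intensity=inten,
                precursor_mz=float(prec_mz),
                precursor_charge=charge,
                spectrum_id=title,
                annotation=annotation,
                is_decoy=is_decoy,
            )


def write_mgf(spectra: Iterable[Spectrum], path: str | Path, header: str = "") -> None:
    """Write spectra to MGF (m/z to 5 decimals, intensity to 4)."""
    entries = []
    for sp in spectra:
        params: dict = {
            "title": sp.spectrum_id,
            "pepmass": round(float(sp.precursor_mz), 5),
            "charge": sp.precursor_charge,
        }
        if sp.annotation is not None:
            params["seq"] = str(sp.annotation)
        if sp.is_decoy:
            params["decoy"] = 1
        entries.append(
            {
                "m/z array": np.round(sp.mz, 5),
                "intensity array": np.round(sp.intensity, 4),
                "params": params,
            }
        )
    with open(path, "w") as handle:
        if header:
            for line in header.rstrip("\n").split("\n"):
                handle.write(f"# {line}\n")
        _mgf.write(
            entries,
            handle,
            fragment_format="%.5f %.4f",
            write_charges=False,
        )


def preprocess(
    sp: Spectrum,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    min_mz: float = DEFAULT_MIN_MZ,
    max_mz: float = DEFAULT_MAX_MZ,
) -> Spectrum:
    """Filter to [min_mz, max_mz], keep the ``max_peaks`` most intense peaks and
    scale intensities to unit Euclidean norm.

    Returns a spectrum with zero peaks when everything is filtered away; callers
    should skip such spectra. Idempotent.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    keep = (sp.mz >= min_mz) & (sp.mz <= max_mz)
    mz, inten = sp.mz[keep], sp.intensity[keep]
    if mz.size > max_peaks:
        top = np.argsort(inten, kind="stable")[-max_peaks:]
        top.sort()
        mz, inten = mz[top], inten[top]
    norm = float(np.linalg.norm(inten))
    if norm > 0:
        inten = inten / norm
    return sp.copy(mz=mz, intensity=inten)
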