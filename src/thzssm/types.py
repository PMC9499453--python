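"""Core containers: sampled absorbance spectra, peak inventories, databases.

A :class:`Spectrum` is a sampled absorbance curve on a strictly increasing
frequency grid in THz.  A :class:`PeakList` is the ordered set of spectral
feature points (fingerprint peaks) of one analyte, either measured or taken
from a quantum-chemical (DFT) simulation.  A :class:`SpectralDatabase` maps
analyte names to (Spectrum, PeakList) pairs and is the corpus every library
search runs over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import DatabaseError, InputTooShortError

#: Qualitative peak-strength labels as used in vibrational spectroscopy tables
#: (very weak ... very strong); "none" marks an unlabeled peak.
STRENGTH_LABELS = ("vw", "w", "m", "s", "vs", "none")

MIN_SPECTRUM_LENGTH = 8


@dataclass
class Peak:
    """One spectral feature point: center frequency (THz), intensity, label."""

    freq: float
    intensity: float
    label: str = "none"

    def __post_init__(self):
        self.freq = float(self.freq)
        self.intensity = float(self.intensity)
        if not np.isfinite(self.freq):
            raise ValueError(f"peak frequency must be finite, got {self.freq}")
        if not np.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError(
                f"peak intensity must be finite and >= 0, got {self.intensity}"
            )
        if self.label not in STRENGTH_LABELS:
            raise ValueError(
                f"unknown strength label {self.label!r}; expected one of {STRENGTH_LABELS}"
            )


@dataclass
class PeakList:
    """Ordered fingerprint peaks of one analyte.

    Parameters
    ----------
    analyte : str
        Analyte name the peaks belong to.
    source : {"experimental", "dft"}
        Whether the peaks were measured or simulated.
    peaks : list of Peak
        Strictly increasing in frequency.
    """

    analyte: str
    source: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        if self.source not in ("experimental", "dft"):
            raise ValueError(f"source must be 'experimental' or 'dft', got {self.source!r}")
        freqs = [p.freq for p in self.peaks]
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError(
                f"peak frequencies of {self.analyte!r} must be strictly increasing: {freqs}"
            )

    @property
    def freqs(self) -> np.ndarray:
        return np.array([p.freq for p in self.peaks], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]


@dataclass
class Spectrum:
    """A sampled absorbance curve on a strictly increasing THz frequency grid."""

    name: str
    freq: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.freq.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("freq and absorbance must be 1-D arrays")
        if self.freq.shape != self.absorbance.shape:
            raise ValueError(
                f"freq and absorbance lengths differ: {len(self.freq)} vs {len(self.absorbance)}"
            )
        if len(self.freq) < MIN_SPECTRUM_LENGTH:
            raise InputTooShortError(
                f"spectrum {self.name!r} has {len(self.freq)} points; "
                f"at least {MIN_SPECTRUM_LENGTH} are required"
            )
        if not np.all(np.isfinite(self.freq)) or not np.all(np.isfinite(self.absorbance)):
            raise ValueError(f"spectrum {self.name!r} contains non-finite values")
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError(f"frequency grid of {self.name!r} must be strictly increasing")

    @property
    def step(self) -> float:
        """Median grid spacing in THz."""
        return float(np.median(np.diff(self.freq)))

    def copy(self) -> "Spectrum":
        return Spectrum(self.name, self.freq.copy(), self.absorbance.copy(), dict(self.meta))

    def with_absorbance(self, y: np.ndarray, name: str | None = None) -> "Spectrum":
        """New Spectrum on the same grid with replaced absorbance values."""
        return Spectrum(name or self.name, self.freq.copy(), np.asarray(y, float), dict(self.meta))


@dataclass
class DatabaseEntry:
    spectrum: Spectrum
    peaks: PeakList


@dataclass
class SpectralDatabase:
    """Named standard spectra with their peak lists; the search corpus."""

    entries: dict[str, DatabaseEntry]
    provenance: str = ""

    def __post_init__(self):
        if not self.entries:
            raise DatabaseError("spectral database is empty")
        for name, entry in self.entries.items():
            if entry.spectrum.name != name or entry.peaks.analyte != name:
                raise DatabaseError(
                    f"database entry {name!r} has mismatched labels "
                    f"(spectrum {entry.spectrum.name!r}, peaks {entry.peaks.analyte!r})"
                )

    @property
    def names(self) -> list[str]:
        return list(self.entries.keys())

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> DatabaseEntry:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def items(self):
        return self.entries.items()
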