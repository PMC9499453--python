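"""Synthetic THz absorbance spectra emulating the measurement regime.

Spectra are sums of Lorentzian (default) or Gaussian lines centered at
fingerprint peak positions, sampled on a 0.5-3.5 THz grid at 30 GHz
resolution, plus an optional smooth drifting baseline (low-order polynomial
and an exponential rise term in the reduced coordinate u = (f - fmin)/span)
and additive Gaussian noise.  Line heights follow the qualitative
strength-label convention (vw 0.1 ... vs 1.0); widths default to 0.08 THz
FWHM so that neighboring fingerprint peaks of one analyte stay resolvable.

Replicate generation emulates pellet-to-pellet variation with Gaussian
peak-position jitter (default sd 0.01 THz), +-10% amplitude jitter, and
fresh measurement noise.  All randomness is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ANALOG_ABBREVIATIONS, STRENGTH_AMPLITUDES, builtin_table1
from .types import DatabaseEntry, Peak, PeakList, SpectralDatabase, Spectrum

__all__ = [
    "SynthConfig",
    "generate_spectrum",
    "generate_database",
    "generate_replicates",
    "replicate_database_entries",
]


@dataclass
class SynthConfig:
    """Conditions of the emulated measurement."""

    freq_min: float = 0.5          # THz
    freq_max: float = 3.5          # THz
    resolution: float = 0.03       # THz (30 GHz instrument resolution)
    lineshape: str = "lorentzian"  # or "gaussian"
    default_width: float = 0.08    # FWHM, THz
    strength_map: dict = field(default_factory=lambda: dict(STRENGTH_AMPLITUDES))
    baseline_poly: tuple = ()      # polynomial coeffs in u, low order first
    baseline_exp_amp: float = 0.0  # amplitude of exp rise toward freq_max
    baseline_exp_rate: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.freq_min >= self.freq_max:
            raise ValueError("freq_min must be < freq_max")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.default_width <= 0:
            raise ValueError("default_width must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")

    def grid(self) -> np.ndarray:
        n = int(round((self.freq_max - self.freq_min) / self.resolution)) + 1
        return self.freq_min + self.resolution * np.arange(n)


def _baseline(cfg: SynthConfig, freq: np.ndarray) -> np.ndarray:
    u = (freq - cfg.freq_min) / (cfg.freq_max - cfg.freq_min)
    y = np.zeros_like(freq)
    for k, c in enumerate(cfg.baseline_poly):
        y += c * u**k
    if cfg.baseline_exp_amp:
        y += cfg.baseline_exp_amp * np.exp(cfg.baseline_exp_rate * (u - 1.0))
    return y


def _amplitude(peak: Peak, cfg: SynthConfig) -> float:
    if peak.label != "none" and peak.label in cfg.strength_map:
        return float(cfg.strength_map[peak.label])
    return peak.intensity


def generate_spectrum(
    peaks: PeakList,
    cfg: SynthConfig | None = None,
    *,
    name: str | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Synthesize one absorbance spectrum from a fingerprint peak list.

    Deterministic for a fixed ``cfg.seed`` (an explicit ``rng`` takes
    precedence, for callers drawing several spectra from one stream).
    """
    cfg = cfg or SynthConfig()
    for p in peaks:
        if not (cfg.freq_min <= p.freq <= cfg.freq_max):
            raise ValueError(
                f"peak at {p.freq:g} THz of {peaks.analyte!r} lies outside the "
                f"simulated range [{cfg.freq_min:g}, {cfg.freq_max:g}] THz"
            )
    freq = cfg.grid()
    y = _baseline(cfg, freq)
    half = cfg.default_width / 2.0
    for p in peaks:
        amp = _amplitude(p, cfg)
        if cfg.lineshape == "lorentzian":
            y = y + amp * half**2 / ((freq - p.freq) ** 2 + half**2)
        else:
            y = y + amp * np.exp(-4.0 * np.log(2.0) * (freq - p.freq) ** 2 / cfg.default_width**2)
    if cfg.noise_sd > 0:
        rng = rng or np.random.default_rng(cfg.seed)
        y = y + rng.normal(0.0, cfg.noise_sd, size=freq.shape)
    return Spectrum(name or peaks.analyte, freq, y, {"synthetic": "true"})


def generate_database(
    source: str = "table1_experimental",
    cfg: SynthConfig | None = None,
) -> SpectralDatabase:
    """Synthetic 8-analog database from the packaged fingerprint inventory.

    ``source`` selects the experimental ("table1_experimental") or
    DFT-simulated ("table1_dft") peak positions.  Entries are named by the
    standard abbreviations (FN, MF, AF, FF, BF, FBF, CF, VF) and store both
    the synthesized spectrum and the originating peak list.
    """
    if source not in ("table1_experimental", "table1_dft"):
        raise ValueError(f"unknown database source {source!r}")
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    entries: dict[str, DatabaseEntry] = {}
    for analyte, pair in builtin_table1().items():
        pl = pair.experimental if source == "table1_experimental" else pair.dft
        abbrev = ANALOG_ABBREVIATIONS[analyte]
        spec = generate_spectrum(pl, cfg, name=abbrev, rng=rng)
        spec.meta["analyte"] = analyte
        peaks = PeakList(
            abbrev, pl.source, [Peak(p.freq, p.intensity, p.label) for p in pl]
        )
        entries[abbrev] = DatabaseEntry(spec, peaks)
    return SpectralDatabase(entries, provenance=f"synthetic ({source})")


def _jitter_peaks(
    pl: PeakList,
    rng: np.random.Generator,
    jitter_freq_sd: float,
    amp_jitter_frac: float,
    fmin: float,
    fmax: float,
) -> PeakList:
    freqs = pl.freqs + rng.normal(0.0, jitter_freq_sd, size=len(pl)) if jitter_freq_sd > 0 \
        else pl.freqs.copy()
    freqs = np.clip(np.sort(freqs), fmin, fmax)
    # enforce strict ordering after clipping/jitter collisions
    for k in range(1, len(freqs)):
        if freqs[k] <= freqs[k - 1]:
            freqs[k] = freqs[k - 1] + 1e-9
    if amp_jitter_frac > 0:
        factors = 1.0 + rng.uniform(-amp_jitter_frac, amp_jitter_frac, size=len(pl))
    else:
        factors = np.ones(len(pl))
    peaks = [
        Peak(float(f), float(p.intensity * c), "none")
        for f, p, c in zip(freqs, pl.peaks, factors)
    ]
    return PeakList(pl.analyte, "experimental", peaks)


def replicate_database_entries(
    db: SpectralDatabase,
    n_rep: int,
    *,
    jitter_freq_sd: float = 0.01,
    amp_jitter_frac: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    cfg: SynthConfig | None = None,
) -> list[tuple[str, Spectrum]]:
    """Labeled synthetic replicates of every entry of an existing database."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if jitter_freq_sd < 0 or noise_sd < 0 or amp_jitter_frac < 0:
        raise ValueError("jitter and noise parameters must be >= 0")
    cfg = cfg or SynthConfig()
    cfg = replace(cfg, noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    out = []
    for name in db.names:
        base = db[name].peaks
        for _ in range(n_rep):
            # amplitudes for labeled peaks come from the strength map; resolve
            # them first so amplitude jitter applies to the realized height
            resolved = PeakList(
                base.analyte,
                "experimental",
                [Peak(p.freq, _amplitude(p, cfg), "none") for p in base],
            )
            jittered = _jitter_peaks(
                resolved, rng, jitter_freq_sd, amp_jitter_frac,
                cfg.freq_min, cfg.freq_max,
            )
            spec = generate_spectrum(jittered, cfg, name=name, rng=rng)
            out.append((name, spec))
    return out


def generate_replicates(
    db_cfg: SynthConfig | None = None,
    n_rep: int = 10,
    jitter_freq_sd: float = 0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    amp_jitter_frac: float = 0.1,
    source: str = "table1_experimental",
) -> list[tuple[str, Spectrum]]:
    """Ground-truth-labeled replicate spectra of the eight analogs.

    With zero jitter (frequency and amplitude) and zero noise the replicates
    are identical to the corresponding ``generate_database`` entries.
    """
    db = generate_database(source, db_cfg)
    return replicate_database_entries(
        db,
        n_rep,
        jitter_freq_sd=jitter_freq_sd,
        amp_jitter_frac=amp_jitter_frac,
        noise_sd=noise_sd,
        seed=seed,
        cfg=db_cfg,
    )
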