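"""Baseline estimation, denoising, normalization, resampling, peak finding.

Baseline correction uses BEADS (baseline estimation and denoising with
sparsity): the measured absorbance y is decomposed additively as

    y = f + x + w

with f a low-pass baseline, x a peak signal whose derivatives are sparse and
whose negative excursions are penalized asymmetrically (absorption peaks are
nonnegative), and w residual noise.  The estimate minimizes

    1/2 ||H(y - x)||^2  +  lam0 * theta_r(x)
        + lam1 * sum phi(D1 x) + lam2 * sum phi(D2 x)

where H = B A^{-1} is a banded zero-phase high-pass filter of order ``d`` and
cutoff ``fc`` (cycles/sample), theta_r the asymmetric penalty with ratio r,
phi(u) = sqrt(u^2 + eps) a smoothed absolute value, and D1, D2 first and
second difference operators.  The problem is solved by majorization-
minimization (MM); each iteration solves one banded sparse linear system,
and the objective is non-increasing.  The baseline is recovered as
f = lowpass(y - x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve
from scipy.stats import median_abs_deviation

from .errors import InputTooShortError, NoOverlapError
from .types import MIN_SPECTRUM_LENGTH, Peak, PeakList, Spectrum

__all__ = [
    "BeadsParams",
    "BeadsResult",
    "PeakFindParams",
    "beads",
    "find_peaks",
    "corrected_peaks",
    "resample_common",
    "normalize",
]


# ---------------------------------------------------------------------------
# BEADS
# ---------------------------------------------------------------------------

@dataclass
class BeadsParams:
    """Tuning parameters for the BEADS decomposition.

    ``lam0``, ``lam1``, ``lam2`` default to (0.5, 5, 4) times an amplitude
    scale estimated per spectrum as the median absolute deviation of the
    first difference of the absorbance (robust to both peaks and drift).
    """

    filt_order: int = 1
    cutoff: float = 0.03         # normalized cutoff, cycles/sample
    asym_ratio: float = 6.0      # penalty ratio r for negative excursions
    lam0: float | None = None
    lam1: float | None = None
    lam2: float | None = None
    n_iter: int = 30
    eps: float = 1e-5            # smoothing constant of phi

    def __post_init__(self):
        if not (0.0 < self.cutoff < 0.5):
            raise ValueError(f"cutoff must be in (0, 0.5), got {self.cutoff}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.filt_order < 1:
            raise ValueError("filt_order must be >= 1")
        for name in ("lam0", "lam1", "lam2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


@dataclass
class BeadsResult:
    """Additive decomposition baseline + signal + residual of one spectrum."""

    baseline: np.ndarray
    signal: np.ndarray
    residual: np.ndarray
    n_iter_used: int
    objective_trace: np.ndarray
    converged: bool = True

    def corrected(self, s: Spectrum) -> Spectrum:
        """Baseline-corrected, denoised spectrum (the clean signal component)."""
        return s.with_absorbance(self.signal)


def _ba_filters(d: int, fc: float, n: int):
    """Banded matrices A, B such that H = B A^{-1} is a zero-phase high-pass."""
    b = np.array([1.0, -1.0])
    for _ in range(d - 1):
        b = np.convolve(b, [-1.0, 2.0, -1.0])
    b = np.convolve(b, [-1.0, 1.0])
    om = 2.0 * np.pi * fc
    t = ((1.0 - np.cos(om)) / (1.0 + np.cos(om))) ** d
    a = np.array([1.0])
    for _ in range(d):
        a = np.convolve(a, [1.0, 2.0, 1.0])
    a = b + t * a
    offsets = list(range(-d, d + 1))
    A = sparse.diags(
        [np.full(n - abs(k), a[k + d]) for k in offsets], offsets, format="csc"
    )
    B = sparse.diags(
        [np.full(n - abs(k), b[k + d]) for k in offsets], offsets, format="csc"
    )
    return A, B


def _theil_sen_slope(y: np.ndarray) -> float:
    """Median of pairwise slopes; robust to a peak sitting near the window edge."""
    n = len(y)
    if n < 2:
        return 0.0
    idx = np.arange(n)
    di = idx[None, :] - idx[:, None]
    dy = y[None, :] - y[:, None]
    mask = di > 0
    return float(np.median(dy[mask] / di[mask]))


def _theta_asym(x: np.ndarray, r: float, eps0: float) -> float:
    """Asymmetric sparsity penalty: ~x for x>0, ~-r*x for x<0, smoothed near 0."""
    pos = x > eps0
    neg = x < -eps0
    mid = ~(pos | neg)
    total = float(np.sum(x[pos])) - r * float(np.sum(x[neg]))
    xm = x[mid]
    total += float(
        np.sum((1 + r) / (4 * eps0) * xm**2 + (1 - r) / 2 * xm + eps0 * (1 + r) / 4)
    )
    return total


def beads(s: Spectrum, p: BeadsParams | None = None) -> BeadsResult:
    """BEADS decomposition of ``s`` into baseline + clean signal + residual.

    The spectrum is extended by anti-symmetric (slope-preserving) reflection
    at both ends before filtering to suppress boundary transients, and the
    decomposition is cropped back to the original grid.  The additive
    identity baseline + signal + residual = absorbance holds exactly.

    Never raises on non-convergence: after ``n_iter`` MM iterations the best
    iterate is returned with ``converged=False``.
    """
    p = p or BeadsParams()
    y_in = np.asarray(s.absorbance, dtype=float)
    n0 = len(y_in)
    # Work on the median-centered signal: the DC level belongs to the baseline
    # by definition, and removing it up front keeps the filters' truncated
    # boundary rows from leaking a large offset into the peak signal.
    offset = float(np.median(y_in))
    y0 = y_in - offset

    # Roughness scale: MAD of the first difference estimates the noise, but
    # vanishes on noiseless smooth input (constant diffs), which would switch
    # the penalties off entirely; floor it at a small fraction of the dynamic
    # range so the decomposition stays regularized.
    scale = max(
        float(median_abs_deviation(np.diff(y0))),
        5e-3 * float(np.ptp(y0)),
    )
    lam0 = p.lam0 if p.lam0 is not None else 0.5 * scale
    lam1 = p.lam1 if p.lam1 is not None else 5.0 * scale
    lam2 = p.lam2 if p.lam2 is not None else 4.0 * scale

    # Linear edge extension, long relative to the low-pass transient
    # (~1/cutoff samples): the filters' truncated-boundary artifacts then
    # fall entirely in the padding and are cropped away.
    pad = int(min(2000, max(40, round(1.5 / p.cutoff))))
    m = min(15, n0 - 1)
    slope_lo = _theil_sen_slope(y0[: m + 1])
    slope_hi = _theil_sen_slope(y0[-(m + 1):])
    left = y0[0] + slope_lo * np.arange(-pad, 0)
    right = y0[-1] + slope_hi * np.arange(1, pad + 1)
    y = np.concatenate([left, y0, right])
    n = len(y)
    A, B = _ba_filters(p.filt_order, p.cutoff, n)
    BTB = (B.T @ B).tocsc()

    def highpass(v):
        return B @ spsolve(A, v)

    crop = slice(pad, pad + n0)

    if lam0 == 0.0 and lam1 == 0.0 and lam2 == 0.0:
        # degenerate no-penalty case (e.g. a constant spectrum): everything
        # smooth goes to the baseline, nothing to the peak signal
        h = highpass(y)
        baseline = (y - h)[crop] + offset
        residual = h[crop]
        signal = y_in - baseline - residual
        return BeadsResult(baseline, signal, residual, 0, np.array([0.0]), True)

    e1 = np.ones(n - 1)
    D1 = sparse.diags([-e1, e1], [0, 1], shape=(n - 1, n), format="csc")
    e2 = np.ones(n - 2)
    D2 = sparse.diags([e2, -2 * e2, e2], [0, 1, 2], shape=(n - 2, n), format="csc")
    D = sparse.vstack([D1, D2]).tocsc()
    w = np.concatenate([lam1 * np.ones(n - 1), lam2 * np.ones(n - 2)])

    eps0 = 1e-6  # transition half-width of the asymmetric penalty
    b_lin = (1.0 - p.asym_ratio) / 2.0 * np.ones(n)
    d_vec = BTB @ spsolve(A, y) - lam0 * (A.T @ b_lin)

    def objective(x):
        hp = highpass(y - x)
        cost = 0.5 * float(hp @ hp)
        cost += lam0 * _theta_asym(x, p.asym_ratio, eps0)
        cost += lam1 * float(np.sum(np.sqrt((D1 @ x) ** 2 + p.eps)))
        cost += lam2 * float(np.sum(np.sqrt((D2 @ x) ** 2 + p.eps)))
        return cost

    # Start from the high-pass part of y: constants and slow drift (the
    # filter's null space, which the data term cannot see) then begin in the
    # baseline rather than in x, where weak penalties could strand them.
    x = highpass(y)
    trace = []
    converged = False
    it = 0
    for it in range(1, p.n_iter + 1):
        Dx = D @ x
        lam_diag = w / np.sqrt(Dx**2 + p.eps)
        absx = np.abs(x)
        gamma = np.where(
            absx > eps0,
            (1 + p.asym_ratio) / (4 * np.maximum(absx, eps0)),
            (1 + p.asym_ratio) / (4 * eps0),
        )
        M = 2 * lam0 * sparse.diags(gamma) + D.T @ sparse.diags(lam_diag) @ D
        Q = (BTB + A.T @ M @ A).tocsc()
        x = A @ spsolve(Q, d_vec)
        trace.append(objective(x))
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) <= 1e-10 * max(1.0, abs(trace[-2])):
            converged = True
            break

    residual_full = highpass(y - x)
    baseline = (y - x - residual_full)[crop] + offset
    residual = residual_full[crop]
    signal = y_in - baseline - residual  # enforces the identity exactly
    return BeadsResult(baseline, signal, residual, it, np.array(trace), converged)


# ---------------------------------------------------------------------------
# peak finding
# ---------------------------------------------------------------------------

@dataclass
class PeakFindParams:
    """Local-maximum peak detection with prominence and separation filters.

    ``min_prominence`` is a fraction of the maximum absolute signal amplitude,
    making detection invariant to intensity rescaling.  ``min_separation`` and
    ``edge_margin`` are in THz.
    """

    min_prominence: float = 0.03
    min_separation: float = 0.09
    edge_margin: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.min_prominence < 1.0):
            raise ValueError("min_prominence must be in (0, 1)")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be > 0")
        if self.edge_margin < 0:
            raise ValueError("edge_margin must be >= 0")


def find_peaks(s: Spectrum, p: PeakFindParams | None = None) -> PeakList:
    """Detect absorption peaks as prominent, well-separated local maxima."""
    p = p or PeakFindParams()
    y = s.absorbance
    amp = float(np.max(np.abs(y)))
    if amp == 0.0:
        return PeakList(s.name, "experimental", [])
    step = s.step
    distance = max(1, int(round(p.min_separation / step)))
    idx, _ = _scipy_find_peaks(y, prominence=p.min_prominence * amp, distance=distance)
    lo = s.freq[0] + p.edge_margin
    hi = s.freq[-1] - p.edge_margin
    peaks = [
        Peak(float(s.freq[i]), max(float(y[i]), 0.0), "none")
        for i in idx
        if lo <= s.freq[i] <= hi
    ]
    return PeakList(s.name, "experimental", peaks)


def corrected_peaks(
    s: Spectrum,
    beads_params: BeadsParams | None = None,
    peak_params: PeakFindParams | None = None,
    *,
    noise_floor_k: float = 3.5,
) -> tuple[Spectrum, PeakList]:
    """Full detection pipeline: BEADS, then noise-aware peak finding.

    Peak *positions* are local maxima of the lightly smoothed (Savitzky-Golay,
    window 5, order 2) baseline-corrected curve, with prominence at least the
    larger of ``min_prominence``  x  max amplitude and ``noise_floor_k``
    standard deviations of the noise (estimated robustly from the BEADS
    residual).  Peak *intensities* are read from the unsmoothed
    baseline-corrected curve, which preserves true line heights that the
    sparsity shrinkage of the BEADS clean signal attenuates.

    Returns the denoised clean-signal spectrum and the detected peak list.
    An empty peak list (e.g. overwhelming noise) is a valid result.
    """
    pp = peak_params or PeakFindParams()
    decomp = beads(s, beads_params)
    corrected = s.absorbance - decomp.baseline
    sigma = 1.4826 * float(median_abs_deviation(decomp.residual))
    smoothed = savgol_filter(corrected, min(5, len(corrected) // 2 * 2 - 1), 2)
    amp = float(np.max(np.abs(smoothed)))
    peaks: list[Peak] = []
    if amp > 0:
        prominence = max(pp.min_prominence * amp, noise_floor_k * sigma)
        distance = max(1, int(round(pp.min_separation / s.step)))
        idx, _ = _scipy_find_peaks(smoothed, prominence=prominence, distance=distance)
        lo = s.freq[0] + pp.edge_margin
        hi = s.freq[-1] - pp.edge_margin
        peaks = [
            Peak(float(s.freq[i]), max(float(corrected[i]), 0.0), "none")
            for i in idx
            if lo <= s.freq[i] <= hi
        ]
    return decomp.corrected(s), PeakList(s.name, "experimental", peaks)


# ---------------------------------------------------------------------------
# resampling and normalization
# ---------------------------------------------------------------------------

def resample_common(a: Spectrum, b: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Interpolate two spectra onto their common frequency grid.

    If the grids are already identical the inputs are returned unchanged.
    Otherwise both are linearly interpolated onto the intersection of their
    ranges, sampled at the coarser of the two resolutions.
    """
    if len(a.freq) == len(b.freq) and np.array_equal(a.freq, b.freq):
        return a, b
    lo = max(a.freq[0], b.freq[0])
    hi = min(a.freq[-1], b.freq[-1])
    if hi <= lo:
        raise NoOverlapError(
            f"spectra {a.name!r} ({a.freq[0]:g}-{a.freq[-1]:g} THz) and {b.name!r} "
            f"({b.freq[0]:g}-{b.freq[-1]:g} THz) have no overlapping frequency range"
        )
    step = max(a.step, b.step)
    npts = int(np.floor((hi - lo) / step + 1e-9)) + 1
    if npts < MIN_SPECTRUM_LENGTH:
        raise InputTooShortError(
            f"common grid of {a.name!r} and {b.name!r} has only {npts} points"
        )
    grid = lo + step * np.arange(npts)
    ya = np.interp(grid, a.freq, a.absorbance)
    yb = np.interp(grid, b.freq, b.absorbance)
    return (
        Spectrum(a.name, grid, ya, dict(a.meta)),
        Spectrum(b.name, grid.copy(), yb, dict(b.meta)),
    )


def normalize(s: Spectrum, method: str = "vector") -> Spectrum:
    """Normalize absorbance: unit Euclidean norm ('vector'), [0, 1] ('minmax'),
    or pass through ('none')."""
    y = s.absorbance
    if method == "none":
        return s.copy()
    if method == "vector":
        nrm = float(np.linalg.norm(y))
        if nrm == 0.0:
            raise ValueError(f"cannot vector-normalize all-zero spectrum {s.name!r}")
        return s.with_absorbance(y / nrm)
    if method == "minmax":
        lo, hi = float(np.min(y)), float(np.max(y))
        if hi == lo:
            raise ValueError(f"cannot min-max normalize constant spectrum {s.name!r}")
        return s.with_absorbance((y - lo) / (hi - lo))
    raise ValueError(f"unknown normalization method {method!r}")
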