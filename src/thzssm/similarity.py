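"""Pairwise spectral comparison measures.

Four measures are provided.  Two act on full absorbance curves sampled on a
common grid: cosine similarity (CS) and cross-correlated cosine similarity
(CCS, the maximum cosine over a range of relative lags, reported with its
dominant lag).  Two act on fingerprint point sets derived from peak lists:
the Hausdorff distance (HD) and the discrete Fréchet distance (DFD, the
order-preserving "dog-leash" distance over monotone couplings).

Peak-derived point sets are made dimensionless before HD/DFD: frequency is
scaled by the full spectral span and intensity is min-max scaled per list,
so both axes live in [0, 1] and neither dominates by choice of units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, directed_hausdorff

from .errors import EmptyPeakListError
from .preprocess import normalize, resample_common
from .types import PeakList, SpectralDatabase

__all__ = [
    "CcsResult",
    "SimilarityMatrix",
    "cosine_similarity",
    "cross_cosine_similarity",
    "hausdorff_distance",
    "discrete_frechet",
    "fingerprint_points",
    "similarity_matrix",
    "combine_scores",
]

SIMILARITY_METRICS = ("cs", "ccs")
DISTANCE_METRICS = ("hd", "dfd")


def cosine_similarity(a, b, variant: str = "standard") -> float:
    """Cosine of the angle between two equal-length vectors.

    ``variant="standard"`` is the plain cosine similarity
    dot(a, b) / (||a|| ||b||), clamped to [-1, 1] against floating-point
    drift.  ``variant="as_printed"`` composes cos((180/pi) * arccos(.)) on
    top of it; it exists only to document a degrees-conversion quirk found
    in some formulations and should not be used for scoring.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    c = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    if variant == "standard":
        return c
    if variant == "as_printed":
        return float(np.cos((180.0 / np.pi) * np.arccos(c)))
    raise ValueError(f"unknown cosine variant {variant!r}")


@dataclass(frozen=True)
class CcsResult:
    """Maximum lagged cosine similarity and the lag (grid steps) achieving it."""

    max_value: float
    dominant_lag: int


def cross_cosine_similarity(a, b, max_lag: int = 10) -> CcsResult:
    """Maximum cosine similarity over relative lags in [-max_lag, max_lag].

    For lag ``l >= 0`` the overlapping segments ``a[l:]`` and ``b[:n-l]`` are
    compared (positive lag means features of ``b`` occur ``l`` grid steps
    earlier than in ``a``); negative lags mirror this.  No zero-padding is
    used.  Ties are broken toward smaller ``|lag|``, then toward negative lag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    n = len(a)
    if n < 2 * max_lag + 2:
        raise ValueError(
            f"vectors of length {n} are too short for max_lag={max_lag} "
            f"(need length >= {2 * max_lag + 2})"
        )
    best_val = -np.inf
    best_lag = 0
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            seg_a, seg_b = a[lag:], b[: n - lag]
        else:
            seg_a, seg_b = a[: n + lag], b[-lag:]
        val = cosine_similarity(seg_a, seg_b)
        if val > best_val:
            best_val, best_lag = val, lag
    return CcsResult(max_value=best_val, dominant_lag=best_lag)


def hausdorff_distance(P, Q) -> float:
    """Symmetric Hausdorff distance between two nonempty 2-D point sets."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.size == 0 or Q.size == 0:
        raise ValueError("Hausdorff distance is undefined for an empty point set")
    return max(directed_hausdorff(P, Q)[0], directed_hausdorff(Q, P)[0])


def discrete_frechet(P, Q) -> float:
    """Discrete Fréchet distance between two nonempty ordered point sequences.

    Standard dynamic program over the coupling lattice: among all monotone,
    order-preserving couplings of the two sequences, minimize the maximum
    Euclidean distance of any coupled pair.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.size == 0 or Q.size == 0:
        raise ValueError("discrete Fréchet distance is undefined for an empty sequence")
    dmat = cdist(P, Q)
    m, k = dmat.shape
    ca = np.empty((m, k))
    ca[0, 0] = dmat[0, 0]
    for j in range(1, k):
        ca[0, j] = max(ca[0, j - 1], dmat[0, j])
    for i in range(1, m):
        ca[i, 0] = max(ca[i - 1, 0], dmat[i, 0])
        row_prev = ca[i - 1]
        for j in range(1, k):
            ca[i, j] = max(
                dmat[i, j], min(row_prev[j], row_prev[j - 1], ca[i, j - 1])
            )
    return float(ca[-1, -1])


def fingerprint_points(pl: PeakList, freq_min: float, freq_max: float) -> np.ndarray:
    """Dimensionless (m, 2) fingerprint point sequence from a peak list.

    Frequency maps to (f - freq_min) / (freq_max - freq_min); intensity is
    scaled by the list maximum, so both axes live in [0, 1].  (Scaling by the
    maximum rather than min-max keeps the map continuous for lists of nearly
    equal intensities, where min-max would blow measurement noise up to the
    full unit range.)  An all-zero intensity list maps to intensity 1.0
    everywhere.
    """
    if len(pl) == 0:
        raise EmptyPeakListError(f"peak list of {pl.analyte!r} is empty")
    span = freq_max - freq_min
    if span <= 0:
        raise ValueError("freq_max must exceed freq_min")
    x = (pl.freqs - freq_min) / span
    inten = pl.intensities
    hi = float(inten.max())
    y = np.ones_like(inten) if hi == 0.0 else inten / hi
    return np.column_stack([x, y])


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity (cs, ccs) or distance (hd, dfd) matrix."""

    names: list[str]
    metric: str
    values: np.ndarray
    kind: str  # "similarity" | "distance"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} names")
        if self.kind not in ("similarity", "distance"):
            raise ValueError(f"kind must be 'similarity' or 'distance', got {self.kind!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="analyte")


def similarity_matrix(
    db: SpectralDatabase,
    metric: str,
    *,
    max_lag: int = 10,
    normalization: str = "vector",
) -> SimilarityMatrix:
    """Full symmetric pairwise matrix over all database entries.

    cs/ccs act on vector-normalized full spectra resampled pairwise to a
    common grid; hd/dfd act on the entries' fingerprint point sets scaled
    over the database-wide frequency span.
    """
    if metric not in SIMILARITY_METRICS + DISTANCE_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    names = db.names
    n = len(names)
    vals = np.zeros((n, n))
    kind = "similarity" if metric in SIMILARITY_METRICS else "distance"

    if metric in DISTANCE_METRICS:
        fmin = min(db[name].spectrum.freq[0] for name in names)
        fmax = max(db[name].spectrum.freq[-1] for name in names)
        points = {
            name: fingerprint_points(db[name].peaks, fmin, fmax) for name in names
        }

    for i in range(n):
        for j in range(i + 1, n):
            a, b = db[names[i]], db[names[j]]
            try:
                if metric in SIMILARITY_METRICS:
                    sa, sb = resample_common(a.spectrum, b.spectrum)
                    ya = normalize(sa, normalization).absorbance
                    yb = normalize(sb, normalization).absorbance
                    if metric == "cs":
                        v = cosine_similarity(ya, yb)
                    else:
                        v = cross_cosine_similarity(ya, yb, max_lag=max_lag).max_value
                elif metric == "hd":
                    v = hausdorff_distance(points[names[i]], points[names[j]])
                else:
                    v = discrete_frechet(points[names[i]], points[names[j]])
            except Exception as exc:
                raise type(exc)(
                    f"{metric} failed for pair ({names[i]!r}, {names[j]!r}): {exc}"
                ) from exc
            vals[i, j] = vals[j, i] = v
    np.fill_diagonal(vals, 1.0 if kind == "similarity" else 0.0)
    return SimilarityMatrix(names, metric, vals, kind)


def combine_scores(m1: SimilarityMatrix, m2: SimilarityMatrix) -> SimilarityMatrix:
    """Element-wise sum of two same-kind matrices, min-max normalized to [0, 1]
    over the off-diagonal entries.

    If all off-diagonal sums are equal (min = max) they map to 0 by
    convention.  The diagonal is reset to 1 (similarity) or 0 (distance).
    """
    if m1.names != m2.names:
        raise ValueError("matrices must share the same analyte names in the same order")
    if m1.kind != m2.kind:
        raise ValueError(
            f"cannot combine a {m1.kind} matrix ({m1.metric}) with a "
            f"{m2.kind} matrix ({m2.metric})"
        )
    total = m1.values + m2.values
    n = len(m1.names)
    off = ~np.eye(n, dtype=bool)
    lo, hi = total[off].min(), total[off].max()
    out = np.zeros_like(total)
    if hi > lo:
        out[off] = (total[off] - lo) / (hi - lo)
    np.fill_diagonal(out, 1.0 if m1.kind == "similarity" else 0.0)
    return SimilarityMatrix(m1.names, f"{m1.metric}+{m2.metric}", out, m1.kind)
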