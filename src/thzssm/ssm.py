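"""Spectral similarity mapping (SSM): fused scoring and database search.

The SSM accuracy of candidate i in a database of n standards for a target
spectrum S_t is

    Acc_i = alpha * CS_i + beta * (1 - DFD_i / sum_k DFD_k),    alpha + beta = 1

where CS_i is the cosine similarity between the full (vector-normalized)
spectra and DFD_i the discrete Fréchet distance between the dimensionless
fingerprint peak sequences of candidate and target.  The shape term rewards
globally similar absorbance curves; the feature term rewards matching peak
positions and relative intensities, normalized over the whole corpus so the
candidate with the smallest fingerprint distance gains the most.  Searching
scores every database entry and returns the candidates sorted by descending
accuracy; the top hit is the identification call.

Note the corpus-relative normalization makes Acc for a fixed pair depend on
the database contents.  A corpus-independent feature term
1 - DFD_i / (1 + DFD_i) is available via ``dfd_norm="independent"`` for users
who need scores stable across databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CorpusTooSmallError, EmptyPeakListError
from .preprocess import (
    BeadsParams,
    PeakFindParams,
    beads,
    corrected_peaks,
    find_peaks,
    normalize,
    resample_common,
)
from .similarity import (
    cosine_similarity,
    cross_cosine_similarity,
    discrete_frechet,
    fingerprint_points,
)
from .types import Peak, PeakList, SpectralDatabase, Spectrum

__all__ = [
    "SsmWeights",
    "MatchHit",
    "MatchList",
    "PeakPairing",
    "ssm_accuracy",
    "search",
    "pair_peaks",
    "identification_rate",
]


@dataclass(frozen=True)
class SsmWeights:
    """Weights of the shape (alpha) and feature (beta) terms; alpha + beta = 1."""

    alpha: float = 0.2
    beta: float = 0.8

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(f"weights must be nonnegative: alpha={self.alpha}, beta={self.beta}")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError(
                f"weights must satisfy alpha + beta = 1, got {self.alpha} + {self.beta}"
            )


@dataclass(frozen=True)
class MatchHit:
    name: str
    acc: float
    shape: float  # CS (or CCS) component
    dfd: float    # raw fingerprint discrete Fréchet distance


@dataclass
class MatchList:
    """Ranked candidate identities for one target spectrum."""

    target_name: str
    hits: list[MatchHit]
    weights: SsmWeights

    @property
    def top_hit(self) -> MatchHit:
        return self.hits[0]

    def __len__(self):
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


def ssm_accuracy(
    target: Spectrum,
    target_peaks: PeakList,
    db: SpectralDatabase,
    w: SsmWeights = SsmWeights(),
    *,
    shape_term: str = "cs",
    dfd_norm: str = "corpus",
    max_lag: int = 10,
) -> dict[str, MatchHit]:
    """Fused SSM accuracy of every database candidate for one target.

    ``shape_term`` selects plain cosine similarity ("cs", default) or the
    maximum lagged cosine ("ccs").  ``dfd_norm="corpus"`` normalizes each
    fingerprint distance by the corpus total; "independent" uses
    1 - DFD/(1+DFD) instead.  If all fingerprint distances are zero the
    feature term is 1 for every candidate (degenerate corpus).
    """
    if len(db) < 2:
        raise CorpusTooSmallError(
            f"database search needs at least 2 entries, got {len(db)}"
        )
    if len(target_peaks) == 0:
        raise EmptyPeakListError(
            f"target {target.name!r} has no peaks; run preprocess.find_peaks "
            "(after baseline correction) first"
        )
    if shape_term not in ("cs", "ccs"):
        raise ValueError(f"shape_term must be 'cs' or 'ccs', got {shape_term!r}")
    if dfd_norm not in ("corpus", "independent"):
        raise ValueError(f"dfd_norm must be 'corpus' or 'independent', got {dfd_norm!r}")

    names = db.names
    fmin = min([target.freq[0]] + [db[n].spectrum.freq[0] for n in names])
    fmax = max([target.freq[-1]] + [db[n].spectrum.freq[-1] for n in names])
    target_fp = fingerprint_points(target_peaks, fmin, fmax)

    shapes = {}
    dfds = {}
    for name in names:
        entry = db[name]
        st, si = resample_common(target, entry.spectrum)
        yt = normalize(st, "vector").absorbance
        yi = normalize(si, "vector").absorbance
        if shape_term == "cs":
            shapes[name] = cosine_similarity(yt, yi)
        else:
            shapes[name] = cross_cosine_similarity(yt, yi, max_lag=max_lag).max_value
        dfds[name] = discrete_frechet(
            fingerprint_points(entry.peaks, fmin, fmax), target_fp
        )

    total_dfd = sum(dfds.values())
    out = {}
    for name in names:
        if dfd_norm == "independent":
            feature = 1.0 - dfds[name] / (1.0 + dfds[name])
        elif total_dfd > 0.0:
            feature = 1.0 - dfds[name] / total_dfd
        else:
            feature = 1.0
        acc = w.alpha * shapes[name] + w.beta * feature
        out[name] = MatchHit(name=name, acc=acc, shape=shapes[name], dfd=dfds[name])
    return out


def search(
    target: Spectrum,
    db: SpectralDatabase,
    w: SsmWeights = SsmWeights(),
    peak_params: PeakFindParams | None = None,
    *,
    target_peaks: PeakList | None = None,
    shape_term: str = "cs",
    dfd_norm: str = "corpus",
    preprocess: bool = False,
    beads_params: BeadsParams | None = None,
) -> MatchList:
    """Search the database for the target's identity.

    Scores every entry with :func:`ssm_accuracy` and returns a
    :class:`MatchList` sorted by descending accuracy (ties broken
    lexicographically by name); the top hit is the identification call.
    With ``preprocess=True`` the target is first BEADS baseline-corrected
    and denoised; the shape term and the peak *positions* use the clean
    signal component, while detected peak *intensities* are read from the
    baseline-corrected raw curve (absorbance minus baseline), which
    preserves true line heights that the sparsity shrinkage of the clean
    signal attenuates.  Target peaks are detected automatically unless
    ``target_peaks`` is given.
    """
    if preprocess:
        clean, detected = corrected_peaks(target, beads_params, peak_params)
        target = clean
        if target_peaks is None:
            target_peaks = detected
    if target_peaks is None:
        target_peaks = find_peaks(target, peak_params)
    scores = ssm_accuracy(
        target, target_peaks, db, w,
        shape_term=shape_term, dfd_norm=dfd_norm,
    )
    hits = sorted(scores.values(), key=lambda h: (-h.acc, h.name))
    return MatchList(target_name=target.name, hits=hits, weights=w)


# ---------------------------------------------------------------------------
# DFT <-> experimental peak pairing
# ---------------------------------------------------------------------------

@dataclass
class PeakPairing:
    """One-to-one assignment of simulated to measured peaks.

    ``pairs`` holds (dft_freq, exp_freq, shift) with shift = dft - exp.
    """

    analyte: str
    pairs: list[tuple[float, float, float]]
    unmatched_dft: list[float] = field(default_factory=list)
    unmatched_exp: list[float] = field(default_factory=list)
    tolerance: float = 0.15


def pair_peaks(dft: PeakList, exp: PeakList, tolerance: float = 0.15) -> PeakPairing:
    """Optimal order-preserving one-to-one pairing of DFT and measured peaks.

    Dynamic programming over the two sorted lists maximizes the number of
    pairs with |dft - exp| <= tolerance and, among those, minimizes the total
    absolute shift.  Unmatched peaks on either side are reported.  A fully
    unmatched result is valid (e.g. an empty measured list).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    d = dft.freqs
    e = exp.freqs
    m, n = len(d), len(e)
    # dp[i][j]: best (n_pairs, -total_shift) using d[:i], e[:j]
    NEG = (-1, 0.0)
    dp = [[(0, 0.0)] * (n + 1) for _ in range(m + 1)]
    choice = [[0] * (n + 1) for _ in range(m + 1)]  # 0 skip-d, 1 skip-e, 2 pair
    for i in range(1, m + 1):
        for j in range(n + 1):
            best = (dp[i - 1][j], 0)
            if j > 0:
                cand = (dp[i][j - 1], 1)
                if cand[0] > best[0]:
                    best = cand
                shift = d[i - 1] - e[j - 1]
                if abs(shift) <= tolerance:
                    prev = dp[i - 1][j - 1]
                    cand = ((prev[0] + 1, prev[1] - abs(shift)), 2)
                    if cand[0] > best[0]:
                        best = cand
            dp[i][j], choice[i][j] = best
    for j in range(1, n + 1):  # first row: only skipping e is possible
        dp[0][j] = (0, 0.0)
        choice[0][j] = 1

    pairs = []
    matched_d = set()
    matched_e = set()
    i, j = m, n
    while i > 0 or j > 0:
        c = choice[i][j] if i > 0 else 1
        if c == 2:
            shift = d[i - 1] - e[j - 1]
            pairs.append((float(d[i - 1]), float(e[j - 1]), float(shift)))
            matched_d.add(i - 1)
            matched_e.add(j - 1)
            i, j = i - 1, j - 1
        elif c == 1:
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    return PeakPairing(
        analyte=dft.analyte,
        pairs=pairs,
        unmatched_dft=[float(d[k]) for k in range(m) if k not in matched_d],
        unmatched_exp=[float(e[k]) for k in range(n) if k not in matched_e],
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# synthetic identification-rate benchmark
# ---------------------------------------------------------------------------

def identification_rate(
    db: SpectralDatabase,
    replicates_per_analyte: int,
    noise_sd: float,
    w: SsmWeights = SsmWeights(),
    seed: int = 0,
    *,
    jitter_freq_sd: float = 0.01,
    amp_jitter_frac: float = 0.1,
    preprocess: bool = True,
    peak_params: PeakFindParams | None = None,
    return_confusion: bool = False,
):
    """Fraction of synthetic replicate spectra identified correctly at rank 1.

    Replicates are generated from each database entry's stored peak list with
    Gaussian peak-position jitter, +-``amp_jitter_frac`` amplitude jitter and
    additive noise, then searched against the database.  Deterministic for a
    fixed seed.  With ``return_confusion=True`` also returns the dict
    (true name -> {called name -> count}).
    """
    from .synth import replicate_database_entries  # deferred: synth imports io only

    if replicates_per_analyte < 1:
        raise ValueError("replicates_per_analyte must be >= 1")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")

    replicates = replicate_database_entries(
        db,
        n_rep=replicates_per_analyte,
        jitter_freq_sd=jitter_freq_sd,
        amp_jitter_frac=amp_jitter_frac,
        noise_sd=noise_sd,
        seed=seed,
    )
    n_correct = 0
    confusion: dict[str, dict[str, int]] = {name: {} for name in db.names}
    for true_name, spec in replicates:
        try:
            result = search(spec, db, w, peak_params, preprocess=preprocess)
        except EmptyPeakListError:
            # no detectable features (overwhelming noise): no identification
            confusion[true_name]["<none>"] = confusion[true_name].get("<none>", 0) + 1
            continue
        called = result.top_hit.name
        confusion[true_name][called] = confusion[true_name].get(called, 0) + 1
        if called == true_name:
            n_correct += 1
    rate = n_correct / len(replicates)
    if return_confusion:
        return rate, confusion
    return rate
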