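# Methods

This note records the models, numerical choices and open design decisions
behind `thzssm`, and what the synthetic test surface does and does not show.

## Problem setting

Crystalline fentanyl analogs have distinct but similar absorption fingerprints
in the 0.5–3.5 THz band. A transmission THz-TDS measurement of a pressed
pellet yields an absorbance curve sampled at 30 GHz (101 points over the
band); instrument drift and etalon-like effects produce a smooth baseline
under the vibrational peaks, and repeated pellets show small shifts in peak
position and height. Identification is library search: score the unknown
curve against every standard in a database and rank.

## BEADS decomposition

The absorbance `y` is modeled additively as baseline + peak signal + noise,
`y = f + x + w`, with `f` low-pass, `x` sparse in its first two derivatives
and penalized asymmetrically for negative excursions (absorption peaks are
nonnegative), and `w` the high-frequency remainder. The estimate minimizes

```
1/2 ||H(y − x)||² + λ0·θ_r(x) + λ1·Σ φ(D1 x) + λ2·Σ φ(D2 x)
```

where `H = B A⁻¹` is a banded zero-phase high-pass filter of order `d` and
normalized cutoff `fc` (cycles/sample), `θ_r(x) = x` for `x > 0` and `−r·x`
for `x < 0` (quadratically smoothed near zero), and `φ(u) = √(u² + ε)`.
Majorization–minimization solves it: each iteration majorizes `θ_r` and `φ`
by quadratics tangent at the current iterate and solves one sparse banded
system, so the objective is non-increasing by construction (this is asserted
by property tests). Non-convergence within `n_iter` returns the best iterate
with a `converged=False` flag rather than raising — preprocessing must never
abort a batch search. The baseline is recovered as the low-pass of `y − x`,
and the returned triple satisfies `baseline + signal + residual = y` exactly.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `filt_order` (d) | 1 | high-pass filter order |
| `cutoff` (fc) | 0.03 cyc/sample | baseline/peak frequency split |
| `asym_ratio` (r) | 6 | extra penalty on negative signal excursions |
| `lam0, lam1, lam2` | (0.5, 5, 4) × scale | asymmetry / 1st / 2nd difference sparsity weights |
| `n_iter` | 30 | MM iteration cap |
| `eps` | 1e-5 | smoothing constant of φ |

`scale` is estimated per spectrum as the median absolute deviation of the
first difference of the absorbance — a robust noise-roughness proxy — floored
at 0.5% of the dynamic range, because the MAD of near-constant differences
(noiseless smooth input) is zero and would switch the penalties off entirely.

The cutoff deserves a comment. At 30 GHz sampling a record spans only 101
points, so a baseline that drifts across the record has spectral content
around 0.005–0.01 cycles/sample while the ~0.08 THz-wide absorption lines
live near 0.2–0.4 cycles/sample. `fc = 0.03` sits between the two: measured
on random quadratic baselines the recovered-baseline RMSE is below 2% of the
baseline range (worst case 1.7% over 90 draws), while peak positions under
combined drift and noise are recovered within one grid step. A markedly
lower cutoff cannot separate drift from signal at this record length — the
high-pass passes most of the drift and the sparse term absorbs it.

### Boundary handling

Banded `A`, `B` truncate at the record ends, which corrupts a 101-sample
record badly if left alone. Three measures keep the transient out of the
result: the input is median-centered first (the DC level belongs to the
baseline by definition, and a large offset otherwise leaks through the
truncated boundary rows); the record is extended on both sides by ~1/fc
samples of linear extrapolation with Theil–Sen edge slopes (robust to a peak
sitting at the record edge) and cropped after filtering; and MM starts from
the high-pass of `y` rather than from `y`, so content in the filter's null
space (constants, slow drift) starts in the baseline, where the data term —
which cannot see that subspace — would otherwise strand it in the peak
signal whenever the penalties are weak.

## Peak detection

`find_peaks` is deterministic local-maximum detection with three filters:
prominence at least `min_prominence` (default 0.03) times the maximum
absolute amplitude (making detection invariant to intensity rescaling),
separation at least `min_separation` (default 0.09 THz, three grid steps),
and an `edge_margin` (default 0.05 THz) excluded at both band ends. The
prominence threshold is a package choice; no numeric criterion exists for
promoting shoulder features, so it is exposed as a parameter.

The full detection pipeline used by `search(preprocess=True)`
(`preprocess.corrected_peaks`) separates position from intensity: positions
come from the Savitzky–Golay-smoothed (window 5, order 2) baseline-corrected
curve with prominence at least `max(min_prominence·amp, 3.5·σ̂)`, where σ̂ is
a robust noise estimate (1.4826 × MAD) from the BEADS residual; intensities
are read from the unsmoothed baseline-corrected curve. The sparsity shrinkage
of the BEADS clean signal attenuates weak lines toward the noise scale —
fine for locating maxima, ruinous for relative intensities — and drops
shoulder peaks riding on a strong line's tail (e.g. the weak 2.93 THz line
of furanylfentanyl next to its very strong 2.50 THz line), hence the split.
The 3.5σ̂ floor suppresses spurious noise maxima on spectra whose strongest
line is itself weak, where a purely relative threshold dips below the noise.

## Similarity measures

* **CS** — plain cosine similarity of the vector-normalized curves on a
  common grid (linear interpolation onto the intersection range at the
  coarser resolution). One printed formulation composes
  `cos((180/π)·arccos(·))` on top; that degrees-conversion artifact is
  provided as `variant="as_printed"` for documentation but never used in
  scoring, since it is the plain cosine that satisfies "identical spectra
  score 1, anything else less" over angles beyond ~1.6°.
* **CCS** — maximum cosine over integer lags in ±`max_lag` (default 10 grid
  steps = 0.3 THz, covering the ±0.09 THz DFT↔experimental shift scale with
  margin), computed on overlapping segments without zero-padding (padding
  deflates similarity at large lags). Ties break toward smaller |lag|, then
  negative lag, for a deterministic output. Whether the original lagged
  comparison binarized the series at threshold crossings first is not
  operationalizable from its description; this implementation correlates the
  continuous normalized curves.
* **HD** — symmetric Hausdorff distance (via `scipy`'s directed primitive)
  between fingerprint point sets.
* **DFD** — discrete Fréchet distance by the standard dynamic program over
  monotone couplings; property tests verify it against explicit enumeration
  of all coupling paths for short sequences.

HD and DFD act on dimensionless fingerprint points: frequency mapped through
the spectral span to [0, 1], intensity divided by the list maximum. Without
scaling, THz units would dominate intensity arbitrarily. Dividing by the
maximum (rather than min–max scaling) keeps the map continuous for lists of
near-equal intensities — several analogs have all-equal tabulated strengths,
and min–max would amplify ±5% measurement noise to the full unit range.

## SSM scoring and search

For a target `t` with fingerprint peaks and a database of `n ≥ 2` standards,

```
Acc_i = α·CS_i + β·(1 − DFD_i / Σ_k DFD_k),    α + β = 1.
```

Defaults α = 0.2, β = 0.8. The DFD normalization is corpus-relative: the
score of a fixed (target, candidate) pair changes when the database changes.
This is implemented as specified and documented prominently;
`dfd_norm="independent"` substitutes `1 − DFD/(1 + DFD)` for users who need
database-stable scores. If every fingerprint distance is zero the feature
term is defined as 1 for all candidates, preserving the exact self-match
optimum `Acc = α + β = 1` and avoiding division by zero. A `shape_term="ccs"`
switch replaces CS with the CCS maximum for users who read the fused score's
shape term as the lagged variant. Candidates are ranked by descending Acc
with lexicographic tie-break; "stepwise search" is exhaustive per-candidate
scoring — no pruning is warranted at library sizes where THz standards exist.

Peak pairing (`pair_peaks`) assigns DFT-simulated to measured peaks by an
order-preserving dynamic program that maximizes the number of pairs within
tolerance (default 0.15 THz, above the largest tabulated |shift| of 0.09) and
minimizes total |shift| among those — equivalent to nearest-neighbor greedy
on the packaged inventory but well-defined under crowding. Shift is
DFT − experimental, matching the tabulated sign convention. One inventory row
(butyrylfentanyl 0.56/0.52, tabulated shift 0.01) is arithmetically
inconsistent (0.56 − 0.52 = 0.04); the fixture stores the values as printed
and the recomputed shift is reported.

## Synthetic data

The generator emulates the measurement regime, not any particular instrument
trace: Lorentzian lines (the standard condensed-phase THz lineshape;
Gaussian available) of 0.08 THz FWHM — chosen so the closest tabulated
within-analog gap (~0.2 THz) stays resolved — at the packaged fingerprint
positions, with relative amplitudes from the qualitative strength labels
(vw 0.1, w 0.2, m 0.5, s 0.8, vs 1.0; an invented but configurable
convention, since the inventory is qualitative and no absolute absorbance
values are available — amplitudes are arbitrary units). Experimental peaks
carry no tabulated strengths and inherit their row's DFT label amplitude.
Baselines are low-order polynomials plus an optional exponential rise in the
reduced frequency coordinate; noise is additive Gaussian. Replicates emulate
pellet-to-pellet variation with Gaussian peak-position jitter (sd 0.01 THz,
within the tabulated shift scale), ±10% amplitude jitter and fresh noise.
All randomness flows from one seeded generator; identical seeds give
bit-identical spectra.

What passing tests show — and do not. The synthetic surface demonstrates
that the pipeline is self-consistent: it recovers what the generator planted
under the stated drift, jitter and noise, scores exact self-matches at 1,
ranks all eight analogs correctly across α ∈ [0.1, 0.6] at low noise, and
degrades to chance when noise overwhelms the lines. Real spectra add
phenomena the generator omits — etalon fringes, water-vapor lines, purity
and particle-size effects, non-Lorentzian solid-state lineshapes — so
synthetic identification rates are not a measured-sample accuracy claim; the
published real-sample accuracies for this method (94–99%) rest on measured
spectra of seized samples that are not publicly available.

## Problem sizes used in the shipped checks

Acceptance-style checks run at the native regime: 101-point spectra, the
8-entry library, 10 replicates per analog for rate estimates (80 searches per
condition), 6-point α sweeps, and ≥200 random instances per brute-force
oracle comparison. These sizes keep the full suite fast while exercising
every code path at the dimensions the method targets.

## Known limitations

* The corpus-relative Acc is not a calibrated probability; it orders
  candidates within one search only.
* Peak-sparse targets (≤2 detected peaks) make the fingerprint term coarse;
  the shape term then carries the discrimination.
* BEADS parameters are per-spectrum heuristics; pathological inputs (e.g.
  baselines oscillating at the line width) violate the low-pass/sparse split
  assumption and are not separable by any parameter choice.
* JCAMP-DX support covers the uncompressed AFFN subset (XYDATA `(X++(Y..Y))`,
  XYPOINTS) only; SQZ/DIF/DUP packed files are rejected with a clear error.
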