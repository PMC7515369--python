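# Methods

## Estimators

All five estimators operate on a one-dimensional real-valued series
`x_1..x_N` with an implicit delay of 1 sample and the natural
logarithm (the ordinal pair can switch to base 2; quadratic sample
entropy always shares sample entropy's base so the `log 2r` correction
is consistent).

**Permutation entropy (PEn).** Each window of `n` consecutive samples
is encoded by the permutation obtained from a *stable* argsort, i.e.
tied samples are ranked by order of appearance. The estimator is the
Shannon entropy of the empirical pattern distribution over the
`N − n + 1` windows; normalisation divides by `log n!`. Study grid:
`n ∈ {3, 4, 5, 6}`.

**Modified permutation entropy (MPEn).** Windows are encoded by dense
ranks, so tied samples share a rank and tie-bearing patterns are
counted separately. The pattern universe is enumerated exhaustively at
first use rather than taken from published constants: the counts are
the ordered Bell numbers (3, 13, 75, 541, 4683 for n = 2..6). A
published upper bound of 4051 for n = 6 circulates in the literature;
enumeration contradicts it, and since the study grid stops at
`n ∈ {3, 4, 5}` the enumerated value is used for normalisation
throughout. On continuous-valued noise, ties have probability zero, so
normalised MPEn saturates at `log(n!) / log(universe)` — 0.6986 for
n = 3 — which is the "0.7 plateau" seen on white-noise inputs.

**Sample entropy (SEn).** `−log(A/B)` with `B` the number of unordered
template pairs of length `m` within Chebyshev distance `r · SD(x)` and
`A` the pairs still matching at length `m + 1`. Self-matches are
excluded and both counts run over the `N − m` templates that admit an
extension (the Richman–Moorman convention). `SD` is the population
standard deviation (ddof = 0) of the exact series passed in; in
windowed analysis that means the window's own SD, so each window is
treated as an independent series. If either count is zero the ratio is
undefined and the estimator returns `nan`; windowed curves keep such
windows tagged (and log a warning) rather than dropping or
extrapolating them. Grid: `m ∈ {1, 2}`, `r ∈ {0.1, 0.15, 0.2, 0.25}`.

**Quadratic sample entropy (QSEn).** `SEn(m, r) + log(2r)`, converting
the conditional-probability estimate to a density by normalising to
the matching-region volume; the identity `QSEn − SEn = log 2r` holds to
machine precision wherever SEn is defined and is asserted in tests.
Two tolerance presets are shipped — `{0.2, 0.4, 0.6, 0.8}` (default)
and `{0.4, 0.6, 0.8, 1.0}` — because both grids appear in the
literature this design follows.

**Fuzzy entropy (FEn).** Template vectors of length `m` (and `m + 1`)
have their own mean subtracted (baseline removal, toggleable), and the
binary match is replaced by the similarity kernel
`D = exp(−d^n / r·SD)` with `d` the Chebyshev distance and `n` a shape
exponent. `φ_m` is the mean pairwise similarity over the `N − m`
vectors excluding self-pairs, and `FEn = −log(φ_{m+1} / φ_m)`. Grid:
`n ∈ {1, 2, 3}`, `m ∈ {1, 2}`, `r ∈ {0.1, 0.15, 0.2, 0.25}`.

Note one consequence of this kernel: for `n = 1` the estimator is
invariant under affine maps `a·x + b` (distances and tolerance both
scale with `a`), but for `n ≥ 2` the numerator scales as `a^n` against
the tolerance's `a`, so FEn with higher exponents is *not* scale-free.
For `m = 1` baseline removal collapses every length-1 vector to zero,
making `φ_1 ≡ 1`; the estimator then reduces to `−log φ_2`, which is
the behaviour of the construction it follows, not a defect.

All five implementations are vectorised (pairwise distances in
chunked NumPy blocks of 512 rows, bounding memory at ~tens of MB for
10 240-sample segments) and are verified against naive double-loop
reference implementations to 1e-10 in the test suite.

## Benchmark signals

Ten signals, 40 s at 256 Hz (10 240 samples), most divided into four
10 s regimes; all stochastic generators are bit-reproducible from a
seed, and `benchmark_suite` expands one master seed into independent
per-generator streams via `numpy.random.SeedSequence.spawn`.

1. **Constant-amplitude chirp** — unit-amplitude sinusoid sweeping
   0.5 → 5 Hz linearly. Base amplitude is 1.0 by choice; all estimators
   here are amplitude-invariant (rank-based or SD-relative).
2. **Modulated chirp** — the same chirp times
   `0.75 + 0.25 cos(2π·0.05 t)`.
3. **Harmonic stack** — segments with 1/2/5/7 sinusoids, frequencies
   log-spaced 0.4–100 Hz, amplitudes log-spaced 0.5–0.005 with the
   highest frequency weakest (an explicit interpretation choice,
   mimicking 1/f-like EEG spectra; linear spacing was the alternative).
4. **Quasi-periodic + noise** — `(1 + 0.1 cos 2π·0.05 t)(sin 2π·0.61 t
   + sin 2π·1 t)` plus white Gaussian noise of per-segment SD
   0/0.1/0.3/0.5 ("noise magnitude" read as standard deviation).
5. **WGN power steps** — independent Gaussian segments of variance
   0.1/0.3/0.5/0.7 ("power" read as variance).
6. **WGN bandwidth steps** — one white realisation; segments 1–3
   low-pass filtered at 30/60/100 Hz (Hamming FIR, order 425, applied
   forward–backward per segment), segment 4 untouched.
7. **MIX process** — per-sample Bernoulli(p_k) choice between the
   period-12 sequence `2 sin(2πk/12)` and Uniform(−3, 3) noise, with
   p swept 0.9 → 0.1. The mixture form `(1−z)x + z·y` follows the
   standard MIX construction.
8. **AR(1) sweep** — `x_k = p_k x_{k−1} + ε_k`, unit-variance Gaussian
   innovations (a convention choice; entropies are scale-free), with p
   swept +0.9 → −0.9 per-sample across the retained record and 100
   burn-in samples discarded.
9. **Logistic map** — `x_k = μ x_{k−1}(1 − x_{k−1})`, 20 s at μ = 3.55
   (a period-8 orbit) then 20 s at μ = 3.8 (chaos), from x₀ = 0.3 with
   a 100-iterate burn-in applied per segment so each regime is sampled
   on-attractor.
10. **Lorenz system** — x-coordinate under (σ, β, ρ) = (10, 8/3, 28)
    (chaotic) then (10, 8/3, 99.96) (torus knot), integrated by
    fixed-step RK4 with dt = 1/256 in system time units from state
    (1, 1, 1), a 10 s transient discarded per parameter set, each half
    standardised to zero mean and unit SD. Step size, transient and
    initial state are configurable.

**Surrogate EEG classes.** Labelled AR(1)-plus-optional-sinusoid
segments with per-class regularity parameters stand in for clinical
recordings when exercising the group-study and classification chain.
They emulate only the property the pipeline consumes — controllable
regularity differences between classes — and none of the physiology of
real EEG (no 1/f spectrum, no alpha rhythm, no artefacts, no
inter-subject variability). Pipeline tests passing on surrogates
therefore demonstrate the machinery (features → tests → classifier),
not clinical effect sizes.

## Windowed analysis

Windows are `length × (1 − overlap)` apart (10 s length, 90 % overlap,
i.e. 1 s hop by default), and curves are stamped at the window *end*,
so a default 40 s curve has 31 points at t = 10..40 s. Embedding
tolerances rescale to each window's own SD rather than the whole
signal's — each window is an independent series; with whole-signal SD
the curves of amplitude-stepped signals would confound amplitude with
irregularity. The transition-contrast statistic is the difference of
mean entropy between windows wholly after and wholly before a
boundary; straddling windows stay in the curve (they are real data)
but are excluded from the contrast, since they mix regimes.

One caveat found while validating curve shapes: on the harmonic-stack
signal the *ordinal* estimators jump as soon as the weak 100 Hz
component appears (its per-sample variation rivals the slow carrier's,
and ranks ignore amplitude), then flatten; segment-over-segment growth
is strict for sample entropy, while for PEn only the overall
first-to-final increase holds. This is a property of rank-based
encoding, not a generator artefact.

## EEG study pipeline

ASCII loading accepts one numeric value per non-empty line and reports
the offending line number otherwise. Band-pass preprocessing (0.5–40 Hz,
Hamming FIR of order 425) is applied zero-phase (forward–backward) so
filtered samples stay aligned with unfiltered time; even (reflect)
padding is used because odd extension of segments cut mid-oscillation
injects edge transients that leak stop-band energy. The filtered
segment is used whole — no edge trimming — matching whole-segment
entropy usage; a trim length can be supplied by slicing beforehand.

Test selection is a pure function of the declared design: paired
two-group → Wilcoxon signed-rank, independent two-group →
Mann–Whitney U, independent k-group → Kruskal–Wallis; all two-sided,
significance at α = 0.01, with scipy's exact small-sample p-values
where available (verified against full enumeration in tests).
Degenerate inputs (all-zero paired differences; identical pooled
values) return tagged non-significant results instead of raising.
Post-hoc pairwise Mann–Whitney p-values are reported raw by default,
with an optional Holm correction flag.

Classification is k-NN with k = 3 on Euclidean distance, stratified
10-fold cross-validation from a seed, and features z-scored with
training-fold statistics only (entropy features span different scales;
leaking test statistics would bias accuracy). Vote ties resolve to the
class of the single nearest neighbour. Feature-set search is
exhaustive over combinations of 1–5 columns with pairwise-distinct
algorithm families; ranking is by mean fold accuracy, ties broken by
smaller set then column order. Both mean-over-folds and pooled
held-out accuracy are reported. Rows with undefined feature values are
dropped with a logged count before cross-validation.

## Problem sizes and numerical choices

The validation suite runs the full 40 s benchmark signals for curve
shapes, 10 000 iterates for orbit counting, sequences of length
50–200 against the brute-force references, and 50 segments of 4 s per
surrogate class for the pipeline — sizes at which every stochastic
assertion has comfortable margin while the whole suite stays quick on
a single CPU. Distinctness of logistic-map orbit values uses a 1e-6
merge tolerance; window counts follow the closed form
`(N − w)/step + 1`; chunked pairwise computations are exact (no
approximation is introduced by blocking).

## Known limitations

* Embedding estimators are O(N²) per evaluation; whole-segment FEn on
  very long records is the slowest path.
* FEn with exponent n ≥ 2 is not affine-invariant (see above); compare
  such values only across signals normalised the same way.
* The surrogate classes are deliberately minimal; no claim about real
  EEG classification accuracy follows from them.
* The Lorenz "torus-knot" half is integrated, not analytically
  periodic; its entropy step at the regime boundary is small and
  depends on the documented integrator settings.
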