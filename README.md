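# entrosig

Entropy estimators and benchmark signals for nonlinear biomedical
time-series analysis, with an EEG-style group-study pipeline.

Entropy algorithms quantify the irregularity of a physiological
recording — an EEG channel, a heart-rate series — but different
estimators respond to different signal properties, and applying them
blindly invites misinterpretation. `entrosig` implements the two major
families side by side so their behaviour can be compared on controlled
signals before they are trusted on clinical data:

* **Ordinal estimators.** Permutation entropy (PEn) encodes each run of
  *n* consecutive samples by the permutation that sorts it and returns
  the Shannon entropy of the pattern distribution,
  `H = −Σ p(π) log p(π)`, normalised by `log n!`. Modified permutation
  entropy (MPEn) keeps tied samples as patterns of their own, enlarging
  the pattern universe to the ordered Bell numbers (13 patterns for
  n = 3); on continuous noise only the strict patterns occur, so
  normalised MPEn saturates at `ln 6 / ln 13 ≈ 0.70` rather than 1.
* **Embedding estimators.** Sample entropy
  `SEn(m, r) = −log(A/B)` compares length-*m* template vectors under
  the Chebyshev distance with tolerance `r · SD`; `B` counts matching
  template pairs, `A` those still matching at length m + 1. Quadratic
  sample entropy adds the matching-volume correction,
  `QSEn = SEn + log 2r`, making values comparable across tolerances.
  Fuzzy entropy replaces the hard match by the graded similarity
  `exp(−d^n / r)` on baseline-removed vectors.

The package also ships the ten synthetic benchmark signals used to
characterise these estimators (chirps, harmonic stacks, noise ramps,
MIX process, AR(1) sweep, logistic map, Lorenz system; 40 s at 256 Hz
in four 10 s regimes), a sliding-window entropy-curve engine (10 s
windows, 90 % overlap), and a study pipeline: single-column ASCII EEG
loading, 0.5–40 Hz zero-phase FIR preprocessing, nonparametric group
tests (Wilcoxon signed-rank / Mann–Whitney U / Kruskal–Wallis at
α = 0.01) and k-NN classification (k = 3, stratified 10-fold CV) over
entropy feature combinations with same-family exclusion.

## Worked example

The logistic-map benchmark switches from a period-8 orbit (μ = 3.55)
to chaos (μ = 3.8) at t = 20 s; both estimator families detect the
transition as a positive jump in windowed entropy:

```python
from entrosig import (GeneratorSpec, PEnConfig, SEnConfig, config_name,
                      entropy_curve, generate_signal, transition_contrast)

sig = generate_signal(9, GeneratorSpec(seed=1))   # logistic map
for cfg in (PEnConfig(n=3), SEnConfig(m=1, r=0.2)):
    curve = entropy_curve(sig, cfg)
    print(f"{config_name(cfg):>14}: first={curve.values[0]:.3f} "
          f"final={curve.values[-1]:.3f} "
          f"contrast(t=20s)={transition_contrast(curve, 20.0):+.3f}")
```

```
      PEn(n=3): first=0.774 final=0.836 contrast(t=20s)=+0.064
SEn(m=1,r=0.2): first=-0.000 final=0.553 contrast(t=20s)=+0.556
```

`first` and `final` are the entropies of the windows ending at t = 10 s
and t = 40 s. Sample entropy of the periodic half is ~0 (every template
recurs exactly), and its step at the regime boundary is far larger than
permutation entropy's — the embedding family is the more sensitive
detector of this transition, at higher computational cost.

A command-line interface wraps the same functionality
(`entrosig simulate`, `entropy`, `curve`, `classify`,
`reproduce-synthetic`); see `entrosig --help`.

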